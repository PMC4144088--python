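"""From gene tables and signal tracks to the standardized predictor matrix.

The pipeline mirrors standard promoter-proximal chromatin preprocessing:
signal is averaged over non-overlapping 200 bp windows on TSS +/- 1 kb
(10 windows per mark, oriented in the direction of transcription), each
column is mapped to standard-normal quantiles after breaking ties with a
small N(0, 0.01) disturbance, and genes are filtered by an ordered set of
rules (annotation mismatch, strand mismatch, masked windows, zero
expression, duplicate TSS) with a telescoping report of counts.

Coordinates are 0-based half-open throughout: a TSS +/- 1 kb span is
[tss-1000, tss+1000), split into windows [tss-1000+200k, tss-800+200k).
For minus-strand genes the window order is reversed so that offset -1000
is always the most upstream window in transcription direction.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureMatrix, FilterReport, GeneRecord

logger = logging.getLogger(__name__)

# the tie-breaking disturbance is N(0, 0.01), i.e. variance 0.01
JITTER_SD = 0.1

CONDITION_NUMBER_CUTOFF = 30.0


# ---------------------------------------------------------------------------
# window averaging


def _track_arrays(track) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, values), sorted by start."""
    if isinstance(track, pd.DataFrame):
        df = track
    else:
        df = pd.DataFrame(track, columns=["chrom", "start", "end", "value"])
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        v = sub["value"].to_numpy(dtype=float)
        if np.any(e <= s):
            raise ValueError(f"empty or inverted interval on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
        out[chrom] = (s, e, v)
    return out


def _interval_mean(
    s: np.ndarray, e: np.ndarray, v: np.ndarray, a: int, b: int
) -> float:
    """Mean of the track over [a, b); uncovered bases contribute 0."""
    lo = np.searchsorted(e, a, side="right")
    hi = np.searchsorted(s, b, side="left")
    if lo >= hi:
        return 0.0
    ss, ee, vv = s[lo:hi], e[lo:hi], v[lo:hi]
    overlap = np.minimum(ee, b) - np.maximum(ss, a)
    return float(np.sum(overlap * vv) / (b - a))


def _windows_for_gene(g: GeneRecord, span: int, window: int) -> list[tuple[int, int]]:
    """Genomic [start, end) of each window, in transcription-direction order."""
    n_win = 2 * span // window
    out = []
    for k in range(n_win):
        off = -span + k * window  # oriented offset of the window's upstream edge
        if g.strand == "+":
            a = g.tss + off
        else:
            a = g.tss - off - window
        out.append((a, a + window))
    return out


def window_average(
    track,
    genes: Sequence[GeneRecord],
    span: int = 1000,
    window_size: int = 200,
    mark: str = "signal",
    mask: Optional[Sequence[tuple[str, int, int]]] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> FeatureMatrix:
    """Average the track over each gene's promoter-proximal windows.

    Entry (t, w) is the mean signal over window w of gene t, windows ordered
    upstream to downstream along the transcription direction.  Windows that
    overlap a masked interval, or that extend past chromosome bounds, are
    flagged in ``mask_flags`` (their values are still computed, never
    silently truncated).
    """
    if span % window_size != 0:
        raise ValueError("span must be divisible by window_size")
    arrays = _track_arrays(track)
    mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if mask is not None:
        mdf = mask if isinstance(mask, pd.DataFrame) else pd.DataFrame(
            mask, columns=["chrom", "start", "end"]
        )
        for chrom, sub in mdf.groupby("chrom", sort=False):
            mask_by_chrom[chrom] = list(zip(sub["start"], sub["end"]))

    n_win = 2 * span // window_size
    values = np.zeros((len(genes), n_win))
    flags = np.zeros((len(genes), n_win), dtype=bool)
    for t, g in enumerate(genes):
        s, e, v = arrays.get(g.chrom, (np.array([], np.int64), np.array([], np.int64), np.array([])))
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        for w, (a, b) in enumerate(_windows_for_gene(g, span, window_size)):
            values[t, w] = _interval_mean(s, e, v, a, b)
            if a < 0 or (size is not None and b > size):
                flags[t, w] = True
            for ms, me in mask_by_chrom.get(g.chrom, ()):
                if a < me and ms < b:
                    flags[t, w] = True
                    break
    columns = [(mark, -span + k * window_size) for k in range(n_win)]
    return FeatureMatrix(values=values, columns=columns,
                         gene_ids=[g.accession for g in genes], mask_flags=flags)


def build_feature_matrix(
    tracks: dict[str, object],
    genes: Sequence[GeneRecord],
    span: int = 1000,
    window_size: int = 200,
    mask=None,
    chrom_sizes=None,
) -> FeatureMatrix:
    """Stack window averages of several marks into one T x p matrix."""
    parts = [
        window_average(track, genes, span, window_size, mark=mark, mask=mask,
                       chrom_sizes=chrom_sizes)
        for mark, track in tracks.items()
    ]
    return FeatureMatrix(
        values=np.hstack([p.values for p in parts]),
        columns=[c for p in parts for c in p.columns],
        gene_ids=[g.accession for g in genes],
        mask_flags=np.hstack([p.mask_flags for p in parts]),
    )


# ---------------------------------------------------------------------------
# standardization


def jitter_ties(values: np.ndarray, sd: float = JITTER_SD, seed: Optional[int] = None) -> np.ndarray:
    """Add i.i.d. N(0, sd^2) noise to break ties; sd=0 returns input unchanged."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    values = np.asarray(values, dtype=float)
    if sd == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    return values + sd * rng.standard_normal(values.shape)


def quantile_normalize(
    values: np.ndarray, seed: Optional[int] = None, jitter_sd: float = JITTER_SD
) -> np.ndarray:
    """Map empirical quantiles onto standard-normal quantiles.

    Rank r of n (ties broken first by jitter, applied only when ties exist)
    maps to Phi^{-1}((r - 0.5)/n), so the output order statistics are exactly
    those normal quantiles and the transform is monotone in the (jittered)
    input.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to standardize")
    work = values
    if len(np.unique(values)) < n:
        work = jitter_ties(values, sd=jitter_sd, seed=seed)
        # jitter breaks ties almost surely; regenerate on the pathological miss
        bump = 0
        while len(np.unique(work)) < n:
            bump += 1
            work = jitter_ties(values, sd=jitter_sd or 1e-9,
                               seed=None if seed is None else seed + bump)
    order = np.argsort(work, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return stats.norm.ppf((ranks - 0.5) / n)


def standardize_features(fm: FeatureMatrix, seed: Optional[int] = None) -> FeatureMatrix:
    """Column-wise quantile standardization of a feature matrix."""
    rng = np.random.default_rng(seed)
    out = np.empty_like(fm.values)
    for j in range(fm.n_features):
        out[:, j] = quantile_normalize(fm.values[:, j], seed=int(rng.integers(2**31 - 1)))
    return FeatureMatrix(values=out, columns=list(fm.columns),
                         gene_ids=fm.gene_ids, mask_flags=fm.mask_flags)


# ---------------------------------------------------------------------------
# gene filtering


DEFAULT_FILTER_ORDER = (
    "unmatched_annotation",
    "strand_mismatch",
    "masked_windows",
    "zero_expression",
    "duplicate_tss",
)


def filter_genes(
    genes: Sequence[GeneRecord],
    feature_matrix: Optional[FeatureMatrix] = None,
    rules: Sequence[str] = DEFAULT_FILTER_ORDER,
    known_accessions: Optional[set] = None,
    reference_strands: Optional[dict[str, str]] = None,
) -> tuple[list[GeneRecord], Optional[FeatureMatrix], FilterReport]:
    """Apply the ordered filtering rules and report telescoping counts.

    duplicate_tss keeps, per (chrom, tss), the record with the highest
    expression.  Raises if nothing survives.
    """
    keep = np.ones(len(genes), dtype=bool)
    report = FilterReport(n_input=len(genes))

    def apply(name: str, drop: np.ndarray) -> None:
        drop = drop & keep
        keep[drop] = False
        report.add(name, int(drop.sum()), int(keep.sum()))

    for rule in rules:
        if rule == "unmatched_annotation":
            if known_accessions is None:
                apply(rule, np.zeros(len(genes), dtype=bool))
            else:
                apply(rule, np.array([g.accession not in known_accessions for g in genes]))
        elif rule == "strand_mismatch":
            if reference_strands is None:
                apply(rule, np.zeros(len(genes), dtype=bool))
            else:
                apply(rule, np.array([
                    reference_strands.get(g.accession, g.strand) != g.strand for g in genes
                ]))
        elif rule == "masked_windows":
            if feature_matrix is None or feature_matrix.mask_flags is None:
                apply(rule, np.zeros(len(genes), dtype=bool))
            else:
                apply(rule, feature_matrix.mask_flags.any(axis=1))
        elif rule == "zero_expression":
            apply(rule, np.array([g.expression == 0 for g in genes]))
        elif rule == "duplicate_tss":
            drop = np.zeros(len(genes), dtype=bool)
            best: dict[tuple[str, int], int] = {}
            for t, g in enumerate(genes):
                if not keep[t]:
                    continue
                key = (g.chrom, g.tss)
                if key not in best:
                    best[key] = t
                elif g.expression > genes[best[key]].expression:
                    drop[best[key]] = True
                    best[key] = t
                else:
                    drop[t] = True
            apply(rule, drop)
        else:
            raise ValueError(f"unknown filter rule {rule!r}")

    if not keep.any():
        raise ValueError("all genes removed by filtering")
    idx = np.flatnonzero(keep)
    kept_genes = _recompute_distances([genes[i] for i in idx])
    fm = feature_matrix.subset(idx) if feature_matrix is not None else None
    return kept_genes, fm, report


def _recompute_distances(genes: list[GeneRecord]) -> list[GeneRecord]:
    prev: dict[str, GeneRecord] = {}
    for g in genes:
        if g.chrom in prev:
            g.dist_prev = int(g.tss - prev[g.chrom].tss) or None
            if g.dist_prev is not None and g.dist_prev < 0:
                raise ValueError("genes must be sorted by TSS within chromosome")
        else:
            g.dist_prev = None
        prev[g.chrom] = g
    return genes


# ---------------------------------------------------------------------------
# multicollinearity diagnostic


def condition_number(X: np.ndarray, with_intercept: bool = False) -> float:
    """sqrt(lambda_max / lambda_min) of X'X; +inf when rank-deficient."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if with_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    eig = np.linalg.eigvalsh(X.T @ X)
    lam_max = eig[-1]
    lam_min = eig[0]
    if lam_min <= lam_max * np.finfo(float).eps * max(X.shape):
        return float("inf")
    return float(np.sqrt(lam_max / lam_min))


def is_multicollinear(X: np.ndarray, cutoff: float = CONDITION_NUMBER_CUTOFF,
                      with_intercept: bool = False) -> bool:
    return condition_number(X, with_intercept=with_intercept) >= cutoff
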