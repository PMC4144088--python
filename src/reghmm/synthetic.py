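"""Synthetic datasets with the statistical structure the regression HMM assumes.

The generator produces gene tables with irregular inter-gene spacing, a hidden
Markov state path whose persistence decays with distance, state-conditional
multivariate-normal predictors, state-specific linear expression responses,
state-biased binary annotations, and (optionally) a base-resolution signal
track whose window averages are known exactly.  Every stage of the analysis
can therefore be tested against known truth.

The default two-state configuration mirrors the structure the model is meant
to detect in promoter-proximal chromatin data: a strong-association state
(within-state R^2 about 0.7, intercept 0.25) and a weak-association state
(R^2 about 0.4, intercept 1.15), a 0.5 baseline stay probability mixed toward
persistence by the distance kernel with D = 4000 bp, log-uniform inter-gene
gaps over 1e2..1e6 bp on a single chromosome, and a CpG-island-like binary
label at per-state rates 0.59 / 0.70.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import chain_starts, transition_matrix
from .types import FeatureMatrix, GeneRecord, format_column


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic dataset."""

    n_genes: int = 500
    state_means: np.ndarray = None  # M x p predictor means
    predictor_cov: np.ndarray = None  # p x p (shared) or M x p x p
    betas: np.ndarray = None  # M x (p+1), intercept first
    sigmas: np.ndarray = None  # M residual SDs
    baseline_transitions: np.ndarray = None  # M x M
    pi: np.ndarray = None
    distance_constant: float = 4000.0
    distance_law: tuple = ("log_uniform", 1e2, 1e6)
    annotation_rates: dict = field(default_factory=dict)  # label -> per-state rates
    marks: Sequence[str] = ("H3K4me3",)
    span: int = 1000
    window: int = 200
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("state_means", "predictor_cov", "betas", "sigmas", "baseline_transitions", "pi"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.betas is None:
            raise ValueError("betas must be provided (use make_two_state_spec for defaults)")
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be >= 0")
        if self.distance_constant <= 0:
            raise ValueError("distance_constant must be > 0")
        M = self.n_states
        if self.pi is None:
            self.pi = np.full(M, 1.0 / M)
        rows = self.baseline_transitions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("rows of baseline_transitions must sum to 1")

    @property
    def n_states(self) -> int:
        return self.betas.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.betas.shape[1] - 1

    @property
    def columns(self) -> list[tuple[str, int]]:
        per_mark = self.n_predictors // len(self.marks)
        cols = []
        for mark in self.marks:
            for k in range(per_mark):
                cols.append((mark, -self.span + k * self.window))
        return cols

    def cov_for_state(self, i: int) -> np.ndarray:
        if self.predictor_cov.ndim == 3:
            return self.predictor_cov[i]
        return self.predictor_cov

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "state_means": self.state_means.tolist(),
            "predictor_cov": self.predictor_cov.tolist(),
            "betas": self.betas.tolist(),
            "sigmas": self.sigmas.tolist(),
            "baseline_transitions": self.baseline_transitions.tolist(),
            "pi": self.pi.tolist(),
            "distance_constant": self.distance_constant,
            "distance_law": list(self.distance_law),
            "annotation_rates": {k: list(v) for k, v in self.annotation_rates.items()},
            "marks": list(self.marks),
            "span": self.span,
            "window": self.window,
            "chrom": self.chrom,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["distance_law"] = tuple(d["distance_law"])
        d["annotation_rates"] = {k: tuple(v) for k, v in d.get("annotation_rates", {}).items()}
        d["marks"] = tuple(d["marks"])
        return cls(**d)


def ar1_covariance(p: int, rho: float = 0.6, scale: float = 1.0) -> np.ndarray:
    """AR(1) correlation within a mark: neighbouring windows are more alike."""
    idx = np.arange(p)
    return scale * rho ** np.abs(idx[:, None] - idx[None, :])


def make_two_state_spec(
    n_genes: int = 500,
    p: int = 10,
    intercepts: tuple[float, float] = (0.25, 1.15),
    target_r2: tuple[float, float] = (0.7, 0.4),
    p_stay: float = 0.5,
    distance_constant: float = 4000.0,
    distance_law: tuple = ("log_uniform", 1e2, 1e6),
    mean_shift: float = 0.5,
    rho: float = 0.6,
    marks: Sequence[str] = ("H3K4me3",),
    seed: int = 0,
) -> SyntheticSpec:
    """Canonical two-state configuration (the study conditions).

    Slopes are distinct between states and scaled so that, within each state,
    the signal variance beta' Sigma beta is 1; the residual SD is then set
    from the requested within-state R^2 via sigma^2 = (1 - R^2)/R^2.
    """
    if p % len(marks) != 0:
        raise ValueError("p must be divisible by the number of marks")
    per_mark = p // len(marks)
    # AR(1) correlation within each mark, marks independent
    blocks = [ar1_covariance(per_mark, rho=rho)] * len(marks)
    cov = np.zeros((p, p))
    for b, blk in enumerate(blocks):
        cov[b * per_mark:(b + 1) * per_mark, b * per_mark:(b + 1) * per_mark] = blk
    # distinct, smoothly varying slope profiles
    k = np.arange(p)
    slope1 = np.sin(np.pi * (k + 1) / (p + 1)) + 0.3
    slope2 = np.cos(np.pi * k / max(p - 1, 1)) * 0.8 + 0.2
    betas = np.zeros((2, p + 1))
    sigmas = np.zeros(2)
    for i, (b0, raw, r2) in enumerate(zip(intercepts, (slope1, slope2), target_r2)):
        scale = 1.0 / np.sqrt(raw @ cov @ raw)
        betas[i, 0] = b0
        betas[i, 1:] = raw * scale
        sigmas[i] = np.sqrt((1.0 - r2) / r2)
    P = np.array([[p_stay, 1.0 - p_stay], [1.0 - p_stay, p_stay]])
    means = np.vstack([np.zeros(p), np.full(p, mean_shift)])
    return SyntheticSpec(
        n_genes=n_genes,
        state_means=means,
        predictor_cov=cov,
        betas=betas,
        sigmas=sigmas,
        baseline_transitions=P,
        distance_constant=distance_constant,
        distance_law=distance_law,
        annotation_rates={"cpg": (0.59, 0.70)},
        marks=tuple(marks),
        seed=seed,
    )


def make_recovery_spec(
    n_genes: int = 2000,
    p: int = 10,
    seed: int = 0,
    distance_law: tuple = ("log_uniform", 1e2, 1e4),
) -> SyntheticSpec:
    """Well-separated two-state configuration for estimator validation.

    Parameter-recovery and model-selection experiments need identifiable,
    well-separated states, so this configuration keeps the canonical
    intercepts (0.25 / 1.15) and within-state R^2 (0.7 / 0.4) but makes the
    two regression surfaces maximally distinct: the slope profiles point in
    opposite directions, state 2 carries twice the signal variance, and the
    gene geometry is dense (log-uniform gaps over 1e2..1e4 bp, mostly below
    D = 4000) so the distance-dependent persistence is strong.  The Viterbi
    decoding ceiling at the true parameters is about 93%; weaker separation
    would test the difficulty of the problem rather than the correctness of
    the estimator.
    """
    cov = ar1_covariance(p, rho=0.6)
    k = np.arange(p)
    raw = np.sin(np.pi * (k + 1) / (p + 1)) + 0.3
    b1 = raw / np.sqrt(raw @ cov @ raw)  # signal variance 1
    b2 = -b1 * np.sqrt(2.0)  # opposed direction, signal variance 2
    betas = np.zeros((2, p + 1))
    betas[0, 0], betas[0, 1:] = 0.25, b1
    betas[1, 0], betas[1, 1:] = 1.15, b2
    sigmas = np.array([np.sqrt(1.0 * 0.3 / 0.7), np.sqrt(2.0 * 0.6 / 0.4)])
    return SyntheticSpec(
        n_genes=n_genes,
        state_means=np.vstack([np.zeros(p), np.full(p, 0.5)]),
        predictor_cov=cov,
        betas=betas,
        sigmas=sigmas,
        baseline_transitions=np.array([[0.5, 0.5], [0.5, 0.5]]),
        distance_law=distance_law,
        annotation_rates={"cpg": (0.59, 0.70)},
        seed=seed,
    )


def make_one_state_spec(n_genes: int = 2000, p: int = 10, seed: int = 0) -> SyntheticSpec:
    """Single-regression data (no latent structure): the M = 1 null."""
    cov = ar1_covariance(p, rho=0.6)
    k = np.arange(p)
    raw = np.sin(np.pi * (k + 1) / (p + 1)) + 0.3
    b1 = raw / np.sqrt(raw @ cov @ raw)
    betas = np.zeros((1, p + 1))
    betas[0, 0], betas[0, 1:] = 0.25, b1
    return SyntheticSpec(
        n_genes=n_genes,
        state_means=np.zeros((1, p)),
        predictor_cov=cov,
        betas=betas,
        sigmas=np.array([np.sqrt(0.3 / 0.7)]),
        baseline_transitions=np.array([[1.0]]),
        distance_law=("log_uniform", 1e2, 1e4),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation stages


def _draw_distances(n: int, law: tuple, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "log_uniform":
        lo, hi = float(law[1]), float(law[2])
        d = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    elif kind == "log_normal":
        mu, sd = float(law[1]), float(law[2])
        d = np.exp(rng.normal(mu, sd, size=n))
    elif kind == "fixed":
        d = np.full(n, float(law[1]))
    else:
        raise ValueError(f"unknown distance law {kind!r}")
    return np.maximum(np.rint(d).astype(int), 1)


def gen_positions(
    n_genes: int,
    distance_law: tuple = ("log_uniform", 1e2, 1e6),
    seed: Optional[int] = None,
    chrom: str = "chr1",
    start: int = 10_000,
    fixed_strand: Optional[str] = None,
) -> list[GeneRecord]:
    """Ordered gene positions with inter-gene gaps drawn from the given law."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    gaps = _draw_distances(n_genes - 1, distance_law, rng) if n_genes > 1 else np.array([], int)
    tss = start + np.concatenate([[0], np.cumsum(gaps)])
    if fixed_strand is None:
        strands = rng.choice(["+", "-"], size=n_genes)
    else:
        strands = np.full(n_genes, fixed_strand)
    genes = []
    for t in range(n_genes):
        genes.append(
            GeneRecord(
                accession=f"NM_{t:06d}",
                chrom=chrom,
                tss=int(tss[t]),
                strand=str(strands[t]),
                dist_prev=int(gaps[t - 1]) if t > 0 else None,
            )
        )
    return genes


def gen_state_path(
    distances: np.ndarray,
    baseline_transitions: np.ndarray,
    D: float,
    pi: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Hidden path: q_1 ~ pi, then the distance-dependent transition kernel.

    Returns 1-based state labels."""
    if rng is None:
        rng = np.random.default_rng(seed)
    distances = np.asarray(distances, dtype=float)
    pi = np.asarray(pi, dtype=float)
    P = np.asarray(baseline_transitions, dtype=float)
    M = len(pi)
    starts = chain_starts(distances)
    T = len(distances)
    states = np.empty(T, dtype=int)
    for t in range(T):
        if starts[t]:
            states[t] = rng.choice(M, p=pi)
        else:
            A = transition_matrix(distances[t], P, D)
            states[t] = rng.choice(M, p=A[states[t - 1]])
    return states + 1


def gen_predictors(
    true_states: np.ndarray,
    spec: SyntheticSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FeatureMatrix:
    """Row t is multivariate normal with the mean/covariance of state q_t."""
    if rng is None:
        rng = np.random.default_rng(seed)
    states0 = np.asarray(true_states, dtype=int) - 1
    T = len(states0)
    p = spec.n_predictors
    X = np.empty((T, p))
    for i in range(spec.n_states):
        sel = states0 == i
        if not sel.any():
            continue
        cov = spec.cov_for_state(i)
        try:
            root = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            # positive SEMI-definite covariances (e.g. exactly zero) are fine
            eigval, eigvec = np.linalg.eigh(cov)
            if np.any(eigval < -1e-10 * max(eigval.max(), 1.0)):
                raise ValueError("predictor covariance must be positive semi-definite")
            root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        X[sel] = spec.state_means[i] + rng.standard_normal((sel.sum(), p)) @ root.T
    return FeatureMatrix(values=X, columns=spec.columns,
                         gene_ids=[f"NM_{t:06d}" for t in range(T)])


def gen_expression(
    predictors: FeatureMatrix | np.ndarray,
    true_states: np.ndarray,
    betas: np.ndarray,
    sigmas: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """y_t = beta_{q_t,0} + x_t . beta_{q_t} + N(0, sigma_{q_t}^2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X = predictors.values if isinstance(predictors, FeatureMatrix) else np.asarray(predictors)
    states0 = np.asarray(true_states, dtype=int) - 1
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be >= 0")
    if X.shape[0] != len(states0):
        raise ValueError("predictors and states must have matching length")
    mu = betas[states0, 0] + np.einsum("tp,tp->t", X, betas[states0, 1:])
    return mu + sigmas[states0] * rng.standard_normal(len(states0))


def gen_annotations(
    true_states: np.ndarray,
    annotation_rates: dict,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Binary labels drawn Bernoulli(rate[state]) per gene, one column per label."""
    if rng is None:
        rng = np.random.default_rng(seed)
    states0 = np.asarray(true_states, dtype=int) - 1
    out = {}
    for label, rates in annotation_rates.items():
        rates = np.asarray(rates, dtype=float)
        out[label] = (rng.random(len(states0)) < rates[states0]).astype(int)
    return pd.DataFrame(out)


def gen_signal_track(
    genes: Sequence[GeneRecord],
    span: int = 1000,
    window: int = 200,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    level_sd: float = 1.0,
    constant: Optional[float] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """bedGraph-like records around each TSS plus the exact window-mean oracle.

    Each window of each gene receives one constant level, emitted as one
    bedGraph interval, so the window average of the track is the level
    itself.  Returns (track DataFrame with chrom/start/end/value, oracle
    matrix in transcription-direction window order).  Raises if two genes'
    windows overlap with contradictory levels.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_win = 2 * span // window
    oracle = np.empty((len(genes), n_win))
    rows = []
    covered: dict[tuple[str, int, int], float] = {}
    for t, g in enumerate(genes):
        for k in range(n_win):
            gstart = g.tss - span + k * window
            gend = gstart + window
            level = float(constant) if constant is not None else float(level_sd * rng.standard_normal())
            key = (g.chrom, gstart, gend)
            if key in covered:
                level = covered[key]  # window shared between genes: one level
            # transcription-direction column: + strand keeps genomic order,
            # - strand reverses it
            col = k if g.strand == "+" else n_win - 1 - k
            oracle[t, col] = level
            if key not in covered:
                covered[key] = level
                rows.append((g.chrom, gstart, gend, level))
    rows.sort(key=lambda r: (r[0], r[1]))
    # identical windows were deduplicated above, so any remaining overlap is
    # partial and would corrupt the window averages
    prev_end: dict[str, int] = {}
    for chrom, s, e, _ in rows:
        if chrom in prev_end and s < prev_end[chrom]:
            raise ValueError(
                f"overlapping contradictory intervals near {chrom}:{s}")
        prev_end[chrom] = max(prev_end.get(chrom, 0), e)
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return track, oracle


@dataclass
class SyntheticDataset:
    genes: list[GeneRecord]
    predictors: FeatureMatrix
    true_states: np.ndarray
    annotations: pd.DataFrame
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        T = len(self.genes)
        if not (self.predictors.n_genes == len(self.true_states) == len(self.annotations) == T):
            raise ValueError("component lengths disagree")
        M = self.spec.n_states
        if np.any((self.true_states < 1) | (self.true_states > M)):
            raise ValueError("true_states out of range 1..M")

    @property
    def expression(self) -> np.ndarray:
        return np.array([g.expression for g in self.genes])

    @property
    def distances(self) -> np.ndarray:
        from .core import distances_from_genes

        return distances_from_genes(self.genes)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full dataset: positions, hidden path, predictors, expression,
    annotations — all from one seeded stream, bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    genes = gen_positions(
        spec.n_genes, spec.distance_law,
        seed=int(rng.integers(2**31 - 1)), chrom=spec.chrom,
    )
    from .core import distances_from_genes

    d = distances_from_genes(genes)
    states = gen_state_path(
        d, spec.baseline_transitions, spec.distance_constant, spec.pi,
        rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
    )
    fm = gen_predictors(states, spec, rng=np.random.default_rng(int(rng.integers(2**31 - 1))))
    fm.gene_ids = [g.accession for g in genes]
    y = gen_expression(fm, states, spec.betas, spec.sigmas,
                       rng=np.random.default_rng(int(rng.integers(2**31 - 1))))
    for g, yi in zip(genes, y):
        g.expression = float(yi)
    ann = gen_annotations(states, spec.annotation_rates,
                          rng=np.random.default_rng(int(rng.integers(2**31 - 1))))
    ann.insert(0, "gene_id", [g.accession for g in genes])
    return SyntheticDataset(genes=genes, predictors=fm, true_states=states,
                            annotations=ann, spec=spec)


# ---------------------------------------------------------------------------
# fixture IO (round-trip exact)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write genes (BED-like, 0-based half-open), predictors, true states,
    annotations and the spec; read_fixture reproduces the dataset exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": directory / "genes.bed",
        "predictors": directory / "predictors.tsv",
        "states": directory / "true_states.tsv",
        "annotations": directory / "annotations.tsv",
        "spec": directory / "spec.yaml",
    }
    with open(paths["genes"], "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for g in dataset.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.accession}\t{g.expression!r}\t{g.strand}\n")
    with open(paths["predictors"], "w") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.predictors.column_names) + "\n")
        for gid, row in zip(dataset.predictors.gene_ids, dataset.predictors.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(paths["states"], "w") as fh:
        fh.write("gene_id\tstate\n")
        for g, s in zip(dataset.genes, dataset.true_states):
            fh.write(f"{g.accession}\t{int(s)}\n")
    dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(dataset.spec.to_dict(), fh)
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    from .io import read_gene_table, read_matrix

    directory = Path(directory)
    with open(directory / "spec.yaml") as fh:
        spec = SyntheticSpec.from_dict(yaml.safe_load(fh))
    genes = read_gene_table(directory / "genes.bed")
    fm = read_matrix(directory / "predictors.tsv")
    states = pd.read_csv(directory / "true_states.tsv", sep="\t")["state"].to_numpy()
    ann = pd.read_csv(directory / "annotations.tsv", sep="\t")
    return SyntheticDataset(genes=genes, predictors=fm, true_states=states,
                            annotations=ann, spec=spec)
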