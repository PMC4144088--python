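"""Readers/writers for the plain-text formats the pipeline exchanges.

Gene tables are BED-like TSV (chrom, start, end, name, score=expression,
strand; 0-based half-open, TSS = start).  Predictor matrices are TSV with a
``gene_id`` column and MARK_OFFSET column headers (e.g. ``H3K4me3_+500``).
Signal is bedGraph (chrom, start, end, value); masks are 3-column BED.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import FeatureMatrix, GeneRecord, format_column, parse_column


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a BED-like gene table, sort by (chrom, tss), compute dist_prev."""
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                tss = int(start)
                expr = float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneRecord(accession=name, chrom=chrom, tss=tss,
                                    strand=strand, expression=expr))
    genes.sort(key=lambda g: (g.chrom, g.tss))
    # dist_prev is None only at chromosome starts; duplicate-TSS genes (which
    # the filtering step resolves) keep a 1 bp pseudo-distance so the chain
    # stays contiguous
    prev: dict[str, int] = {}
    for g in genes:
        if g.chrom in prev:
            g.dist_prev = max(g.tss - prev[g.chrom], 1)
        else:
            g.dist_prev = None
        prev[g.chrom] = g.tss
    return genes


def write_gene_table(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.accession}\t"
                     f"{g.expression!r}\t{g.strand}\n")


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a TSV predictor matrix with MARK_OFFSET headers."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id'")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values")
    columns = [parse_column(c) for c in df.columns[1:]]
    return FeatureMatrix(values=df.iloc[:, 1:].to_numpy(dtype=float),
                         columns=columns, gene_ids=df["gene_id"].tolist())


def write_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write at full precision so read->write->read round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(fm.column_names) + "\n")
        ids = fm.gene_ids or [str(i) for i in range(fm.n_genes)]
        for gid, row in zip(ids, fm.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_mask_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None,
                       usecols=[0, 1, 2], names=["chrom", "start", "end"])


def read_annotation_labels(path: str | Path) -> pd.DataFrame:
    """TSV of gene_id plus either a binary 'value' column or a 'label' column."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default constants."""

    out_dir: str = "results/run"
    genes: Optional[str] = None
    signal: dict = field(default_factory=dict)  # mark -> bedGraph path
    features: Optional[str] = None  # precomputed matrix path
    mask: Optional[str] = None
    annotations: dict = field(default_factory=dict)  # name -> TSV path
    span: int = 1000
    window: int = 200
    D: float = 4000.0
    M_range: tuple = (1, 2, 3, 4, 5, 6)
    n_states: Optional[int] = None  # fixed M; None -> select by BIC
    restarts: int = 20
    reps: int = 1000
    alpha: float = 0.05
    kfold: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.span % self.window != 0:
            raise ValueError("span must be divisible by window")
        for name in ("span", "window", "restarts", "reps", "kfold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.D <= 0:
            raise ValueError("D must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "M_range" in data:
            data["M_range"] = tuple(data["M_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["M_range"] = list(self.M_range)
        return d

    @property
    def config_hash(self) -> str:
        # out_dir does not affect what is computed, only where it lands
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
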