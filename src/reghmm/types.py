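"""Shared containers for the regression-HMM pipeline.

States are reported 1-based ("State 1", "State 2", ...) everywhere a user sees
them; internal array indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class GeneRecord:
    """One gene: location, orientation and its expression response.

    ``dist_prev`` is the distance in bp to the previous gene on the same
    chromosome (gene order sorted by TSS); it is ``None`` for the first gene
    of each chromosome, which starts a fresh Markov chain.
    """

    accession: str
    chrom: str
    tss: int
    strand: str
    expression: float = np.nan
    dist_prev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.dist_prev is not None and self.dist_prev <= 0:
            raise ValueError(f"dist_prev must be > 0 when defined, got {self.dist_prev}")


@dataclass
class FeatureMatrix:
    """T x p predictor matrix with (mark, window-offset) column metadata.

    Columns are ordered mark-major; the offset is the window's upstream edge
    in the direction of transcription, in bp relative to the TSS (so
    offset -1000 is the most upstream window of a TSS+/-1kb span with 200 bp
    windows, +800 the most downstream). ``mask_flags`` marks entries whose
    window overlapped a masked region or ran past a chromosome end.
    """

    values: np.ndarray
    columns: list[tuple[str, int]]
    gene_ids: Optional[list[str]] = None
    mask_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.columns)} column labels"
            )
        if self.gene_ids is not None and len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match number of rows")
        if self.mask_flags is not None:
            self.mask_flags = np.asarray(self.mask_flags, dtype=bool)
            if self.mask_flags.shape != self.values.shape:
                raise ValueError("mask_flags shape must match values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [format_column(mark, off) for mark, off in self.columns]

    @property
    def marks(self) -> list[str]:
        seen: list[str] = []
        for mark, _ in self.columns:
            if mark not in seen:
                seen.append(mark)
        return seen

    def subset(self, idx: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            values=self.values[idx],
            columns=list(self.columns),
            gene_ids=[self.gene_ids[i] for i in idx] if self.gene_ids is not None else None,
            mask_flags=self.mask_flags[idx] if self.mask_flags is not None else None,
        )


def format_column(mark: str, offset: int) -> str:
    return f"{mark}_{offset:+d}"


def parse_column(name: str) -> tuple[str, int]:
    mark, _, off = name.rpartition("_")
    if not mark:
        raise ValueError(f"column name {name!r} is not of the form MARK_OFFSET")
    return mark, int(off)


@dataclass
class FilterReport:
    """Ordered record of gene-filtering steps: (name, n_removed, n_remaining)."""

    n_input: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_input
        if prev - n_removed != n_remaining:
            raise ValueError(
                f"filter counts do not telescope at {name}: "
                f"{prev} - {n_removed} != {n_remaining}"
            )
        self.steps.append((name, n_removed, n_remaining))

    @property
    def n_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [
                {"filter": n, "n_removed": r, "n_remaining": k} for n, r, k in self.steps
            ],
        }


@dataclass
class RegHMMParams:
    """Parameters of the regression HMM.

    ``baseline_transitions`` is the long-range transition matrix P = (p_ij);
    the transition actually applied between genes separated by d bp is
    A(d) = exp(-d/D) I + (1 - exp(-d/D)) P, so adjacent genes tend to share a
    state and distant genes mix according to P.
    """

    pi: np.ndarray
    baseline_transitions: np.ndarray
    distance_constant: float
    betas: np.ndarray  # M x (p+1), intercept first
    sigmas: np.ndarray  # M residual SDs

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.baseline_transitions = np.asarray(self.baseline_transitions, dtype=float)
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.pi)

    @property
    def n_predictors(self) -> int:
        return self.betas.shape[1] - 1

    def validate(self) -> None:
        M = len(self.pi)
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if self.baseline_transitions.shape != (M, M):
            raise ValueError("baseline_transitions must be M x M")
        if not np.allclose(self.baseline_transitions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of baseline_transitions must sum to 1")
        if np.any(self.baseline_transitions < -1e-12):
            raise ValueError("baseline_transitions must be non-negative")
        if self.distance_constant <= 0:
            raise ValueError("distance_constant must be > 0")
        if self.betas.shape[0] != M or self.sigmas.shape[0] != M:
            raise ValueError("betas/sigmas must have one row per state")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be > 0")

    def permuted(self, order: Sequence[int]) -> "RegHMMParams":
        """Re-index states by ``order`` (new state i is old state order[i])."""
        order = list(order)
        P = self.baseline_transitions[np.ix_(order, order)]
        return RegHMMParams(
            pi=self.pi[order],
            baseline_transitions=P,
            distance_constant=self.distance_constant,
            betas=self.betas[order],
            sigmas=self.sigmas[order],
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "baseline_transitions": self.baseline_transitions.tolist(),
            "distance_constant": self.distance_constant,
            "betas": self.betas.tolist(),
            "sigmas": self.sigmas.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegHMMParams":
        return cls(
            pi=np.array(d["pi"]),
            baseline_transitions=np.array(d["baseline_transitions"]),
            distance_constant=float(d["distance_constant"]),
            betas=np.array(d["betas"]),
            sigmas=np.array(d["sigmas"]),
        )


@dataclass
class FitResult:
    """Output of one EM fit (best restart)."""

    params: RegHMMParams
    loglik_trace: np.ndarray
    gamma: np.ndarray  # T x M posterior state probabilities
    xi_sums: np.ndarray  # M x M expected transition counts
    viterbi_path: np.ndarray  # T-vector, values in 1..M
    bic: float
    n_params: int
    converged: bool
    n_iterations: int
    seed: Optional[int] = None
    restart_logliks: Optional[np.ndarray] = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "bic": self.bic,
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "seed": self.seed,
            "viterbi_path": np.asarray(self.viterbi_path).tolist(),
        }


@dataclass
class ModelScore:
    """BIC bookkeeping for one candidate number of states."""

    n_states: int
    loglik: float
    n_params: int
    bic: float
    restart_logliks: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "restart_logliks": np.asarray(self.restart_logliks).tolist(),
        }
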