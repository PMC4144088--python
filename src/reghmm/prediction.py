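"""Held-out expression prediction.

A trained two-state model does not directly give states for new genes whose
expression is unknown.  Instead, each state's predictor profile on the
training data is summarised by a multivariate normal (sample mean x_bar_m,
sample covariance V_m) and a mixing proportion phi (the fraction of training
genes decoded into State 1).  A test gene with predictors z is assigned to
State 1 iff phi * p_1(z) > (1 - phi) * p_2(z) (ties to State 2), and its
expression predicted with the assigned state's regression.  Performance is
the R^2 of regressing the true on the predicted expression, per state and
overall, evaluated by k-fold cross-validation (default 5-fold, gene-wise
random folds; the Markov chain is rebuilt between retained neighbours
within each training set).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import fit_em, relabel_by_r2
from .state_analysis import ols_r2
from .types import FitResult, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class StateProfile:
    """Per-state training summaries used for test-gene state assignment."""

    means: np.ndarray  # M x p sample means
    covariances: np.ndarray  # M x p x p sample covariances (ridged if needed)
    phi: np.ndarray  # M mixing proportions from the training decode
    betas: np.ndarray  # M x (p+1) state regressions
    counts: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.phi)


def build_profiles(
    X_train: np.ndarray,
    state_path: np.ndarray,
    fit: FitResult,
    ridge_rel: float = 1e-6,
) -> StateProfile:
    """Sample mean/covariance of the predictors per decoded state, plus the
    state proportions and regression coefficients.

    Singular or ill-conditioned covariances are ridged by
    ``ridge_rel * trace(V)/p`` (logged).
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    states = np.asarray(state_path, dtype=int)
    M = fit.params.n_states
    p = X.shape[1]
    means = np.zeros((M, p))
    covs = np.zeros((M, p, p))
    counts = np.zeros(M, dtype=int)
    for i in range(M):
        sel = states == i + 1
        counts[i] = sel.sum()
        if counts[i] == 0:
            logger.warning("state %d has no training genes", i + 1)
            covs[i] = np.eye(p)
            continue
        means[i] = X[sel].mean(axis=0)
        if counts[i] > 1:
            V = np.cov(X[sel], rowvar=False)
        else:
            V = np.eye(p)
        V = np.atleast_2d(V)
        if counts[i] <= p or np.linalg.cond(V) > 1e10:
            ridge = ridge_rel * np.trace(V) / p
            ridge = max(ridge, 1e-8)
            V = V + ridge * np.eye(p)
            logger.info("state %d covariance ridged (+%.3g)", i + 1, ridge)
        covs[i] = V
    phi = counts / counts.sum()
    return StateProfile(means=means, covariances=covs, phi=phi,
                        betas=fit.params.betas, counts=counts)


def assign_states(X_test: np.ndarray, profiles: StateProfile) -> np.ndarray:
    """Assign each test gene to the state maximizing phi_m * p_m(z).

    Evaluated in log space.  For the two-state rule, State 1 wins only on a
    strict inequality; ties (and the general-M case) resolve to the higher
    state index, matching 'State 2 otherwise'.
    """
    X = np.atleast_2d(np.asarray(X_test, dtype=float))
    M = profiles.n_states
    if X.shape[1] != profiles.means.shape[1]:
        raise ValueError("test predictors do not match the training columns")
    scores = np.full((X.shape[0], M), -np.inf)
    for m in range(M):
        if profiles.phi[m] == 0:
            continue
        logp = stats.multivariate_normal.logpdf(
            X, mean=profiles.means[m], cov=profiles.covariances[m],
            allow_singular=True,
        )
        scores[:, m] = np.log(profiles.phi[m]) + np.atleast_1d(logp)
    # argmax over reversed columns -> ties go to the higher state index
    rev = scores[:, ::-1]
    labels = M - 1 - np.argmax(rev, axis=1)
    return labels + 1


@dataclass
class PredictionResult:
    predicted: np.ndarray
    labels: np.ndarray
    r2_by_state: dict
    r2_overall: Optional[float]

    def to_dict(self) -> dict:
        return {
            "r2_by_state": self.r2_by_state,
            "r2_overall": self.r2_overall,
            "n_by_state": {int(s): int((self.labels == s).sum())
                           for s in np.unique(self.labels)},
        }


def predict_expression(
    X_test: np.ndarray,
    labels: np.ndarray,
    profiles: StateProfile,
    y_true: Optional[np.ndarray] = None,
) -> PredictionResult:
    """Predict expression with each gene's assigned-state regression.

    When the true expression is supplied, the evaluation R^2 (true regressed
    on predicted, with intercept) is reported per assigned state and overall;
    states with no assigned genes are skipped with a note.
    """
    X = np.atleast_2d(np.asarray(X_test, dtype=float))
    labels = np.asarray(labels, dtype=int)
    betas = profiles.betas
    yhat = betas[labels - 1, 0] + np.einsum("tp,tp->t", X, betas[labels - 1, 1:])
    r2_by_state: dict = {}
    r2_overall = None
    if y_true is not None:
        y_true = np.asarray(y_true, dtype=float)
        for m in range(profiles.n_states):
            sel = labels == m + 1
            if sel.sum() < 3:
                logger.info("state %d: %d assigned genes; evaluation skipped", m + 1, sel.sum())
                r2_by_state[m + 1] = None
                continue
            r2_by_state[m + 1] = ols_r2(yhat[sel, None], y_true[sel])
        r2_overall = ols_r2(yhat[:, None], y_true)
    return PredictionResult(predicted=yhat, labels=labels,
                            r2_by_state=r2_by_state, r2_overall=r2_overall)


# ---------------------------------------------------------------------------
# k-fold evaluation


def _distances_for_subset(genes: Sequence[GeneRecord], idx: np.ndarray) -> np.ndarray:
    """Chain distances between retained neighbours, NaN at chromosome starts."""
    d = np.full(len(idx), np.nan)
    prev_chrom = None
    prev_tss = None
    for k, i in enumerate(idx):
        g = genes[i]
        if g.chrom == prev_chrom:
            d[k] = g.tss - prev_tss
            if d[k] <= 0:
                d[k] = 1.0  # duplicate TSS in a subset: treat as adjacent
        prev_chrom, prev_tss = g.chrom, g.tss
    return d


def kfold_evaluate(
    genes: Sequence[GeneRecord],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    M: int = 2,
    D: float = 4000.0,
    n_restarts: int = 5,
    seed: Optional[int] = None,
    **fit_kwargs,
) -> list[dict]:
    """Gene-wise k-fold cross-validation of the train/assign/predict cycle.

    Each fold: fit the regression HMM on the training genes (chain rebuilt
    between retained neighbours), relabel so State 1 is the stronger-
    association state, build the state profiles, assign test genes and
    predict their expression.  Returns one report dict per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    T = len(y)
    if T < 2 * k:
        raise ValueError("too few genes for the requested number of folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(T)
    folds = np.array_split(perm, k)
    reports = []
    for f, test_idx in enumerate(folds):
        test_idx = np.sort(test_idx)
        train_idx = np.sort(np.setdiff1d(perm, test_idx))
        d_train = _distances_for_subset(genes, train_idx)
        fit = fit_em(X[train_idx], y[train_idx], d_train, M, D=D,
                     n_restarts=n_restarts,
                     seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
        fit = relabel_by_r2(fit, X[train_idx], y[train_idx])
        profiles = build_profiles(X[train_idx], fit.viterbi_path, fit)
        labels = assign_states(X[test_idx], profiles)
        pred = predict_expression(X[test_idx], labels, profiles, y_true=y[test_idx])
        # single pooled regression baseline: train on all training genes
        Z_tr = np.column_stack([np.ones(len(train_idx)), X[train_idx]])
        coef, *_ = np.linalg.lstsq(Z_tr, y[train_idx], rcond=None)
        yhat_single = np.column_stack([np.ones(len(test_idx)), X[test_idx]]) @ coef
        r2_single = ols_r2(yhat_single[:, None], y[test_idx])
        train_r2 = {}
        for m in range(M):
            sel = fit.viterbi_path == m + 1
            if sel.sum() > X.shape[1] + 1:
                train_r2[m + 1] = ols_r2(X[train_idx][sel], y[train_idx][sel])
        reports.append({
            "fold": f,
            "n_train": len(train_idx),
            "n_test": len(test_idx),
            "train_r2_by_state": train_r2,
            "train_state_sizes": {m + 1: int((fit.viterbi_path == m + 1).sum())
                                  for m in range(M)},
            "test": pred.to_dict(),
            "r2_single_model": r2_single,
        })
    return reports
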