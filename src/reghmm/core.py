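"""Regression hidden Markov model with distance-dependent transitions.

The observation at gene t is O_t = (x_t, y_t): a vector of standardized
histone-modification predictors and a scalar expression response.  Given the
hidden state q_t = i the emission density is the regression likelihood

    b_i(O_t) = N(y_t ; beta_i0 + x_t . beta_i, sigma_i^2),

i.e. the marginal density of x is not modelled (p(x|q) = 1), so the states
are defined purely by the predictor/response relationship.  Genes are
unequally spaced, and the transition matrix applied between genes d bp apart
interpolates between persistence and a baseline stochastic matrix P:

    A(d) = exp(-d/D) I + (1 - exp(-d/D)) P,

with D a predetermined constant (default 4000 bp).  At d = 0 the state is
carried over with probability 1; as d grows the chain mixes according to P.

Fitting is by Baum-Welch EM with scaled forward-backward recursions and
multiple random restarts; decoding by Viterbi; the number of states is chosen
by BIC in the form  loglik - 0.5 * N_M * ln(T)  (maximized).  Each chromosome
is an independent chain restarted from the initial distribution pi.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .types import FitResult, GeneRecord, ModelScore, RegHMMParams

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# chain geometry


def distances_from_genes(genes: Sequence[GeneRecord]) -> np.ndarray:
    """Distance to the previous gene, NaN where a new chain (chromosome) starts."""
    d = np.full(len(genes), np.nan)
    for t, g in enumerate(genes):
        if g.dist_prev is not None:
            d[t] = g.dist_prev
    if len(d) and not np.isnan(d[0]):
        raise ValueError("first gene must start a chain (dist_prev undefined)")
    return d


def chain_starts(distances: np.ndarray) -> np.ndarray:
    """Boolean mask of positions that begin a new independent chain."""
    distances = np.asarray(distances, dtype=float)
    starts = np.isnan(distances)
    if len(starts) and not starts[0]:
        raise ValueError("distances[0] must be NaN (first position starts a chain)")
    return starts


# ---------------------------------------------------------------------------
# emissions and transitions


def emission_logdensity(
    X: np.ndarray, y: np.ndarray, betas: np.ndarray, sigmas: np.ndarray
) -> np.ndarray:
    """T x M matrix of log b_i(O_t) under the state-specific regressions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be > 0")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    mu = betas[:, 0][None, :] + X @ betas[:, 1:].T  # T x M
    resid = y[:, None] - mu
    return -0.5 * (_LOG2PI + 2.0 * np.log(sigmas)[None, :] + (resid / sigmas[None, :]) ** 2)


def transition_matrix(d: float, baseline_transitions: np.ndarray, D: float) -> np.ndarray:
    """A(d) = exp(-d/D) I + (1 - exp(-d/D)) P."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    P = np.asarray(baseline_transitions, dtype=float)
    e = np.exp(-d / D)
    return e * np.eye(P.shape[0]) + (1.0 - e) * P


# ---------------------------------------------------------------------------
# forward-backward (scaled)


def forward_backward(
    distances: np.ndarray,
    logB: np.ndarray,
    params: RegHMMParams,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact E-step quantities for the non-homogeneous chain.

    Returns ``(loglik, gamma, xi)`` where gamma[t, i] = P(q_t = i | O) and
    xi[t, i, j] = P(q_{t-1} = i, q_t = j | O) for every within-chain t
    (zero at chain starts).  Per-step scaling keeps the recursion stable.
    """
    logB = np.asarray(logB, dtype=float)
    if np.any(np.isnan(logB)):
        raise ValueError("NaN in emission log-densities")
    T, M = logB.shape
    distances = np.asarray(distances, dtype=float)
    if len(distances) != T:
        raise ValueError("distances length must match number of observations")
    starts = chain_starts(distances)

    # scale emissions per row to avoid under/overflow in the linear domain
    offset = logB.max(axis=1)
    B = np.exp(logB - offset[:, None])

    P = params.baseline_transitions
    D = params.distance_constant
    e = np.exp(-distances / D)  # NaN at starts, unused there
    e_safe = np.where(starts, 0.0, e)
    # all step transition matrices at once: A[t] = e_t I + (1-e_t) P
    A = e_safe[:, None, None] * np.eye(M) + (1.0 - e_safe)[:, None, None] * P

    alpha = np.empty((T, M))
    c = np.empty(T)  # scaling factors
    for t in range(T):
        if starts[t]:
            a = params.pi * B[t]
        else:
            a = (alpha[t - 1] @ A[t]) * B[t]
        ct = a.sum()
        if ct <= 0 or not np.isfinite(ct):
            raise FloatingPointError("forward recursion underflowed to zero mass")
        c[t] = ct
        alpha[t] = a / ct

    beta = np.empty((T, M))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        if starts[t + 1]:
            beta[t] = 1.0
        else:
            beta[t] = (A[t + 1] @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # xi[t] = alpha[t-1] A[t] (B[t] beta[t]) / c[t], zero at chain starts
    xi = np.zeros((T, M, M))
    within = ~starts
    within[0] = False
    w_idx = np.flatnonzero(within)
    if len(w_idx):
        xi[w_idx] = (
            alpha[w_idx - 1][:, :, None]
            * A[w_idx]
            * (B[w_idx] * beta[w_idx] / c[w_idx, None])[:, None, :]
        )

    loglik = float(np.sum(np.log(c)) + np.sum(offset))
    return loglik, gamma, xi


# ---------------------------------------------------------------------------
# M-step


def _weighted_regression(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Solve the weighted least squares normal equations, ridging if singular."""
    A = Z.T @ (Z * w[:, None])
    b = Z.T @ (w * y)
    if ridge > 0:
        A = A + ridge * np.eye(A.shape[0])
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def m_step(
    X: np.ndarray,
    y: np.ndarray,
    gamma: np.ndarray,
    xi: np.ndarray,
    distances: np.ndarray,
    params: RegHMMParams,
    update_pi: bool = True,
) -> RegHMMParams:
    """Maximize the expected complete-data log-likelihood.

    Regression coefficients are gamma-weighted least squares, variances the
    gamma-weighted mean squared residual (floored at SIGMA2_FLOOR), pi the
    normalized posterior at chain starts.  The baseline matrix P enters the
    transition A(d) = e I + (1-e) P only through a mixture, so its update
    uses a nested EM step: conditional on a (q_{t-1}=i, q_t=j) transition,
    the probability it was generated by the P branch rather than the
    carry-over branch is 1 for i != j and (1-e)p_ii / (e + (1-e)p_ii) for
    i = j; P is re-estimated from those reweighted expected counts.  This is
    a generalized EM update, so the likelihood still never decreases.
    """
    gamma = np.asarray(gamma, dtype=float)
    T, M = gamma.shape
    Z = np.column_stack([np.ones(T), np.atleast_2d(X)])
    starts = chain_starts(distances)

    betas = np.empty((M, Z.shape[1]))
    sigmas = np.empty(M)
    for i in range(M):
        w = gamma[:, i]
        tot = w.sum()
        ridge = 0.0
        if tot < Z.shape[1]:
            ridge = 1e-8 * max(tot, 1.0)
            logger.debug("state %d near-degenerate (weight %.3g); ridge-stabilized", i, tot)
        betas[i] = _weighted_regression(Z, y, w, ridge=ridge)
        resid = y - Z @ betas[i]
        sigma2 = float(w @ resid**2) / max(tot, 1e-300)
        if sigma2 < SIGMA2_FLOOR:
            logger.debug("state %d variance floored (%.3g)", i, sigma2)
            sigma2 = SIGMA2_FLOOR
        sigmas[i] = np.sqrt(sigma2)

    if update_pi and starts.any():
        pi = gamma[starts].sum(axis=0)
        pi = pi / pi.sum()
    else:
        pi = params.pi.copy()

    P_old = params.baseline_transitions
    e = np.exp(-np.asarray(distances, dtype=float) / params.distance_constant)
    within = ~starts
    within[0] = False
    w_idx = np.flatnonzero(within)
    num = xi[w_idx].sum(axis=0)  # off-diagonal transitions always come from P
    diag_xi = np.einsum("tii->ti", xi[w_idx])
    pd = np.diag(P_old)
    denom = e[w_idx, None] + (1.0 - e[w_idx, None]) * pd[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        diag_w = np.where(denom > 0, (1.0 - e[w_idx, None]) * pd[None, :] / denom, 0.0)
    np.fill_diagonal(num, np.einsum("ti,ti->i", diag_xi, diag_w))
    row = num.sum(axis=1, keepdims=True)
    P_new = np.where(row > 1e-300, num / np.where(row > 0, row, 1.0), P_old)
    P_new = P_new / P_new.sum(axis=1, keepdims=True)

    return RegHMMParams(
        pi=pi,
        baseline_transitions=P_new,
        distance_constant=params.distance_constant,
        betas=betas,
        sigmas=sigmas,
    )


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(
    distances: np.ndarray, logB: np.ndarray, params: RegHMMParams
) -> np.ndarray:
    """Most probable state path (1-based labels); ties go to the lower index."""
    logB = np.asarray(logB, dtype=float)
    T, M = logB.shape
    starts = chain_starts(distances)
    e = np.exp(-np.asarray(distances, dtype=float) / params.distance_constant)
    P = params.baseline_transitions
    eye = np.eye(M)

    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)

    delta = np.empty((T, M))
    back = np.zeros((T, M), dtype=int)
    for t in range(T):
        if starts[t]:
            delta[t] = log_pi + logB[t]
        else:
            with np.errstate(divide="ignore"):
                logA = np.log(e[t] * eye + (1.0 - e[t]) * P)
            cand = delta[t - 1][:, None] + logA  # prev x next
            back[t] = np.argmax(cand, axis=0)  # first max -> lower index on ties
            delta[t] = cand[back[t], np.arange(M)] + logB[t]

    path = np.empty(T, dtype=int)
    # decode each chain backwards from its last position
    boundaries = list(np.flatnonzero(starts)) + [T]
    for s, nxt in zip(boundaries[:-1], boundaries[1:]):
        path[nxt - 1] = int(np.argmax(delta[nxt - 1]))
        for t in range(nxt - 1, s, -1):
            path[t - 1] = back[t, path[t]]
    return path + 1


# ---------------------------------------------------------------------------
# BIC


def n_free_params(M: int, p: int) -> int:
    """Free parameters: M(p+1) coefficients, M variances, M(M-1) baseline
    transition entries, M-1 initial probabilities."""
    return M * (p + 1) + M + M * (M - 1) + (M - 1)


def bic(loglik: float, n_params: int, T: int) -> float:
    """loglik - 0.5 * N ln(T); larger is better."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return float(loglik) - 0.5 * n_params * np.log(T)


# ---------------------------------------------------------------------------
# EM driver


def _init_params(
    X: np.ndarray,
    y: np.ndarray,
    M: int,
    D: float,
    rng: np.random.Generator,
    strategy: str = "random_states",
    p_stay: float = 0.5,
) -> RegHMMParams:
    T, p = X.shape
    if strategy == "random_states":
        labels = rng.integers(0, M, size=T)
    elif strategy == "quantile":
        ranks = np.argsort(np.argsort(y))
        labels = np.minimum((ranks * M) // T, M - 1)
    else:
        raise ValueError(f"unknown init strategy {strategy!r}")

    Z = np.column_stack([np.ones(T), X])
    betas = np.empty((M, p + 1))
    sigmas = np.empty(M)
    for i in range(M):
        sel = labels == i
        if sel.sum() <= p + 1:
            sel = np.ones(T, dtype=bool)  # too few: fall back to pooled fit
        coef, *_ = np.linalg.lstsq(Z[sel], y[sel], rcond=None)
        betas[i] = coef
        resid = y[sel] - Z[sel] @ coef
        sigmas[i] = max(np.std(resid), 1e-3) * (1.0 + 0.1 * rng.standard_normal())
        sigmas[i] = abs(sigmas[i]) + 1e-3

    if M == 1:
        P = np.array([[1.0]])
    else:
        P = np.full((M, M), (1.0 - p_stay) / (M - 1))
        np.fill_diagonal(P, p_stay)
    return RegHMMParams(
        pi=np.full(M, 1.0 / M),
        baseline_transitions=P,
        distance_constant=D,
        betas=betas,
        sigmas=sigmas,
    )


def _em_single(
    X: np.ndarray,
    y: np.ndarray,
    distances: np.ndarray,
    init: RegHMMParams,
    tol: float,
    max_iter: int,
) -> tuple[RegHMMParams, list[float], np.ndarray, np.ndarray, bool, int]:
    params = init
    trace: list[float] = []
    gamma = xi = None
    converged = False
    for it in range(max_iter):
        logB = emission_logdensity(X, y, params.betas, params.sigmas)
        loglik, gamma, xi = forward_backward(distances, logB, params)
        trace.append(loglik)
        if len(trace) > 1:
            prev = trace[-2]
            rel = abs(loglik - prev) / max(abs(prev), 1.0)
            if rel < tol:
                converged = True
                break
        params = m_step(X, y, gamma, xi, distances, params)
    return params, trace, gamma, xi, converged, len(trace)


def fit_em(
    X: np.ndarray,
    y: np.ndarray,
    distances: np.ndarray,
    M: int,
    D: float = 4000.0,
    n_restarts: int = 20,
    init_strategy: str = "random_states",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
) -> FitResult:
    """Fit an M-state regression HMM by Baum-Welch EM with multiple restarts.

    Each restart draws an independent random initialization; the restart with
    the highest final log-likelihood is returned.  Within every restart the
    log-likelihood is non-decreasing (up to numerical tolerance).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    distances = np.asarray(distances, dtype=float)
    T, p = X.shape
    if M < 1:
        raise ValueError("M must be >= 1")
    if T <= p:
        raise ValueError(f"need more observations than predictors (T={T}, p={p})")
    if len(y) != T or len(distances) != T:
        raise ValueError("X, y and distances must have matching lengths")

    rng = np.random.default_rng(seed)
    best: Optional[tuple] = None
    restart_logliks = np.full(n_restarts, -np.inf)
    n_failed = 0
    for r in range(n_restarts):
        init = _init_params(X, y, M, D, rng, strategy=init_strategy)
        try:
            out = _em_single(X, y, distances, init, tol, max_iter)
        except FloatingPointError as exc:
            logger.warning("restart %d failed: %s", r, exc)
            n_failed += 1
            continue
        restart_logliks[r] = out[1][-1]
        if best is None or out[1][-1] > best[1][-1]:
            best = out
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts degenerated (forward underflow); "
            "check the predictors for collinearity or scale"
        )

    params, trace, gamma, xi, converged, n_iter = best
    logB = emission_logdensity(X, y, params.betas, params.sigmas)
    path = viterbi(distances, logB, params)
    N = n_free_params(M, p)
    return FitResult(
        params=params,
        loglik_trace=np.array(trace),
        gamma=gamma,
        xi_sums=xi.sum(axis=0),
        viterbi_path=path,
        bic=bic(trace[-1], N, T),
        n_params=N,
        converged=converged,
        n_iterations=n_iter,
        seed=seed,
        restart_logliks=restart_logliks,
    )


def loglik_at(
    X: np.ndarray, y: np.ndarray, distances: np.ndarray, params: RegHMMParams
) -> float:
    """Marginal log-likelihood of the data at fixed parameters."""
    logB = emission_logdensity(X, y, params.betas, params.sigmas)
    return forward_backward(distances, logB, params)[0]


def select_num_states(
    X: np.ndarray,
    y: np.ndarray,
    distances: np.ndarray,
    M_range: Sequence[int],
    D: float = 4000.0,
    n_restarts: int = 20,
    seed: Optional[int] = None,
    **fit_kwargs,
) -> tuple[int, list[ModelScore]]:
    """Fit every candidate M and pick the BIC maximizer."""
    if len(M_range) == 0:
        raise ValueError("M_range must be nonempty")
    rng = np.random.default_rng(seed)
    scores: list[ModelScore] = []
    for M in M_range:
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            fit = fit_em(X, y, distances, M, D=D, n_restarts=n_restarts, seed=sub, **fit_kwargs)
        except Exception as exc:  # keep scoring the other candidates
            logger.warning("fit with M=%d failed: %s", M, exc)
            continue
        scores.append(
            ModelScore(
                n_states=M,
                loglik=fit.loglik,
                n_params=fit.n_params,
                bic=fit.bic,
                restart_logliks=fit.restart_logliks,
            )
        )
    if not scores:
        raise RuntimeError("every candidate state count failed to fit")
    best = max(scores, key=lambda s: s.bic)
    return best.n_states, scores


# ---------------------------------------------------------------------------
# no-Markov baseline: independent mixture of regressions


def fit_mixture_no_markov(
    X: np.ndarray,
    y: np.ndarray,
    M: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
) -> FitResult:
    """EM for a mixture of linear regressions with i.i.d. component labels.

    The comparison model: identical emissions, but mixing weights replace the
    Markov transition structure.  Its BIC is directly comparable with the
    regression HMM's (free parameters: M(p+1) coefficients, M variances,
    M-1 mixing weights).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    T, p = X.shape
    if T <= p:
        raise ValueError(f"need more observations than predictors (T={T}, p={p})")
    Z = np.column_stack([np.ones(T), X])
    rng = np.random.default_rng(seed)

    best = None
    restart_logliks = np.full(n_restarts, -np.inf)
    for r in range(n_restarts):
        init = _init_params(X, y, M, 1.0, rng)
        betas, sigmas = init.betas.copy(), init.sigmas.copy()
        w = np.full(M, 1.0 / M)
        trace: list[float] = []
        gamma = None
        converged = False
        for it in range(max_iter):
            logB = emission_logdensity(X, y, betas, sigmas)
            with np.errstate(divide="ignore"):
                logw = np.log(w)
            lj = logB + logw[None, :]
            mx = lj.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(lj - mx).sum(axis=1))
            loglik = float(lse.sum())
            gamma = np.exp(lj - lse[:, None])
            trace.append(loglik)
            if len(trace) > 1 and abs(loglik - trace[-2]) / max(abs(trace[-2]), 1.0) < tol:
                converged = True
                break
            w = gamma.mean(axis=0)
            for i in range(M):
                g = gamma[:, i]
                betas[i] = _weighted_regression(Z, y, g, ridge=0.0 if g.sum() > p + 1 else 1e-8)
                resid = y - Z @ betas[i]
                sigmas[i] = np.sqrt(max(float(g @ resid**2) / max(g.sum(), 1e-300), SIGMA2_FLOOR))
        restart_logliks[r] = trace[-1]
        if best is None or trace[-1] > best[0][-1]:
            best = (trace, betas.copy(), sigmas.copy(), w.copy(), gamma, converged, len(trace))

    trace, betas, sigmas, w, gamma, converged, n_iter = best
    N = M * (p + 1) + M + (M - 1)
    params = RegHMMParams(
        pi=w,
        baseline_transitions=np.tile(w, (M, 1)),
        distance_constant=1.0,
        betas=betas,
        sigmas=sigmas,
    )
    return FitResult(
        params=params,
        loglik_trace=np.array(trace),
        gamma=gamma,
        xi_sums=np.zeros((M, M)),
        viterbi_path=np.argmax(gamma, axis=1) + 1,
        bic=bic(trace[-1], N, T),
        n_params=N,
        converged=converged,
        n_iterations=n_iter,
        seed=seed,
        restart_logliks=restart_logliks,
    )


# ---------------------------------------------------------------------------
# reporting convention


def relabel_by_r2(fit: FitResult, X: np.ndarray, y: np.ndarray) -> FitResult:
    """Reorder states by descending within-state R-squared of the decoded fit,
    so "State 1" is always the stronger-association state in reports."""
    M = fit.params.n_states
    if M == 1:
        return fit
    r2 = np.full(M, -np.inf)
    Z = np.column_stack([np.ones(len(y)), np.atleast_2d(X)])
    for i in range(M):
        sel = fit.viterbi_path == i + 1
        if sel.sum() > Z.shape[1]:
            coef, *_ = np.linalg.lstsq(Z[sel], y[sel], rcond=None)
            resid = y[sel] - Z[sel] @ coef
            sst = np.sum((y[sel] - y[sel].mean()) ** 2)
            r2[i] = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
    order = list(np.argsort(-r2, kind="stable"))
    inv = np.empty(M, dtype=int)
    for new, old in enumerate(order):
        inv[old] = new
    return FitResult(
        params=fit.params.permuted(order),
        loglik_trace=fit.loglik_trace,
        gamma=fit.gamma[:, order],
        xi_sums=fit.xi_sums[np.ix_(order, order)],
        viterbi_path=inv[fit.viterbi_path - 1] + 1,
        bic=fit.bic,
        n_params=fit.n_params,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        seed=fit.seed,
        restart_logliks=fit.restart_logliks,
    )
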