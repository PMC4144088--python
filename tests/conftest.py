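"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from reghmm import core, synthetic
from reghmm.types import RegHMMParams


def enumerate_paths_loglik(
    distances: np.ndarray, logB: np.ndarray, params: RegHMMParams
) -> tuple[float, np.ndarray, float]:
    """Brute-force oracle: sum and argmax over all M^T state paths.

    Returns (log marginal likelihood, best path 1-based, best path joint
    log-probability).  Independent of the forward-backward/Viterbi code:
    the joint probability of each path is assembled term by term.
    """
    T, M = logB.shape
    starts = np.isnan(np.asarray(distances, dtype=float))
    paths = np.indices((M,) * T).reshape(T, -1).T  # M^T x T
    logp = np.zeros(paths.shape[0])
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    for t in range(T):
        logp += logB[t, paths[:, t]]
        if starts[t]:
            logp += log_pi[paths[:, t]]
        else:
            A = core.transition_matrix(distances[t], params.baseline_transitions,
                                       params.distance_constant)
            with np.errstate(divide="ignore"):
                logp += np.log(A[paths[:, t - 1], paths[:, t]])
    mx = logp.max()
    marginal = mx + np.log(np.exp(logp - mx).sum())
    best = int(np.argmax(logp))
    return float(marginal), paths[best] + 1, float(logp[best])


def random_instance(rng: np.random.Generator, T_max: int = 8, M_max: int = 3):
    """Small random regression-HMM instance for oracle comparisons."""
    T = int(rng.integers(1, T_max + 1))
    M = int(rng.integers(1, M_max + 1))
    p = int(rng.integers(1, 4))
    X = rng.standard_normal((T, p))
    y = rng.standard_normal(T)
    d = np.concatenate([[np.nan], 10 ** rng.uniform(1, 5, size=T - 1)])
    if T > 4 and rng.random() < 0.3:
        d[int(rng.integers(2, T))] = np.nan  # second chain
    pi = rng.dirichlet(np.ones(M))
    P = rng.dirichlet(np.ones(M), size=M)
    params = RegHMMParams(
        pi=pi, baseline_transitions=P, distance_constant=float(10 ** rng.uniform(2, 4)),
        betas=rng.standard_normal((M, p + 1)), sigmas=rng.uniform(0.3, 2.0, M),
    )
    return X, y, d, params


@pytest.fixture(scope="session")
def recovery_dataset():
    """One well-separated two-state dataset at moderate size."""
    spec = synthetic.make_recovery_spec(n_genes=800, seed=11)
    return synthetic.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Small study-conditions dataset for fast integration tests."""
    spec = synthetic.make_two_state_spec(n_genes=150, seed=5)
    return synthetic.generate_dataset(spec)
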