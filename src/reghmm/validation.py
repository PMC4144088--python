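"""Validation experiments: the package checking its own statistical machinery.

Each function runs a self-contained experiment against an independent oracle
(path enumeration, known simulation truth, analytic limits, printed
contingency totals) and returns plain numbers.  They are used by the
acceptance suite and the reproduction script; sizes are chosen so the whole
battery runs on a laptop in minutes.
"""
from __future__ import annotations

import itertools
from typing import Optional

import numpy as np
from scipy import stats

from . import core, synthetic
from .state_analysis import enrichment_test, r2_difference_simtest
from .types import RegHMMParams


def _enumerate_loglik(distances, logB, params):
    """Brute-force marginal log-likelihood and best path over all M^T paths."""
    T, M = logB.shape
    starts = np.isnan(np.asarray(distances, dtype=float))
    paths = np.indices((M,) * T).reshape(T, -1).T
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
    return float(mx + np.log(np.exp(logp - mx).sum())), float(mx)


def _random_instance(rng, T_max=8, M_max=3):
    T = int(rng.integers(1, T_max + 1))
    M = int(rng.integers(1, M_max + 1))
    p = int(rng.integers(1, 4))
    X = rng.standard_normal((T, p))
    y = rng.standard_normal(T)
    d = np.concatenate([[np.nan], 10 ** rng.uniform(1, 5, size=T - 1)])
    params = RegHMMParams(
        pi=rng.dirichlet(np.ones(M)),
        baseline_transitions=rng.dirichlet(np.ones(M), size=M),
        distance_constant=float(10 ** rng.uniform(2, 4)),
        betas=rng.standard_normal((M, p + 1)),
        sigmas=rng.uniform(0.3, 2.0, M),
    )
    return X, y, d, params


def oracle_comparison(n_instances: int = 200, seed: int = 0) -> dict:
    """Forward-backward and Viterbi against path enumeration (T<=8, M<=3)."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    viterbi_gap = 0.0
    for _ in range(n_instances):
        X, y, d, params = _random_instance(rng)
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        ll, _, _ = core.forward_backward(d, logB, params)
        oracle_ll, oracle_best = _enumerate_loglik(d, logB, params)
        max_diff = max(max_diff, abs(ll - oracle_ll))
        path0 = core.viterbi(d, logB, params) - 1
        starts = np.isnan(d)
        lp = 0.0
        for t in range(len(path0)):
            lp += logB[t, path0[t]]
            if starts[t]:
                lp += np.log(params.pi[path0[t]])
            else:
                A = core.transition_matrix(d[t], params.baseline_transitions,
                                           params.distance_constant)
                lp += np.log(A[path0[t - 1], path0[t]])
        viterbi_gap = max(viterbi_gap, oracle_best - lp)
    return {"n": n_instances, "max_abs_loglik_diff": max_diff,
            "max_viterbi_logprob_gap": viterbi_gap}


def em_monotonicity(n_fits: int = 50, seed: int = 0, T: int = 300) -> dict:
    """Minimum per-iteration log-likelihood increment over random fits."""
    rng = np.random.default_rng(seed)
    worst = np.inf
    for _ in range(n_fits):
        M = int(rng.integers(1, 4))
        spec = synthetic.make_recovery_spec(n_genes=T, seed=int(rng.integers(2**31 - 1)))
        ds = synthetic.generate_dataset(spec)
        fit = core.fit_em(ds.predictors.values, ds.expression, ds.distances, M,
                          n_restarts=1, max_iter=100,
                          seed=int(rng.integers(2**31 - 1)))
        inc = np.diff(fit.loglik_trace)
        if len(inc):
            worst = min(worst, float(inc.min()))
    return {"n": n_fits, "min_loglik_increment": worst}


def recovery_experiment(n_reps: int = 10, seed: int = 0, n_genes: int = 2000,
                        n_restarts: int = 5) -> dict:
    """Coefficient RMSE and Viterbi agreement on well-separated 2-state data."""
    rng = np.random.default_rng(seed)
    rmses, agrees = [], []
    for _ in range(n_reps):
        spec = synthetic.make_recovery_spec(n_genes=n_genes,
                                            seed=int(rng.integers(2**31 - 1)))
        ds = synthetic.generate_dataset(spec)
        fit = core.fit_em(ds.predictors.values, ds.expression, ds.distances, 2,
                          n_restarts=n_restarts, seed=int(rng.integers(2**31 - 1)))
        fit = core.relabel_by_r2(fit, ds.predictors.values, ds.expression)
        rmses.append(float(np.sqrt(np.mean((fit.params.betas - spec.betas) ** 2))))
        a = float(np.mean(fit.viterbi_path == ds.true_states))
        agrees.append(max(a, 1.0 - a))
    rmses, agrees = np.array(rmses), np.array(agrees)
    return {
        "n": n_reps,
        "rmse": rmses.tolist(),
        "agreement": agrees.tolist(),
        "median_rmse": float(np.median(rmses)),
        "median_agreement": float(np.median(agrees)),
        "n_pass": int(np.sum((rmses < 0.1) & (agrees > 0.85))),
    }


def bic_selection_experiment(n_reps: int = 10, seed: int = 0,
                             n_genes: int = 2000, n_restarts: int = 4,
                             max_iter: int = 120) -> dict:
    """How often BIC picks the generating number of states.

    Overfitted candidates (M above the truth) crawl along a nearly flat
    likelihood; the iteration cap trims that tail, which moves their BIC by
    far less than the parameter penalty separating the candidates.
    """
    rng = np.random.default_rng(seed)
    picked_on_two, picked_on_one = [], []
    for _ in range(n_reps):
        spec2 = synthetic.make_recovery_spec(n_genes=n_genes,
                                             seed=int(rng.integers(2**31 - 1)))
        ds2 = synthetic.generate_dataset(spec2)
        M2, _ = core.select_num_states(ds2.predictors.values, ds2.expression,
                                       ds2.distances, [1, 2, 3],
                                       n_restarts=n_restarts, max_iter=max_iter,
                                       seed=int(rng.integers(2**31 - 1)))
        picked_on_two.append(M2)
        spec1 = synthetic.make_one_state_spec(n_genes=n_genes,
                                              seed=int(rng.integers(2**31 - 1)))
        ds1 = synthetic.generate_dataset(spec1)
        M1, _ = core.select_num_states(ds1.predictors.values, ds1.expression,
                                       ds1.distances, [1, 2, 3],
                                       n_restarts=n_restarts, max_iter=max_iter,
                                       seed=int(rng.integers(2**31 - 1)))
        picked_on_one.append(M1)
    return {
        "n": n_reps,
        "picked_on_two_state_data": picked_on_two,
        "picked_on_one_state_data": picked_on_one,
        "n_correct_two": int(sum(m == 2 for m in picked_on_two)),
        "n_correct_one": int(sum(m == 1 for m in picked_on_one)),
    }


def markov_advantage_experiment(n_reps: int = 10, seed: int = 0,
                                n_genes: int = 2000, n_restarts: int = 3) -> dict:
    """BIC of the regHMM vs the order-free mixture on persistent data."""
    rng = np.random.default_rng(seed)
    advantages = []
    for _ in range(n_reps):
        spec = synthetic.make_recovery_spec(n_genes=n_genes,
                                            seed=int(rng.integers(2**31 - 1)))
        ds = synthetic.generate_dataset(spec)
        X, y, d = ds.predictors.values, ds.expression, ds.distances
        hmm = core.fit_em(X, y, d, 2, n_restarts=n_restarts,
                          seed=int(rng.integers(2**31 - 1)))
        mix = core.fit_mixture_no_markov(X, y, 2, n_restarts=n_restarts,
                                         seed=int(rng.integers(2**31 - 1)))
        advantages.append(float(hmm.bic - mix.bic))
    advantages = np.array(advantages)
    return {"n": n_reps, "bic_advantage": advantages.tolist(),
            "n_hmm_wins": int(np.sum(advantages > 0))}


def enrichment_dialect_check() -> dict:
    """Yates chi-square on the printed housekeeping/TATA/CpG state tables.

    The inputs are the published per-state totals (states of sizes 10211 and
    6809; 192/239 housekeeping, 1200/629 TATA-containing, 6057/4758
    CpG-overlapping genes).
    """
    hk = enrichment_test([[192, 10211 - 192], [239, 6809 - 239]])
    tata = enrichment_test([[1200, 10211 - 1200], [629, 6809 - 629]])
    cpg = enrichment_test([[6057, 10211 - 6057], [4758, 6809 - 4758]])
    return {"housekeeping_p": hk.pvalue, "tata_p": tata.pvalue, "cpg_p": cpg.pvalue}


def calibration_experiment(n_meta: int = 200, seed: int = 0, n_inner: int = 1000,
                           n_genes: int = 140, p: int = 5) -> dict:
    """Null calibration of the R^2-difference resampling test.

    Genes from one homogeneous regression population are split into two
    arbitrary groups; the resulting p-values should be uniform.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_meta)
    for m in range(n_meta):
        X = rng.standard_normal((n_genes, p))
        beta = rng.standard_normal(p)
        y = X @ beta + rng.standard_normal(n_genes)
        perm = rng.permutation(n_genes)
        res = r2_difference_simtest(perm[: n_genes // 2], perm[n_genes // 2:],
                                    X, y, n_reps=n_inner,
                                    seed=int(rng.integers(2**31 - 1)))
        pvals[m] = res.pvalue
    ks = stats.kstest(pvals, "uniform")
    return {"n": n_meta, "ks_pvalue": float(ks.pvalue),
            "mean_p": float(pvals.mean())}


def transition_limit_check(M: int = 3, seed: int = 0) -> dict:
    """Analytic limits of the distance kernel and monotonicity in D."""
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.ones(M), size=M)
    err_identity = float(np.abs(core.transition_matrix(0.0, P, 4000) - np.eye(M)).max())
    err_baseline = float(np.abs(core.transition_matrix(1e12, P, 4000) - P).max())
    Ds = np.linspace(100, 100_000, 50)
    diags = np.array([np.diag(core.transition_matrix(4000.0, P, D)) for D in Ds])
    monotone = bool(np.all(np.diff(diags, axis=0) > -1e-15))
    return {"identity_error": err_identity, "baseline_error": err_baseline,
            "self_transition_monotone_in_D": monotone}
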