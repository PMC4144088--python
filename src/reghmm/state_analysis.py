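"""Downstream characterization of the decoded regulatory states.

Given a decoded state path, these routines quantify how the states differ:
per-state regressions and R^2 (with the pooled-fit and combined-fit
comparisons), signed per-variable R^2, Bonferroni-corrected comparisons of
predictor means and regression coefficients across states, 2x2 enrichment
tests of binary gene labels (CpG island, TATA, housekeeping, ...), the
effect of adding a binary covariate to the state regressions, and two
resampling tests on R^2 (difference between two gene groups; extremity of a
gene subset against random same-size subsets).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class StateRegression:
    state: int | str
    n: int
    r_squared: float
    intercept: float
    coefficients: np.ndarray  # including intercept, intercept first
    std_errors: np.ndarray
    residual_variance: float

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "n": self.n,
            "r_squared": self.r_squared,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "std_errors": np.asarray(self.std_errors).tolist(),
            "residual_variance": self.residual_variance,
        }


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2, rows = states, cols = (label present, absent)
    statistic: float
    pvalue: float
    method: str
    proportions: np.ndarray  # per-state label proportion
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "table": np.asarray(self.table).tolist(),
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "method": self.method,
            "proportions": np.asarray(self.proportions).tolist(),
            "warning": self.warning,
        }


@dataclass
class SimTestResult:
    observed: float
    n_reps: int
    count: int
    pvalue: float
    seed: Optional[int]
    null_min: float
    null_max: float
    group_sizes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_reps": self.n_reps,
            "count": self.count,
            "pvalue": self.pvalue,
            "seed": self.seed,
            "null_min": self.null_min,
            "null_max": self.null_max,
            "group_sizes": list(self.group_sizes),
        }


# ---------------------------------------------------------------------------
# regression helpers


def _ols(X: np.ndarray, y: np.ndarray):
    Z = sm.add_constant(np.atleast_2d(X), has_constant="add")
    return sm.OLS(y, Z).fit()


def ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Plain OLS coefficient of determination."""
    Z = np.column_stack([np.ones(len(y)), np.atleast_2d(X)])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    sst = np.sum((y - y.mean()) ** 2)
    return 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0


def per_state_ols(
    X: np.ndarray, y: np.ndarray, state_path: np.ndarray
) -> tuple[list[StateRegression], float, float]:
    """Per-state OLS plus the two headline comparisons.

    Returns (fits, combined_r2, all_r2): ``combined_r2`` is the R^2 of
    regressing y on the concatenated per-state fitted values — how much the
    two-relationship description explains overall — and ``all_r2`` is a
    single regression on the pooled data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    states = np.asarray(state_path, dtype=int)
    p = X.shape[1]
    fits: list[StateRegression] = []
    yhat = np.full(len(y), np.nan)
    for s in np.unique(states):
        sel = states == s
        n = int(sel.sum())
        if n <= p + 1:
            logger.warning("state %s has only %d genes (p=%d); left unfit", s, n, p)
            fits.append(StateRegression(state=int(s), n=n, r_squared=np.nan,
                                        intercept=np.nan,
                                        coefficients=np.full(p + 1, np.nan),
                                        std_errors=np.full(p + 1, np.nan),
                                        residual_variance=np.nan))
            continue
        res = _ols(X[sel], y[sel])
        fits.append(StateRegression(
            state=int(s), n=n, r_squared=float(res.rsquared),
            intercept=float(res.params[0]),
            coefficients=np.asarray(res.params),
            std_errors=np.asarray(res.bse),
            residual_variance=float(res.mse_resid),
        ))
        yhat[sel] = res.fittedvalues
    ok = ~np.isnan(yhat)
    combined_r2 = ols_r2(yhat[ok, None], y[ok]) if ok.any() else np.nan
    all_r2 = ols_r2(X, y)
    return fits, combined_r2, all_r2


def signed_r2_per_variable(
    X: np.ndarray, y: np.ndarray, state_path: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Univariate R^2 of y on each predictor, signed by the slope.

    Equals (Pearson correlation)^2 times its sign.  Computed per state when
    a state path is given, plus an 'all' row for the pooled data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups: dict[str, np.ndarray] = {"all": np.ones(len(y), dtype=bool)}
    if state_path is not None:
        for s in np.unique(state_path):
            groups[f"state_{int(s)}"] = np.asarray(state_path) == s
    rows = {}
    for name, sel in groups.items():
        vals = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            xj = X[sel, j]
            if np.std(xj) == 0 or np.std(y[sel]) == 0:
                warnings.warn(f"zero-variance predictor {j} in group {name}")
                vals[j] = 0.0
            else:
                r = np.corrcoef(xj, y[sel])[0, 1]
                vals[j] = r * r * np.sign(r)
        rows[name] = vals
    return pd.DataFrame(rows).T


def compare_state_means(
    X: np.ndarray,
    state_path: np.ndarray,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
    states: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Welch two-sample t-test of each predictor's mean between two states,
    significant at the Bonferroni level alpha/n_tests."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sel1 = np.asarray(state_path) == states[0]
    sel2 = np.asarray(state_path) == states[1]
    if sel1.sum() < 2 or sel2.sum() < 2:
        raise ValueError("need at least 2 genes per state")
    if n_tests is None:
        n_tests = X.shape[1]
    rows = []
    for j in range(X.shape[1]):
        a, b = X[sel1, j], X[sel2, j]
        if np.var(a) == 0 and np.var(b) == 0:
            rows.append((j, a.mean(), b.mean(), np.nan, np.nan, False, True))
            continue
        t, pv = stats.ttest_ind(a, b, equal_var=False)
        rows.append((j, a.mean(), b.mean(), t, pv, pv < alpha / n_tests, False))
    return pd.DataFrame(
        rows,
        columns=["variable", "mean_1", "mean_2", "t", "pvalue", "significant", "degenerate"],
    )


def compare_state_coefficients(
    fit1: StateRegression, fit2: StateRegression, alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Z-test on each coefficient difference between two independent fits."""
    if np.any(np.isnan(fit1.std_errors)) or np.any(np.isnan(fit2.std_errors)):
        raise ValueError("both fits must carry standard errors")
    diff = np.asarray(fit1.coefficients) - np.asarray(fit2.coefficients)
    se = np.sqrt(np.asarray(fit1.std_errors) ** 2 + np.asarray(fit2.std_errors) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / se, 0.0)
    pv = 2.0 * stats.norm.sf(np.abs(z))
    if n_tests is None:
        n_tests = len(diff)
    return pd.DataFrame({
        "coefficient": ["intercept"] + [f"x{j}" for j in range(len(diff) - 1)],
        "difference": diff,
        "se": se,
        "z": z,
        "pvalue": pv,
        "significant": pv < alpha / n_tests,
    })


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(table, method: str = "yates") -> EnrichmentResult:
    """Chi-square (Yates-corrected by default) test of a 2x2 state-by-label
    table; 'plain' and 'fisher' dialects available."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be > 0")
    warning = None
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if np.any(expected < 5):
        warning = "expected cell count < 5; consider method='fisher'"
    if method == "fisher":
        statistic, pvalue = stats.fisher_exact(table.astype(int))
    elif method in ("yates", "plain"):
        res = stats.chi2_contingency(table, correction=(method == "yates"))
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    proportions = table[:, 0] / table.sum(axis=1)
    return EnrichmentResult(table=table.astype(int), statistic=float(statistic),
                            pvalue=float(pvalue), method=method,
                            proportions=proportions, warning=warning)


def table_from_labels(state_path: np.ndarray, labels: np.ndarray,
                      states: tuple[int, int] = (1, 2)) -> np.ndarray:
    """2x2 counts: rows the two states, columns (label=1, label=0)."""
    state_path = np.asarray(state_path)
    labels = np.asarray(labels).astype(bool)
    return np.array([
        [int((labels & (state_path == s)).sum()), int((~labels & (state_path == s)).sum())]
        for s in states
    ])


def go_frequency_scan(
    annotations: dict[str, set[str]] | pd.DataFrame,
    gene_ids: Sequence[str],
    state_path: np.ndarray,
    min_count: int = 10,
    alpha: float = 0.05,
    method: str = "yates",
) -> tuple[pd.DataFrame, dict]:
    """Per-annotation two-proportion test between the two states.

    ``annotations`` maps gene id -> set of labels (or a long DataFrame with
    gene_id/label columns).  Labels with more than ``min_count`` genes in
    each state are tested (chi-square on the 2x2 membership table) with
    Bonferroni correction over the tested labels; the rest are listed as
    skipped.  Also reports how many genes carry no label at all, per state.
    """
    if isinstance(annotations, pd.DataFrame):
        ann_map: dict[str, set[str]] = {}
        for gid, label in zip(annotations["gene_id"], annotations["label"]):
            ann_map.setdefault(str(gid), set()).add(str(label))
    else:
        ann_map = {str(k): set(v) for k, v in annotations.items()}
    if not ann_map:
        raise ValueError("empty annotation table")
    state_path = np.asarray(state_path)
    gene_ids = [str(g) for g in gene_ids]
    n_state = {s: int((state_path == s).sum()) for s in (1, 2)}

    counts: dict[str, dict[int, int]] = {}
    unannotated = {1: 0, 2: 0}
    for gid, s in zip(gene_ids, state_path):
        labels = ann_map.get(gid, set())
        if not labels:
            if s in unannotated:
                unannotated[int(s)] += 1
            continue
        for lab in labels:
            counts.setdefault(lab, {1: 0, 2: 0})
            if int(s) in (1, 2):
                counts[lab][int(s)] += 1

    rows, skipped = [], []
    for lab, c in sorted(counts.items()):
        if c[1] <= min_count or c[2] <= min_count:
            skipped.append(lab)
            continue
        table = np.array([
            [c[1], n_state[1] - c[1]],
            [c[2], n_state[2] - c[2]],
        ])
        res = enrichment_test(table, method=method)
        rows.append((lab, c[1], c[2], c[1] / n_state[1], c[2] / n_state[2], res.pvalue))
    df = pd.DataFrame(rows, columns=["label", "n_state1", "n_state2",
                                     "prop_state1", "prop_state2", "pvalue"])
    if len(df):
        df["significant"] = df["pvalue"] < alpha / len(df)
        df = df.sort_values("pvalue").reset_index(drop=True)
    else:
        df["significant"] = pd.Series(dtype=bool)
    meta = {"skipped": skipped, "unannotated": unannotated, "n_tested": len(df)}
    return df, meta


# ---------------------------------------------------------------------------
# added binary covariate


def add_binary_covariate(
    X: np.ndarray, y: np.ndarray, state_path: np.ndarray, label: np.ndarray,
    states: tuple[int, int] = (1, 2),
) -> dict:
    """Refit each state's regression with an extra binary column.

    Reports, per state: the new R^2 and its gain over the original fit, the
    new intercept, the label's coefficient and SE, and the nested-model
    F-test.  Across states, a z-test compares the label coefficients.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    label = np.asarray(label, dtype=float)
    out: dict = {"per_state": {}}
    coefs, ses = [], []
    for s in states:
        sel = np.asarray(state_path) == s
        if label[sel].min() == label[sel].max():
            out["per_state"][s] = {"identifiable": False}
            coefs.append(np.nan)
            ses.append(np.nan)
            logger.warning("label constant within state %s; coefficient unidentifiable", s)
            continue
        base = _ols(X[sel], y[sel])
        ext = _ols(np.column_stack([X[sel], label[sel]]), y[sel])
        f, f_p, _ = ext.compare_f_test(base)
        out["per_state"][s] = {
            "identifiable": True,
            "r2": float(ext.rsquared),
            "delta_r2": float(ext.rsquared - base.rsquared),
            "intercept": float(ext.params[0]),
            "intercept_before": float(base.params[0]),
            "label_coef": float(ext.params[-1]),
            "label_se": float(ext.bse[-1]),
            "f_stat": float(f),
            "f_pvalue": float(f_p),
        }
        coefs.append(float(ext.params[-1]))
        ses.append(float(ext.bse[-1]))
    if not any(np.isnan(coefs)):
        diff = coefs[1] - coefs[0]
        se = float(np.sqrt(ses[0] ** 2 + ses[1] ** 2))
        z = diff / se
        out["cross_state"] = {
            "difference": diff, "se": se, "z": z,
            "pvalue": float(2.0 * stats.norm.sf(abs(z))),
        }
    return out


# ---------------------------------------------------------------------------
# simulation-based R^2 tests


def r2_difference_simtest(
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> SimTestResult:
    """Resampling test of the R^2 difference between two gene groups.

    The pooled group is repeatedly split at random into sizes (|A|, |B|);
    the p-value is the fraction of splits whose absolute R^2 difference is
    at least the observed one (non-strict).
    """
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if len(idx_a) <= p + 1 or len(idx_b) <= p + 1:
        raise ValueError("both groups must exceed the number of predictors")
    obs = abs(ols_r2(X[idx_a], y[idx_a]) - ols_r2(X[idx_b], y[idx_b]))
    pool = np.concatenate([idx_a, idx_b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(pool)
        a, b = perm[: len(idx_a)], perm[len(idx_a):]
        null[r] = abs(ols_r2(X[a], y[a]) - ols_r2(X[b], y[b]))
    count = int(np.sum(null >= obs))
    return SimTestResult(observed=float(obs), n_reps=n_reps, count=count,
                         pvalue=count / n_reps, seed=seed,
                         null_min=float(null.min()), null_max=float(null.max()),
                         group_sizes=(len(idx_a), len(idx_b)))


def r2_extremity_simtest(
    subset_idx: np.ndarray,
    universe_idx: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n_reps: int = 1000,
    side: str = "smaller",
    seed: Optional[int] = None,
) -> SimTestResult:
    """Is the subset's R^2 extreme against random same-size subsets?

    Draws ``n_reps`` random gene sets of the subset's size from the universe,
    fits OLS on each, and counts how many null R^2 fall on the requested side
    of the observed value: side='smaller' counts null <= observed (small
    count means the observed R^2 is unusually small), side='larger' counts
    null >= observed.  The null's min/max are reported alongside.
    """
    subset_idx = np.asarray(subset_idx)
    universe_idx = np.asarray(universe_idx)
    if len(subset_idx) > len(universe_idx):
        raise ValueError("subset larger than universe")
    if side not in ("smaller", "larger"):
        raise ValueError("side must be 'smaller' or 'larger'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    obs = ols_r2(X[subset_idx], y[subset_idx])
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.choice(universe_idx, size=len(subset_idx), replace=False)
        null[r] = ols_r2(X[draw], y[draw])
    count = int(np.sum(null <= obs) if side == "smaller" else np.sum(null >= obs))
    return SimTestResult(observed=float(obs), n_reps=n_reps, count=count,
                         pvalue=count / n_reps, seed=seed,
                         null_min=float(null.min()), null_max=float(null.max()),
                         group_sizes=(len(subset_idx), len(universe_idx)))
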