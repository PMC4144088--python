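"""Tests for state characterization: regressions, enrichment, resampling tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reghmm import state_analysis as sa


@pytest.fixture(scope="module")
def two_group_data():
    """Two gene groups with different regression structure."""
    rng = np.random.default_rng(0)
    n, p = 600, 4
    X = rng.standard_normal((n, p))
    states = np.concatenate([np.ones(n // 2, int), np.full(n // 2, 2)])
    betas = np.array([[0.25, 1.0, -1.0, 0.5, 0.0], [1.15, 0.3, 0.3, -0.2, 0.1]])
    sigmas = np.array([0.5, 1.2])
    y = betas[states - 1, 0] + np.einsum("tp,tp->t", X, betas[states - 1, 1:]) \
        + sigmas[states - 1] * rng.standard_normal(n)
    return X, y, states


class TestPerStateOLS:
    def test_exact_linear_gives_unit_r2(self, two_group_data):
        X, _, states = two_group_data
        y = 1.0 + X @ np.array([1.0, 2.0, -1.0, 0.5])
        fits, combined, single = sa.per_state_ols(X, y, states)
        assert all(np.isclose(f.r_squared, 1.0) for f in fits)
        assert np.isclose(combined, 1.0) and np.isclose(single, 1.0)

    def test_independent_response_near_zero_r2(self):
        rng = np.random.default_rng(1)
        n, p = 2000, 4
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        fits, _, single = sa.per_state_ols(X, y, np.ones(n, int))
        assert fits[0].r_squared < 3 * p / (n - 1)
        assert single < 3 * p / (n - 1)

    def test_combined_exceeds_single_when_states_differ(self, two_group_data):
        X, y, states = two_group_data
        fits, combined, single = sa.per_state_ols(X, y, states)
        assert combined >= single - 1e-12
        assert fits[0].r_squared > fits[1].r_squared  # tight vs noisy state

    def test_underdetermined_state_reported_not_crashed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        states = np.concatenate([np.ones(17, int), np.full(3, 2)])
        fits, _, _ = sa.per_state_ols(X, y, states)
        assert np.isnan(fits[1].r_squared)


class TestSignedR2:
    def test_perfect_positive_and_negative(self):
        y = np.linspace(-2, 2, 50)
        X = np.column_stack([y, -y])
        out = sa.signed_r2_per_variable(X, y)
        assert np.isclose(out.loc["all", 0], 1.0)
        assert np.isclose(out.loc["all", 1], -1.0)

    def test_equals_signed_squared_correlation(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        y = X @ np.array([0.5, -1.0, 0.0]) + rng.standard_normal(100)
        out = sa.signed_r2_per_variable(X, y)
        for j in range(3):
            r = stats.pearsonr(X[:, j], y).statistic
            assert np.isclose(out.loc["all", j], r * abs(r), atol=1e-12)

    def test_magnitude_bounded_by_one(self, two_group_data):
        X, y, states = two_group_data
        out = sa.signed_r2_per_variable(X, y, states)
        assert (out.abs() <= 1.0 + 1e-12).all().all()


class TestCompareStateMeans:
    def test_shifted_column_detected(self):
        rng = np.random.default_rng(4)
        n = 1000
        X = rng.standard_normal((n, 5))
        states = np.concatenate([np.ones(n // 2, int), np.full(n // 2, 2)])
        X[states == 2, 0] += 1.0  # 1 SD shift in the first column only
        out = sa.compare_state_means(X, states)
        assert bool(out.loc[0, "significant"])
        assert not out.loc[1:, "significant"].any()

    def test_bonferroni_controls_permuted_labels(self):
        rng = np.random.default_rng(5)
        n, p = 400, 20
        X = rng.standard_normal((n, p))
        false_pos = 0
        reps = 200
        for _ in range(reps):
            states = rng.permutation(np.repeat([1, 2], n // 2))
            out = sa.compare_state_means(X, states)
            false_pos += int(out["significant"].sum() > 0)
        # family-wise error should be near alpha = 0.05
        assert false_pos / reps < 0.12


class TestCompareStateCoefficients:
    def test_identical_fits_no_differences(self, two_group_data):
        X, y, states = two_group_data
        fits, _, _ = sa.per_state_ols(X, y, states)
        out = sa.compare_state_coefficients(fits[0], fits[0])
        assert np.allclose(out["difference"], 0.0)
        assert not out["significant"].any()

    def test_intercept_only_difference_flagged(self):
        rng = np.random.default_rng(6)
        n, p = 4000, 3
        X = rng.standard_normal((n, p))
        states = np.concatenate([np.ones(n // 2, int), np.full(n // 2, 2)])
        slope = np.array([1.0, -0.5, 0.2])
        y = np.where(states == 1, 0.0, 2.0) + X @ slope + 0.5 * rng.standard_normal(n)
        fits, _, _ = sa.per_state_ols(X, y, states)
        out = sa.compare_state_coefficients(fits[0], fits[1])
        assert bool(out.loc[0, "significant"])  # intercept
        assert not out.loc[1:, "significant"].any()

    def test_five_se_difference_flagged(self, two_group_data):
        X, y, states = two_group_data
        fits, _, _ = sa.per_state_ols(X, y, states)
        f2 = sa.StateRegression(
            state=2, n=fits[0].n, r_squared=fits[0].r_squared,
            intercept=fits[0].intercept,
            coefficients=np.asarray(fits[0].coefficients).copy(),
            std_errors=np.asarray(fits[0].std_errors).copy(),
            residual_variance=fits[0].residual_variance)
        f2.coefficients[1] += 5 * np.sqrt(2) * f2.std_errors[1]
        out = sa.compare_state_coefficients(fits[0], f2)
        assert bool(out.loc[1, "significant"])


class TestEnrichment:
    def test_housekeeping_table_pvalue(self):
        # 192 of 10211 vs 239 of 6809 housekeeping genes by state
        res = sa.enrichment_test([[192, 10211 - 192], [239, 6809 - 239]])
        assert res.pvalue == pytest.approx(4.693e-11, rel=0.01)

    def test_tata_table_pvalue(self):
        # 1200 of 10211 vs 629 of 6809 TATA-containing genes by state
        res = sa.enrichment_test([[1200, 10211 - 1200], [629, 6809 - 629]])
        assert res.pvalue == pytest.approx(2.42e-7, rel=0.01)

    def test_cpg_table_strongly_significant(self):
        # CpG-island overlap: 6057/10211 (59%) vs 4758/6809 (70%)
        res = sa.enrichment_test([[6057, 4154], [4758, 2051]])
        assert res.pvalue < 2.2e-16
        np.testing.assert_allclose(res.proportions, [0.59, 0.70], atol=0.005)

    def test_balanced_table_p_one(self):
        res = sa.enrichment_test([[50, 50], [50, 50]])
        assert res.pvalue == pytest.approx(1.0)

    def test_symmetric_under_double_swap(self):
        t = np.array([[30, 70], [55, 45]])
        a = sa.enrichment_test(t)
        b = sa.enrichment_test(t[::-1, ::-1])
        assert np.isclose(a.pvalue, b.pvalue)

    def test_small_expected_warns(self):
        res = sa.enrichment_test([[2, 100], [1, 120]])
        assert res.warning is not None

    def test_dialects_differ(self):
        t = [[192, 10019], [239, 6570]]
        yates = sa.enrichment_test(t, method="yates").pvalue
        plain = sa.enrichment_test(t, method="plain").pvalue
        assert plain < yates

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sa.enrichment_test([[0, 0], [5, 5]])


class TestGoFrequencyScan:
    def _setup(self, rates, n=1500, seed=7):
        rng = np.random.default_rng(seed)
        states = rng.integers(1, 3, n)
        gene_ids = [f"g{i}" for i in range(n)]
        ann = {}
        for gid, s in zip(gene_ids, states):
            labels = set()
            for lab, rr in rates.items():
                if rng.random() < rr[s - 1]:
                    labels.add(lab)
            if labels:
                ann[gid] = labels
        return ann, gene_ids, states

    def test_state_independent_labels_not_flagged(self):
        ann, ids, states = self._setup({f"GO:{k}": (0.2, 0.2) for k in range(8)})
        df, meta = sa.go_frequency_scan(ann, ids, states)
        assert not df["significant"].any()

    def test_biased_label_detected(self):
        ann, ids, states = self._setup({"GO:bias": (0.10, 0.30),
                                        "GO:null": (0.2, 0.2)}, n=2000)
        df, _ = sa.go_frequency_scan(ann, ids, states)
        row = df[df["label"] == "GO:bias"].iloc[0]
        assert bool(row["significant"])

    def test_rare_label_skipped(self):
        ann, ids, states = self._setup({"GO:rare": (0.004, 0.004),
                                        "GO:ok": (0.3, 0.3)})
        df, meta = sa.go_frequency_scan(ann, ids, states, min_count=10)
        assert "GO:rare" in meta["skipped"]
        assert "GO:ok" in set(df["label"])

    def test_unannotated_genes_counted(self):
        ann = {"g0": {"GO:x"}}
        ids = ["g0", "g1", "g2"]
        _, meta = sa.go_frequency_scan(ann, ids, np.array([1, 1, 2]))
        assert meta["unannotated"] == {1: 1, 2: 1}

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            sa.go_frequency_scan({}, ["g0"], np.array([1]))


class TestAddBinaryCovariate:
    def _data(self, effect=(0.5, 0.5), seed=8, n=2000):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        states = np.concatenate([np.ones(n // 2, int), np.full(n // 2, 2)])
        label = (rng.random(n) < 0.5).astype(float)
        eff = np.where(states == 1, effect[0], effect[1])
        y = 0.2 + X @ np.array([1.0, -0.5, 0.3]) + eff * label \
            + 0.6 * rng.standard_normal(n)
        return X, y, states, label

    def test_true_effect_recovered(self):
        X, y, states, label = self._data(effect=(0.5, 0.5))
        out = sa.add_binary_covariate(X, y, states, label)
        for s in (1, 2):
            rec = out["per_state"][s]
            assert abs(rec["label_coef"] - 0.5) < 3 * rec["label_se"]
            assert rec["f_pvalue"] < 1e-6

    def test_null_label_no_improvement(self):
        rng = np.random.default_rng(9)
        X, y, states, _ = self._data(effect=(0.0, 0.0))
        label = (rng.random(len(y)) < 0.5).astype(float)
        out = sa.add_binary_covariate(X, y, states, label)
        for s in (1, 2):
            assert out["per_state"][s]["delta_r2"] < 0.01

    def test_equal_effects_cross_state_null(self):
        X, y, states, label = self._data(effect=(0.5, 0.5))
        out = sa.add_binary_covariate(X, y, states, label)
        assert out["cross_state"]["pvalue"] > 0.01

    def test_unequal_effects_cross_state_detected(self):
        X, y, states, label = self._data(effect=(0.1, 0.9), n=4000)
        out = sa.add_binary_covariate(X, y, states, label)
        assert out["cross_state"]["pvalue"] < 0.001
        assert out["cross_state"]["difference"] > 0

    def test_constant_label_flagged(self):
        X, y, states, label = self._data()
        label[states == 1] = 1.0
        out = sa.add_binary_covariate(X, y, states, label)
        assert out["per_state"][1] == {"identifiable": False}


class TestR2DifferenceSimtest:
    def _data(self, n=300, p=3, seed=10, noise_b=1.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        noise = np.concatenate([np.full(n // 2, 0.5), np.full(n - n // 2, 0.5 * noise_b)])
        y = X @ np.array([1.0, -1.0, 0.5]) + noise * rng.standard_normal(n)
        return X, y

    def test_identical_groups_p_one(self):
        X, y = self._data()
        idx = np.arange(100)
        res = sa.r2_difference_simtest(idx, idx, X, y, n_reps=50, seed=0)
        assert res.observed == 0.0 and res.pvalue == 1.0

    def test_null_mean_p_near_half(self):
        X, y = self._data(n=240)
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(30):
            perm = rng.permutation(240)
            res = sa.r2_difference_simtest(perm[:120], perm[120:], X, y,
                                           n_reps=200, seed=rep)
            ps.append(res.pvalue)
        assert 0.3 < np.mean(ps) < 0.7

    def test_double_noise_detected(self):
        X, y = self._data(n=400, noise_b=3.0, seed=12)
        res = sa.r2_difference_simtest(np.arange(200), np.arange(200, 400), X, y,
                                       n_reps=500, seed=1)
        assert res.pvalue < 0.05

    def test_reproducible_under_seed(self):
        X, y = self._data()
        a = sa.r2_difference_simtest(np.arange(100), np.arange(100, 200), X, y,
                                     n_reps=100, seed=42)
        b = sa.r2_difference_simtest(np.arange(100), np.arange(100, 200), X, y,
                                     n_reps=100, seed=42)
        assert a.pvalue == b.pvalue and a.count == b.count

    def test_small_group_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            sa.r2_difference_simtest(np.arange(2), np.arange(2, 100), X, y)


class TestR2ExtremitySimtest:
    def _data(self, n=500, seed=13):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.7 * rng.standard_normal(n)
        return X, y

    def test_random_subset_p_near_half(self):
        X, y = self._data()
        rng = np.random.default_rng(14)
        ps = [sa.r2_extremity_simtest(rng.choice(500, 60, replace=False),
                                      np.arange(500), X, y, n_reps=200,
                                      seed=rep).pvalue
              for rep in range(20)]
        assert 0.25 < np.mean(ps) < 0.75

    def test_shuffled_response_subset_in_left_tail(self):
        X, y = self._data()
        rng = np.random.default_rng(15)
        sub = np.arange(60)
        y2 = y.copy()
        y2[sub] = rng.permutation(y2[sub])  # destroy the association in the subset
        res = sa.r2_extremity_simtest(sub, np.arange(500), X, y2, n_reps=300,
                                      side="smaller", seed=0)
        assert res.pvalue < 0.05
        assert res.null_min > res.observed  # mirrors reporting the null minimum

    def test_single_rep_resolution(self):
        X, y = self._data()
        res = sa.r2_extremity_simtest(np.arange(60), np.arange(500), X, y,
                                      n_reps=1, seed=0)
        assert res.pvalue in (0.0, 1.0)

    def test_subset_larger_than_universe_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            sa.r2_extremity_simtest(np.arange(200), np.arange(100), X, y)
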