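import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit
from statsmodels.stats.multitest import multipletests

from perio16s.association import (
    DesignError,
    bh_adjust,
    fit_binomial_glm,
    gingivitis_trend_test,
    gingivitis_trend_tests,
    health_status_test,
    health_status_tests,
    perm_pvalue,
    predict_trend_curve,
)
from perio16s.synthetic import SimulationConfig, simulate_dataset
from oracles import bh_naive


class TestGlmFit:
    def test_saturated_two_group_fit_is_exact(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        fit = fit_binomial_glm([12, 52], [104, 204], X)
        assert fit.converged
        assert fit.fitted_proportions == pytest.approx([12 / 104, 52 / 204])
        log_or = np.log((12 / 92) / (52 / 152))
        assert -fit.coefficients[1] == pytest.approx(log_or, abs=1e-6)
        assert round(-fit.coefficients[1], 4) == -0.9642

    def test_intercept_only_is_pooled_logit(self):
        y = [5, 7, 9, 3]
        n = [50, 50, 50, 50]
        fit = fit_binomial_glm(y, n, np.ones((4, 1)))
        assert fit.coefficients[0] == pytest.approx(
            logit(sum(y) / sum(n)), abs=1e-8
        )

    def test_matches_statsmodels_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = rng.integers(50, 200, size=30).astype(float)
            X = np.column_stack([np.ones(30), rng.normal(size=30)])
            p = 1 / (1 + np.exp(-(-2.0 + 0.5 * X[:, 1])))
            y = rng.binomial(n.astype(int), p).astype(float)
            y = np.clip(y, 1, n - 1)  # keep the MLE interior
            ours = fit_binomial_glm(y, n, X)
            ref = sm.GLM(
                np.column_stack([y, n - y]), X, family=sm.families.Binomial()
            ).fit()
            assert ours.coefficients == pytest.approx(ref.params, abs=1e-6)
            assert ours.standard_errors == pytest.approx(ref.bse, rel=1e-4)
            assert ours.deviance == pytest.approx(ref.deviance, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(DesignError):
            fit_binomial_glm([1, 2, 3, 4], [10, 10, 10, 10], X)


class TestPermutationMachinery:
    def test_p_value_formula(self):
        # Observed strictly above all 999 permuted values -> 1/1000.
        assert perm_pvalue(10.0, np.zeros(999)) == pytest.approx(0.001)
        assert perm_pvalue(0.0, np.zeros(999)) == pytest.approx(1.0)
        assert perm_pvalue(5.0, np.array([4.0, 6.0, 5.0])) == pytest.approx(3 / 4)

    def test_constant_counts_give_null_result(self):
        labels = ["health"] * 3 + ["gingivitis"] * 3 + ["pd1"] * 3
        res = health_status_test([7] * 9, [1000] * 9, labels, n_perm=99, seed=0)
        assert res.overall_perm_p == 1.0
        for key, est in res.contrast_estimates.items():
            assert est == pytest.approx(0.0, abs=1e-9)
            assert res.contrast_perm_p[key] == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=12)
        totals = rng.integers(5000, 9000, size=12)
        labels = ["health"] * 4 + ["gingivitis"] * 4 + ["pd1"] * 4
        a = health_status_test(counts, totals, labels, n_perm=200, seed=42)
        b = health_status_test(counts, totals, labels, n_perm=200, seed=42)
        assert a == b

    def test_empty_group_rejected(self):
        with pytest.raises(DesignError, match="pd1"):
            health_status_test([1, 2], [10, 10], ["health", "gingivitis"],
                               n_perm=9)

    def test_null_pvalues_on_lattice_and_calibrated(self):
        # Under exchangeability p-values live on {1/(B+1), ..., 1} and are
        # approximately uniform.
        rng = np.random.default_rng(99)
        B = 99
        labels = np.array(["health"] * 6 + ["gingivitis"] * 6 + ["pd1"] * 6)
        ps = []
        for i in range(120):
            totals = rng.integers(4000, 8000, size=18)
            counts = rng.binomial(totals, 0.005)
            res = health_status_test(counts, totals, labels, n_perm=B,
                                     seed=rng.integers(2**31), contrasts=[])
            ps.append(res.overall_perm_p)
        ps = np.array(ps)
        lattice = np.arange(1, B + 2) / (B + 1)
        assert np.all(np.isin(np.round(ps * (B + 1)), np.arange(1, B + 2)))
        assert abs(ps.mean() - 0.5) < 0.09
        assert abs((ps < 0.25).mean() - 0.25) < 0.13


class TestTrend:
    def test_saturated_slope_closed_form(self):
        # Adjusted proportions 0.1 and 0.3 at scores 0 and 3.
        res = gingivitis_trend_test([18, 58], [196, 196], [0.0, 3.0],
                                    n_perm=9, seed=1)
        expected = (logit(0.3) - logit(0.1)) / 3
        assert res.slope == pytest.approx(expected, abs=1e-6)
        assert round(res.slope, 4) == 0.4500

    def test_constant_counts_flat(self):
        res = gingivitis_trend_test([5] * 6, [800] * 6,
                                    [0, 1, 1.5, 2, 2.5, 3], n_perm=49, seed=0)
        assert res.slope == pytest.approx(0.0, abs=1e-7)
        assert res.perm_p == 1.0

    def test_score_sign_flip_negates_slope(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 60, size=10)
        totals = rng.integers(4000, 9000, size=10)
        scores = rng.uniform(0, 3, size=10)
        a = gingivitis_trend_test(counts, totals, scores, n_perm=9, seed=3)
        b = gingivitis_trend_test(counts, totals, -scores, n_perm=9, seed=3)
        assert a.slope == pytest.approx(-b.slope, abs=1e-8)

    def test_constant_scores_rejected(self):
        with pytest.raises(DesignError):
            gingivitis_trend_test([1, 2], [10, 10], [2.0, 2.0], n_perm=9)


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
         ((0.005, 0.1, 0.9), (0.015, 0.15, 0.9)),
         ((0.37,), (0.37,))],
    )
    def test_known_values(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_naive_and_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            ours = bh_adjust(p)
            assert ours == pytest.approx(bh_naive(p))
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(ref)

    def test_domain_validated(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestTrendCurve:
    def test_flat_fit_and_band_inside_unit_interval(self):
        res = gingivitis_trend_test([5] * 6, [800] * 6,
                                    [0, 1, 1.5, 2, 2.5, 3], n_perm=9, seed=0)
        grid = np.linspace(0, 3, 13)
        curve, lo, hi = predict_trend_curve(res.fit, grid)
        assert np.allclose(curve, curve[0])
        assert np.all((lo > 0) & (hi < 1))
        assert np.all((lo <= curve) & (curve <= hi))

    def test_band_narrows_with_information(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 3, size=20)
        totals = np.full(20, 2000)
        counts = rng.binomial(totals, 0.01 * (1 + scores))
        grid = np.linspace(0, 3, 7)
        small = gingivitis_trend_test(counts, totals, scores, n_perm=9, seed=0)
        big = gingivitis_trend_test(counts * 100, totals * 100, scores,
                                    n_perm=9, seed=0)
        _, lo_s, hi_s = predict_trend_curve(small.fit, grid)
        _, lo_b, hi_b = predict_trend_curve(big.fit, grid)
        assert np.all((hi_b - lo_b) < (hi_s - lo_s))


class TestTableWrappers:
    def test_family_q_values_and_shape(self):
        config = SimulationConfig(
            n_samples_per_group={"health": 5, "gingivitis": 6, "pd1": 5},
            n_otus=8, n_rare_otus=3, seed=13,
        )
        ds = simulate_dataset(config)
        from perio16s.abundance import classify_rare
        filtered = classify_rare(ds.counts, ds.metadata)
        assoc = health_status_tests(filtered.retained, ds.metadata,
                                    n_perm=49, seed=1)
        n_otus = len(filtered.retained.otu_ids) - 1  # RARE excluded
        assert set(assoc["contrast"]) == {"overall", "H-vs-G", "G-vs-PD1",
                                          "H-vs-PD1"}
        assert len(assoc) == 4 * n_otus
        for fam, sub in assoc.groupby("contrast"):
            assert np.all(sub["q_value"] >= sub["perm_p"] - 1e-12)
            assert bh_adjust(sub["perm_p"].to_numpy()) == pytest.approx(
                sub["q_value"].to_numpy()
            )
        trend = gingivitis_trend_tests(filtered.retained, ds.metadata,
                                       n_perm=49, seed=2)
        assert "RARE" in set(trend["otu_id"])  # rare row kept for trend
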