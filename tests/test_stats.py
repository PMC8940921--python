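"""Growth rates, geometric summaries, tests: oracles and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phycogradients.stats import (bh_fdr, fold_change_by_distance,
                                  geometric_stats, permutation_trend_test,
                                  permutation_trend_pvalues_batch,
                                  specific_growth_rate,
                                  two_way_anova_interaction, welch_t_test,
                                  welch_t_test_batch)


class TestSpecificGrowthRate:
    def _frame(self, t, values):
        return pd.DataFrame({"rep1": values}, index=pd.Index(t, name="time"))

    def test_doubling_per_day_gives_ln2(self):
        res = specific_growth_rate(self._frame([0, 1], [1e6, 2e6]), 0, 1)
        assert res.mu_mean == pytest.approx(np.log(2.0))

    def test_constant_density_gives_zero(self):
        res = specific_growth_rate(self._frame([0, 1, 2], [5e6] * 3), 0, 2)
        assert res.mu_mean == 0.0

    def test_forward_simulated_exponential_recovered_exactly(self):
        t = np.linspace(0, 6, 25)
        reps = pd.DataFrame({f"r{i}": 1e5 * np.exp(0.25 * t) for i in range(3)},
                            index=t)
        res = specific_growth_rate(reps, 3.0, 5.0)
        assert res.mu_mean == pytest.approx(0.25, rel=1e-10)
        assert res.mu_sd == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_density_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            specific_growth_rate(self._frame([0, 1], [0.0, 1e6]), 0, 1)


class TestGeometricStats:
    def test_identical_values(self):
        out = geometric_stats([7.0, 7.0, 7.0])
        assert out["geo_mean"] == pytest.approx(7.0)
        assert out["geo_sd"] == pytest.approx(1.0)

    def test_two_decades(self):
        assert geometric_stats([1.0, 100.0])["geo_mean"] == pytest.approx(10.0)

    def test_lognormal_monte_carlo(self):
        """geo_sd of a large lognormal(0, 0.5) sample is within 1% of
        exp(0.5)."""
        rng = np.random.default_rng(7)
        v = rng.lognormal(0.0, 0.5, 100_000)
        assert geometric_stats(v)["geo_sd"] == pytest.approx(np.exp(0.5), rel=0.01)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            geometric_stats([1.0, 0.0])


def _abund_table(by_distance: dict[float, list[float]], taxon="x") -> pd.DataFrame:
    rows = []
    for d, vals in by_distance.items():
        for i, v in enumerate(vals):
            rows.append({"well_id": f"w{d}", "layer": 1, "distance_mm": d,
                         "treatment": "with_alga", "taxon": taxon,
                         "absolute_density": v, "relative_abundance": np.nan,
                         "replicate": i + 1, "timepoint": 20.0})
    return pd.DataFrame(rows)


class TestFoldChangeByDistance:
    def test_uniform_abundance_gives_unity(self):
        t = _abund_table({7.0: [1e6] * 3, 21.0: [1e6] * 3})
        resp = fold_change_by_distance(t, "x")
        assert resp.fold_decrease == pytest.approx(1.0)

    def test_reported_style_arithmetic(self):
        t = _abund_table({7.0: [9.7e6] * 3, 21.0: [1e5] * 3})
        resp = fold_change_by_distance(t, "x")
        assert resp.fold_decrease == pytest.approx(97.0)

    def test_scale_invariance(self):
        t1 = _abund_table({7.0: [2e6, 4e6], 14.0: [8e5, 9e5], 21.0: [1e5, 3e5]})
        t2 = t1.copy()
        t2["absolute_density"] *= 37.0
        f1 = fold_change_by_distance(t1, "x").fold_decrease
        f2 = fold_change_by_distance(t2, "x").fold_decrease
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_detection_floor_keeps_fold_finite(self):
        t = _abund_table({7.0: [1e7] * 3, 21.0: [0.0, 0.0, 0.0]})
        with pytest.warns(RuntimeWarning, match="floor"):
            resp = fold_change_by_distance(t, "x")
        assert resp.fold_decrease == pytest.approx(1e4)
        assert resp.at_detection_floor

    def test_missing_taxon_rejected(self):
        with pytest.raises(KeyError):
            fold_change_by_distance(_abund_table({7.0: [1.0]}), "nope")


class TestWelch:
    def test_identical_samples_give_p_one(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_tailed == pytest.approx(1.0)
        assert res.t == pytest.approx(0.0)

    def test_large_shift_is_significant(self):
        res = welch_t_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.p_two_tailed < 0.01

    def test_symmetric_under_swap(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [2.0, 2.5, 9.1]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, rel=1e-12)
        assert r1.t == pytest.approx(-r2.t, rel=1e-12)

    def test_zero_variance_equal_means(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_two_tailed == 1.0

    def test_oracle_equivalence_with_scipy(self):
        """Agreement with scipy's Welch test to 1e-10 on 100 random
        fixtures (the implementation is independent of scipy's)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 12))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 12))
            ours = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-10)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 over 1e4 simulations with
        n=9 per group lies in [0.04, 0.06]."""
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10_000, 9))
        b = rng.standard_normal((10_000, 9))
        _, _, p = welch_t_test_batch(a, b)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06


class TestAnova:
    def _table(self, y, layers, treatments):
        return pd.DataFrame({"layer": layers, "treatment": treatments,
                             "y": y})

    def _balanced(self, rng, n_rep=5, effects=(0.0, 0.0, 0.0)):
        a_eff, b_eff, ab_eff = effects
        rows = []
        for la in (1, 2):
            for tr in ("t", "c"):
                mu = (a_eff * (la == 2) + b_eff * (tr == "t")
                      + ab_eff * (la == 2) * (tr == "t"))
                for _ in range(n_rep):
                    rows.append({"layer": la, "treatment": tr,
                                 "y": mu + rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_constant_response_degenerate(self):
        t = self._table([3.0] * 8, [1, 1, 2, 2] * 2, ["a"] * 4 + ["b"] * 4)
        terms = two_way_anova_interaction(t, "y")
        assert terms["layer:treatment"]["F"] == 0.0
        assert terms["layer:treatment"].get("degenerate")

    def test_crossover_interaction_detected(self):
        """A treatment effect that reverses sign between layers yields a
        significant interaction."""
        rng = np.random.default_rng(3)
        rows = []
        for la in (1, 2):
            for tr in ("t", "c"):
                mu = 3.0 if (la == 1) == (tr == "t") else -3.0
                for _ in range(6):
                    rows.append({"layer": la, "treatment": tr,
                                 "y": mu + 0.5 * rng.standard_normal()})
        terms = two_way_anova_interaction(pd.DataFrame(rows), "y")
        assert terms["layer:treatment"]["p"] < 0.01
        assert terms["layer"]["p"] > 0.05  # mains cancel in a pure crossover

    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(9)
        t = self._balanced(rng, n_rep=7, effects=(1.0, -0.5, 2.0))
        terms = two_way_anova_interaction(t, "y")
        lhs = terms["total"]["ss"]
        rhs = (terms["layer"]["ss"] + terms["treatment"]["ss"]
               + terms["layer:treatment"]["ss"] + terms["residual"]["ss"])
        assert rhs == pytest.approx(lhs, rel=1e-9)

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(21)
        t = self._balanced(rng, n_rep=6, effects=(0.8, 0.3, -1.1))
        terms = two_way_anova_interaction(t, "y")
        fit = smf.ols("y ~ C(layer) * C(treatment)", data=t).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert terms["layer:treatment"]["F"] == pytest.approx(
            ref.loc["C(layer):C(treatment)", "F"], rel=1e-9)
        assert terms["layer:treatment"]["p"] == pytest.approx(
            ref.loc["C(layer):C(treatment)", "PR(>F)"], rel=1e-9)

    def test_null_interaction_pvalues_uniform(self):
        """Under additive effects the interaction p-value is uniform
        (KS test over seeded simulations)."""
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(400):
            t = self._balanced(rng, n_rep=5, effects=(1.0, -1.0, 0.0))
            ps.append(two_way_anova_interaction(t, "y")["layer:treatment"]["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_design_directed_to_permutation(self):
        t = self._table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                        [1, 1, 1, 2, 2, 2, 2],
                        ["a", "b", "a", "b", "a", "b", "a"])
        with pytest.raises(ValueError, match="permutation"):
            two_way_anova_interaction(t, "y")


class TestPermutationTrend:
    def test_perfect_monotone_trend_significant(self):
        a = np.arange(8, dtype=float)
        d = np.arange(8, dtype=float)
        res = permutation_trend_test(a, d, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        a, d = rng.normal(size=10), np.arange(10, dtype=float)
        r1 = permutation_trend_test(a, d, seed=123)
        r2 = permutation_trend_test(a, d, seed=123)
        assert r1 == r2

    def test_constant_abundance(self):
        res = permutation_trend_test([2.0] * 6, np.arange(6.0), seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pvalue_floor(self):
        res = permutation_trend_test(np.arange(10.0), np.arange(10.0),
                                     n_perm=999, seed=0)
        assert res.p_value >= 1.0 / 1000.0

    def test_null_pvalues_uniform(self):
        """Null p-values over 1000 seeded datasets pass a KS uniformity
        check at alpha=0.01 (discreteness-tolerant)."""
        rng = np.random.default_rng(17)
        ab = rng.standard_normal((1000, 8))
        d = np.arange(8.0)
        ps = permutation_trend_pvalues_batch(ab, d, n_perm=999, seed=99)
        # compare against the discrete uniform on {1/1000, ..., 1}
        grid = np.arange(1, 1001) / 1000.0
        assert sps.ks_2samp(ps, grid).pvalue > 0.01

    def test_unseeded_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            permutation_trend_test(np.arange(6.0), np.arange(6.0))


class TestBhFdr:
    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        ours = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
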