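import numpy as np
import pytest
from scipy import stats

import boldfractal as bf
from boldfractal.gradstats import aic, cohort_ancova, metric_hurst_correlations
from oracles import anova_f_bruteforce


class TestAic:
    def test_algebraic_identity(self):
        for rss, n, k in [(1.0, 10, 2), (0.37, 40, 3), (123.4, 165, 4)]:
            assert aic(rss, n, k) == pytest.approx(n * np.log(rss / n) + 2 * (k + 1))

    def test_zero_rss_is_minus_inf_with_warning(self):
        with pytest.warns(UserWarning, match="zero residual"):
            assert aic(0.0, 10, 2) == -np.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aic(-1.0, 10, 2)
        with pytest.raises(ValueError):
            aic(1.0, 3, 3)


class TestTissueAnova:
    def test_known_value(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        f, p = bf.tissue_anova(groups)
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_matches_oracle_and_scipy(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, size=12) for m in (0.0, 0.3, 0.7)]
        f, p = bf.tissue_anova(groups)
        assert f == pytest.approx(anova_f_bruteforce(groups), abs=1e-10)
        f_sp, p_sp = stats.f_oneway(*groups)
        assert f == pytest.approx(f_sp) and p == pytest.approx(p_sp)

    def test_degenerate_within_variance_warns(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            f, p = bf.tissue_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert f == np.inf and np.isnan(p)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            bf.tissue_anova([np.array([1.0, 2.0])])


class TestFitGradientModels:
    def test_polynomial_data_recovers_its_own_family(self):
        rng = np.random.default_rng(1)
        d = np.linspace(1, 29, 60)
        for family, coeffs in [
            ("linear", (1.0, -0.02)),
            ("quadratic", (0.9, 0.02, -0.0008)),
            # turning points at 8 and 22 mm: a non-monotonic shape that no
            # three-parameter family can approximate within the parsimony
            # margin, so the extra cubic term is identifiable
            ("cubic", (0.9, 0.528, -0.045, 0.001)),
        ]:
            y_true = np.polyval(coeffs[::-1], d)
            wins = 0
            for rep in range(20):
                noise = rng.normal(0, 0.25 * np.ptp(y_true), size=d.size)
                fits = bf.fit_gradient_models(d, y_true + noise, seed=rep)
                if bf.select_best(fits).family == family:
                    wins += 1
            assert wins >= 10, f"{family}: selected only {wins}/20"

    def test_aic_tie_breaks_to_fewest_parameters(self):
        from boldfractal.gradstats import ModelFit

        fits = [
            ModelFit("cubic", np.zeros(4), 1.0, -np.inf, 20),
            ModelFit("linear", np.zeros(2), 1.0, -np.inf, 20),
            ModelFit("quadratic", np.zeros(3), 1.0, -np.inf, 20),
        ]
        assert bf.select_best(fits).family == "linear"

    def test_unconverged_fits_excluded(self):
        from boldfractal.gradstats import ModelFit

        fits = [
            ModelFit("exponential", np.zeros(2), 1.0, -1e9, 20, converged=False),
            ModelFit("linear", np.zeros(2), 0.5, -10.0, 20),
        ]
        assert bf.select_best(fits).family == "linear"
        with pytest.raises(ValueError, match="no converged"):
            bf.select_best([fits[0]])

    def test_noisy_linear_data_selects_linear(self):
        rng = np.random.default_rng(11)
        d = np.linspace(1, 29, 200)
        y = 1.0 - 0.005 * d + rng.normal(0, 0.02, size=d.size)
        fits = bf.fit_gradient_models(d, y, seed=0)
        assert bf.select_best(fits).family == "linear"

    def test_exponential_coefficients_recovered(self):
        rng = np.random.default_rng(2)
        d = np.linspace(0, 30, 80)
        y = 2.0 * np.exp(-0.1 * d) + rng.normal(0, 0.01, size=d.size)
        fits = {f.family: f for f in bf.fit_gradient_models(d, y, seed=0)}
        b, c = fits["exponential"].coefficients
        assert b == pytest.approx(2.0, abs=0.05)
        assert c == pytest.approx(-0.1, abs=0.01)
        assert fits["exponential"].converged

    def test_exponential_intersect_recovered_and_selected(self):
        rng = np.random.default_rng(3)
        d = np.linspace(0, 30, 100)
        y = 0.9 + 0.4 * np.exp(-0.3 * d) + rng.normal(0, 0.005, size=d.size)
        fits = bf.fit_gradient_models(d, y, seed=0)
        best = bf.select_best(fits)
        assert best.family == "exponential_intersect"
        a, b, c = best.coefficients
        assert a == pytest.approx(0.9, abs=0.02)
        assert b == pytest.approx(0.4, abs=0.05)
        assert c == pytest.approx(-0.3, abs=0.05)

    def test_predict_round_trip(self):
        rng = np.random.default_rng(10)
        d = np.linspace(1, 20, 30)
        y = 1.0 + 0.1 * d - 0.004 * d**2 + rng.normal(0, 1e-6, size=d.size)
        fits = {f.family: f for f in bf.fit_gradient_models(d, y, seed=0)}
        np.testing.assert_allclose(fits["quadratic"].predict(d), y, atol=1e-4)

    def test_r_squared_and_p_value_sane(self):
        rng = np.random.default_rng(4)
        d = np.linspace(1, 29, 50)
        y = 1.0 - 0.01 * d + rng.normal(0, 0.01, size=d.size)
        for f in bf.fit_gradient_models(d, y, seed=0):
            if f.converged:
                assert 0.0 <= f.r_squared <= 1.0
        lin = next(f for f in bf.fit_gradient_models(d, y, seed=0) if f.family == "linear")
        assert lin.p_value < 1e-6

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            bf.fit_gradient_models(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            bf.fit_gradient_models(np.arange(10.0), np.arange(9.0))

    def test_nonfinite_pairs_dropped(self):
        rng = np.random.default_rng(5)
        d = np.linspace(1, 29, 40)
        y = 1.0 - 0.01 * d + rng.normal(0, 0.01, size=d.size)
        y[3] = np.nan
        d2, y2 = np.delete(d, 3), np.delete(y, 3)
        a = bf.fits_table(bf.fit_gradient_models(d, y, seed=0))
        b = bf.fits_table(bf.fit_gradient_models(d2, y2, seed=0))
        np.testing.assert_allclose(a["aic"], b["aic"])
        assert (a["n_obs"] == d.size - 1).all()


class TestCohortAncova:
    def _simulate(self, slopes, seed, n_per=40, sigma=0.05):
        rng = np.random.default_rng(seed)
        d, y, g = [], [], []
        for name, slope in slopes.items():
            dd = rng.uniform(1, 29, size=n_per)
            yy = -0.3 + slope * dd + rng.normal(0, sigma, size=n_per)
            d.append(dd)
            y.append(yy)
            g.append(np.repeat(name, n_per))
        return np.concatenate(y), np.concatenate(d), np.concatenate(g)

    def test_slopes_match_per_cohort_ols_exactly(self):
        y, d, g = self._simulate({"a": 0.01, "b": -0.02}, seed=0)
        res = cohort_ancova(y, d, g)
        for name in ("a", "b"):
            sel = g == name
            slope_ols = np.polyfit(d[sel], y[sel], 1)[0]
            assert res.slopes[name] == pytest.approx(slope_ols, abs=1e-10)

    def test_strong_interaction_detected(self):
        y, d, g = self._simulate({"a": 0.01, "b": -0.02}, seed=1)
        res = cohort_ancova(y, d, g)
        assert res.p_interaction < 1e-6
        assert res.f_interaction > 10

    def test_null_p_values_roughly_uniform(self):
        """Under equal slopes the interaction p-value is Uniform(0, 1):
        KS test over 200 simulated datasets."""
        ps = []
        for s in range(200):
            y, d, g = self._simulate({"a": 0.005, "b": 0.005}, seed=100 + s, n_per=25)
            ps.append(cohort_ancova(y, d, g).p_interaction)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_posthoc_bonferroni_exact(self):
        y, d, g = self._simulate({"a": 0.01, "b": 0.0, "c": -0.01}, seed=2)
        res = cohort_ancova(y, d, g)
        assert len(res.posthoc) == 3
        m = 3
        for _, row in res.posthoc.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, m * row["p_raw"]))

    def test_two_cohorts_posthoc_single_uncorrected(self):
        y, d, g = self._simulate({"a": 0.01, "b": -0.02}, seed=3)
        res = cohort_ancova(y, d, g)
        assert len(res.posthoc) == 1
        row = res.posthoc.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(row["p_raw"])
        # the pairwise slope contrast equals the slope difference
        assert row["slope_diff"] == pytest.approx(
            res.slopes["a"] - res.slopes["b"], abs=1e-10
        )

    def test_constant_distance_rank_deficient(self):
        y = np.random.default_rng(6).normal(size=20)
        d = np.full(20, 5.0)
        g = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="rank-deficient"):
            cohort_ancova(y, d, g)

    def test_input_contracts(self):
        with pytest.raises(ValueError, match=">= 2 cohorts"):
            cohort_ancova(np.zeros(6), np.arange(6.0), np.repeat("a", 6))
        with pytest.raises(ValueError, match=">= 3 observations"):
            cohort_ancova(
                np.zeros(5), np.arange(5.0), np.array(["a", "a", "a", "b", "b"])
            )


class TestMetricHurstCorrelations:
    def test_perfect_correlation(self):
        import pandas as pd

        h = np.linspace(0.5, 0.9, 30)
        metrics = pd.DataFrame({"id": np.arange(30), "strength": 2 * h + 1})
        out = metric_hurst_correlations(h, metrics, columns=("strength",))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p_raw"].iloc[0] < 1e-12

    def test_bonferroni_over_columns(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        h = rng.normal(size=50)
        metrics = pd.DataFrame(
            {"id": np.arange(50), "a": rng.normal(size=50), "b": rng.normal(size=50)}
        )
        out = metric_hurst_correlations(h, metrics, columns=("a", "b")).set_index("metric")
        for m in ("a", "b"):
            assert out.loc[m, "p_bonferroni"] == pytest.approx(
                min(1.0, 2 * out.loc[m, "p_raw"])
            )

    def test_constant_column_gives_nan(self):
        import pandas as pd

        h = np.linspace(0, 1, 20)
        metrics = pd.DataFrame({"id": np.arange(20), "flat": np.ones(20)})
        out = metric_hurst_correlations(h, metrics, columns=("flat",))
        assert np.isnan(out["r"].iloc[0])
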