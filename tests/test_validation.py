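"""Buffer-mean covariate extraction, NB regression, AICc and pseudo-R²."""

import numpy as np
import pytest

from prairieq import (
    GridSpec,
    QualityRaster,
    SurveyStop,
    aicc,
    fit_negbin,
    mean_quality_at_stops,
    pseudo_r2,
    select_model,
)
from prairieq.synth import CountModelConfig, generate_counts
from prairieq.validation import RegressionResult


class TestMeanQualityAtStops:
    def test_uniform_field_returns_its_value(self):
        spec = GridSpec(30, 30)
        q = QualityRaster(spec, np.full((30, 30), 0.7))
        stops = [SurveyStop("s1", 450.0, -450.0), SurveyStop("s2", 200.0, -600.0)]
        out = mean_quality_at_stops(q, stops)
        np.testing.assert_allclose(out["mean_quality"], 0.7)

    def test_halfplane_boundary_matches_pixel_enumeration(self):
        # left half 1.0, right half 0.0; stop centred on the boundary
        spec = GridSpec(40, 40)
        vals = np.zeros((40, 40))
        vals[:, :20] = 1.0
        q = QualityRaster(spec, vals)
        stop = SurveyStop("s", 600.0, -600.0)  # x=600 = boundary between cols 19/20
        got = mean_quality_at_stops(q, [stop])["mean_quality"].iloc[0]
        X, Y = spec.cell_centers()
        inside = (X - 600.0) ** 2 + (Y + 600.0) ** 2 <= 400.0**2
        expected = vals[inside].mean()
        assert got == pytest.approx(expected)
        assert expected == pytest.approx(0.5)  # symmetric pixel-centre counting

    def test_tiny_radius_returns_containing_pixel_value(self):
        spec = GridSpec(5, 5)
        vals = np.arange(25, dtype=float).reshape(5, 5) / 25
        q = QualityRaster(spec, vals)
        stop = SurveyStop("s", 75.0, -75.0, buffer_radius=5.0)
        got = mean_quality_at_stops(q, [stop])["mean_quality"].iloc[0]
        assert got == pytest.approx(vals[2, 2])

    def test_nodata_excluded_and_empty_buffer_flagged(self):
        spec = GridSpec(5, 5)
        vals = np.full((5, 5), np.nan)
        vals[0, 0] = 0.4
        q = QualityRaster(spec, vals)
        near = SurveyStop("near", 15.0, -15.0, buffer_radius=40.0)
        far = SurveyStop("far", 120.0, -120.0, buffer_radius=40.0)
        out = mean_quality_at_stops(q, [near, far])
        assert out.loc[0, "mean_quality"] == pytest.approx(0.4)
        assert bool(out.loc[1, "missing"]) is True


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-100.0, 2, 100) == pytest.approx(204.0 + 12.0 / 97.0)

    def test_zero_parameters_reduces_to_deviance(self):
        assert aicc(-50.0, 0, 30) == 100.0

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 3
        assert aicc(-100.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_small_n_undefined(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitNegbin:
    def test_constant_covariate_detected(self):
        counts = np.arange(20)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_negbin(counts, np.full(20, 0.5))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_negbin(np.arange(5), np.arange(5.0))

    def test_recovers_generating_parameters(self):
        cfg = CountModelConfig(beta0=1.0, beta1=1.76, theta=1.5, n_stops=2000, seed=42)
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 1, cfg.n_stops)
        y = generate_counts(x, cfg)
        res = fit_negbin(y, x)
        assert res.converged
        assert res.ci_low <= 1.76 <= res.ci_high
        assert res.beta0 == pytest.approx(1.0, abs=0.3)
        assert res.theta == pytest.approx(1.5, rel=0.25)
        assert res.K == 3  # intercept + slope + dispersion

    def test_poisson_data_gives_near_zero_dispersion(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 1500)
        y = rng.poisson(np.exp(0.5 + 1.0 * x))
        res = fit_negbin(y, x)
        assert res.alpha < 0.05  # variance ≈ mean
        # NB log-likelihood approaches the Poisson one in this limit
        import statsmodels.api as sm

        pois = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert res.log_likelihood == pytest.approx(pois.llf, abs=2.0)

    def test_null_model_has_two_parameters(self):
        y = generate_counts(np.zeros(500), CountModelConfig(seed=1, n_stops=500))
        res = fit_negbin(y)
        assert res.K == 2 and res.beta1 is None
        assert res.aicc >= -2 * res.log_likelihood + 2 * res.K  # AICc >= AIC


class TestSelectModel:
    @staticmethod
    def _result(name, ll, K=3, n=100):
        return RegressionResult(
            model_name=name, n=n, K=K, log_likelihood=ll, aicc=aicc(ll, K, n), beta0=0.0
        )

    def test_weights_from_delta_aicc(self):
        a = self._result("A", ll=-2.0)
        b = self._result("B", ll=-4.0)  # AICc difference of exactly 4
        table = select_model([a, b])
        assert table.model.tolist() == ["A", "B"]
        np.testing.assert_allclose(table.delta_aicc, [0.0, 4.0])
        np.testing.assert_allclose(table.weight, [0.8808, 0.1192], atol=5e-5)

    def test_identical_fits_share_weight_equally(self):
        table = select_model([self._result("A", -5.0), self._result("B", -5.0)])
        np.testing.assert_allclose(table.weight, [0.5, 0.5])

    def test_different_n_rejected(self):
        with pytest.raises(ValueError, match="different n"):
            select_model([self._result("A", -5.0, n=100), self._result("B", -5.0, n=90)])

    def test_quality_model_beats_null_on_simulated_counts(self):
        cfg = CountModelConfig(beta0=1.0, beta1=1.76, theta=1.5, n_stops=2000, seed=9)
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, cfg.n_stops)
        y = generate_counts(x, cfg)
        table = select_model([fit_negbin(y), fit_negbin(y, x, model_name="Quality")])
        assert table.model.iloc[0] == "Quality"
        assert table.delta_aicc.iloc[1] > 2.0


class TestPseudoR2:
    def test_fit_equal_to_null_gives_zero(self):
        a = RegressionResult("Null", 100, 2, -50.0, aicc(-50.0, 2, 100), 0.0)
        assert pseudo_r2(a, a) == 0.0

    def test_matches_hand_computed_formula(self):
        n, ll0, ll1 = 50, -120.0, -100.0
        fitted = RegressionResult("Q", n, 3, ll1, aicc(ll1, 3, n), 0.0)
        null = RegressionResult("Null", n, 2, ll0, aicc(ll0, 2, n), 0.0)
        cs = 1 - np.exp(2 * (ll0 - ll1) / n)
        expected = cs / (1 - np.exp(2 * ll0 / n))
        assert pseudo_r2(fitted, null) == pytest.approx(expected)
        assert pseudo_r2(fitted, null, method="mcfadden") == pytest.approx(1 - ll1 / ll0)

    def test_nagelkerke_bounded_and_ordered(self):
        # a better fit yields a larger pseudo-R², approaching 1
        n, ll0 = 100, -300.0
        null = RegressionResult("Null", n, 2, ll0, aicc(ll0, 2, n), 0.0)
        values = []
        for ll1 in (-250.0, -150.0, -20.0, -0.01):
            fitted = RegressionResult("Q", n, 3, ll1, aicc(ll1, 3, n), 0.0)
            values.append(pseudo_r2(fitted, null))
        assert all(0 <= v <= 1 for v in values)
        assert values == sorted(values)
        assert values[-1] > 0.99

    def test_worse_than_null_clamps_to_zero(self, caplog):
        n = 40
        fitted = RegressionResult("Q", n, 3, -60.0, aicc(-60.0, 3, n), 0.0)
        null = RegressionResult("Null", n, 2, -55.0, aicc(-55.0, 2, n), 0.0)
        with caplog.at_level("WARNING"):
            assert pseudo_r2(fitted, null) == 0.0
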