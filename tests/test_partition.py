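"""Regression, relative weights (with LMG oracle), VIF, and per-site
attribution of size control."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ostrea.growth import GrowthCurveParams, compute_residuals, fit_growth_curve
from ostrea.partition import (
    compute_vif,
    fit_regression,
    lmg_weights,
    partition_by_site,
    relative_weights,
)
from ostrea.simulate import ScenarioConfig, simulate_assemblage


def _correlated_pair(rng, r, n):
    x1 = rng.normal(size=n)
    x2 = r * x1 + np.sqrt(1 - r * r) * rng.normal(size=n)
    return x1, x2


class TestFitRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        age = rng.integers(1, 15, 50).astype(float)
        resid = rng.normal(size=50)
        y = 2.0 * age + resid
        s = fit_regression(y, {"age": age, "growth": resid})
        assert s.r_squared == pytest.approx(1.0)
        assert s.coef["age"] == pytest.approx(2.0)
        assert s.coef["growth"] == pytest.approx(1.0)

    def test_null_response_has_no_fit(self):
        rng = np.random.default_rng(0)
        s = fit_regression(
            rng.normal(size=200),
            {"a": rng.normal(size=200), "b": rng.normal(size=200)},
        )
        assert s.r_squared < 0.05
        assert s.p_overall > 0.05

    def test_zscored_inputs_make_raw_equal_standardized(self):
        rng = np.random.default_rng(2)
        x1, x2 = _correlated_pair(rng, 0.4, 100)
        y = x1 + 0.5 * x2 + rng.normal(size=100)
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        s = fit_regression(z(y), {"a": z(x1), "b": z(x2)})
        for name in ("a", "b"):
            assert s.coef[name] == pytest.approx(s.coef_standardized[name])

    def test_standardized_slopes_invariant_to_rescaling(self):
        rng = np.random.default_rng(3)
        x1, x2 = _correlated_pair(rng, 0.3, 150)
        y = x1 - x2 + rng.normal(size=150)
        a = fit_regression(y, {"a": x1, "b": x2})
        b = fit_regression(y * 3.0, {"a": 100 * x1 + 5, "b": 0.01 * x2})
        for name in ("a", "b"):
            assert a.coef_standardized[name] == pytest.approx(
                b.coef_standardized[name]
            )

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_regression([1.0, 2.0, 3.0, 4.0, 5.0],
                           {"a": [1.0] * 5, "b": [1, 2, 3, 4, 5.0]})


class TestRelativeWeights:
    def test_unnormalized_weights_sum_to_r_squared(self):
        rng = np.random.default_rng(10)
        for r in (-0.8, 0.0, 0.5):
            x1, x2 = _correlated_pair(rng, r, 250)
            y = x1 + 2 * x2 + rng.normal(size=250)
            rw = relative_weights(y, {"a": x1, "b": x2})
            assert rw.raw.sum() == pytest.approx(rw.r_squared, abs=1e-10)
            assert rw.pct.sum() == pytest.approx(100.0)
            assert np.all(rw.raw >= 0)

    def test_orthogonal_predictors_give_squared_correlations(self):
        rng = np.random.default_rng(20)
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        x2 = x2 - x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal, centered
        y = 1.5 * x1 + 0.5 * x2 + rng.normal(size=400)
        rw = relative_weights(y, {"a": x1, "b": x2})
        r1 = np.corrcoef(x1, y)[0, 1] ** 2
        r2 = np.corrcoef(x2, y)[0, 1] ** 2
        assert rw.raw[0] == pytest.approx(r1, abs=1e-6)
        assert rw.raw[1] == pytest.approx(r2, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_two_predictor_weights_match_lmg_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        r = rng.uniform(-0.9, 0.9)
        x1, x2 = _correlated_pair(rng, r, 300)
        b1, b2 = rng.uniform(-2, 2, 2)
        y = b1 * x1 + b2 * x2 + rng.normal(size=300)
        rw = relative_weights(y, {"a": x1, "b": x2})
        lmg = lmg_weights(y, {"a": x1, "b": x2})
        lmg_pct = 100 * lmg / lmg.sum()
        assert np.max(np.abs(rw.pct - lmg_pct)) < 2.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(30)
        x1, x2 = _correlated_pair(rng, 0.6, 200)
        y = x1 + x2 + rng.normal(size=200)
        a = relative_weights(y, {"a": x1, "b": x2})
        b = relative_weights(5 * y - 2, {"a": -3 * x1 + 7, "b": 0.2 * x2})
        assert a.pct == pytest.approx(b.pct)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_rank_deficient_predictors_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="rank"):
            relative_weights(np.random.default_rng(0).normal(size=20),
                             {"a": x, "b": 2 * x})


class TestVif:
    def test_orthogonal_predictors_give_unit_vif(self):
        rng = np.random.default_rng(40)
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        x2 = x2 - x1 * (x1 @ x2) / (x1 @ x1)
        vif = compute_vif({"a": x1, "b": x2})
        assert vif["a"] == pytest.approx(1.0, abs=1e-9)
        assert vif["b"] == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_for_known_correlation(self):
        rng = np.random.default_rng(41)
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        # construct empirical correlation exactly 0.6 via Gram-Schmidt
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        x1 = z(x1)
        e = z(x2 - x1 * np.dot(x1, x2) / np.dot(x1, x1))
        x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * e
        vif = compute_vif({"a": x1, "b": x2})
        assert vif["a"] == pytest.approx(1 / (1 - 0.36), abs=1e-6)
        assert vif["b"] == pytest.approx(1.5625, abs=1e-6)

    def test_duplicated_predictor_flagged_infinite(self):
        x = np.random.default_rng(42).normal(size=50)
        vif = compute_vif({"a": x, "b": x})
        assert np.isinf(vif).all()

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            compute_vif({"a": np.arange(10.0)})


# designed single-site scenarios where exactly one causal channel varies
PURE_HARVEST = ScenarioConfig(
    seed=3, n_sites=1, layers_per_site=8, n_per_layer=60,
    harvest_pressure=tuple(np.linspace(0.15, 0.8, 8)), env_multiplier=1.0,
    individual_growth_cv=0.1, measurement_sd=0.3,
    missing_age_rate=0.0, missing_hinge_rate=0.0,
)
PURE_ENVIRONMENT = ScenarioConfig(
    seed=3, n_sites=1, layers_per_site=8, n_per_layer=60,
    true_params=GrowthCurveParams(10.0, 1.0, 0.0),  # near-asymptote harvesting
    harvest_pressure=0.85, env_multiplier=tuple(np.linspace(1.8, 0.3, 8)),
    individual_growth_cv=0.3, measurement_sd=0.3, max_age=8,
    missing_age_rate=0.0, missing_hinge_rate=0.0,
)


class TestPartitionBySite:
    def _weights(self, config):
        asm, _ = simulate_assemblage(config)
        fit = fit_growth_curve(asm)
        resid = compute_residuals(fit.params, asm)
        return partition_by_site(asm, resid)

    def test_age_driven_site_attributed_to_age(self):
        table = self._weights(PURE_HARVEST)
        assert table["weight_age_pct"].iloc[0] > 80

    def test_environment_driven_site_attributed_to_growth(self):
        table = self._weights(PURE_ENVIRONMENT)
        assert table["weight_growth_pct"].iloc[0] > 80

    def test_weights_sum_to_hundred_and_reliability_flagged(self):
        table = self._weights(PURE_HARVEST)
        assert table["weight_age_pct"].iloc[0] + table[
            "weight_growth_pct"
        ].iloc[0] == pytest.approx(100.0)
        assert bool(table["reliable"].iloc[0])
        # short sequence fails the reliability thresholds
        short = dataclasses.replace(PURE_HARVEST, layers_per_site=3, n_per_layer=5)
        short_table = self._weights(
            dataclasses.replace(short, harvest_pressure=tuple([0.2, 0.45, 0.8]))
        )
        assert not bool(short_table["reliable"].iloc[0])

    def test_sites_without_usable_records_skipped(self):
        asm, _ = simulate_assemblage(
            dataclasses.replace(PURE_HARVEST, n_per_layer=1, layers_per_site=4,
                                harvest_pressure=0.3)
        )
        fit_input = pd.DataFrame(
            {"shell_id": asm.records["shell_id"][:2],
             "residual_mm": [0.1, -0.1]}
        )
        assert partition_by_site(asm, fit_input).empty
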