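"""Period comparisons: Mann-Whitney (exact and asymptotic), spread tests,
and the Bonferroni correction."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from ostrea.compare import (
    bonferroni_adjust,
    compare_by_period,
    levene_test,
    mann_whitney,
    significance_stars,
    variance_f_test,
)

from conftest import make_assemblage


def mw_oracle(a, b):
    """Independent exact two-sided Mann-Whitney by pairwise counting over
    every assignment of pooled values to the first group."""
    pooled = list(a) + list(b)
    n_a, n = len(a), len(pooled)

    def u_of(group_a_vals, group_b_vals):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in group_a_vals
            for y in group_b_vals
        )

    mu = n_a * (n - n_a) / 2.0
    u_obs = u_of(a, b)
    hits = 0
    for idx in combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        if abs(u_of(ga, gb) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / comb(n, n_a)


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.statistic == 12.5  # n^2/2 with mid-ranks
        assert res.p_raw == pytest.approx(1.0)
        assert res.stars == 0

    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1)  # 2/20 assignments as extreme

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_small_sample_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7, 2)
        a = rng.integers(1, 6, n_a)  # heavy ties on purpose
        b = rng.integers(1, 6, n_b)
        res = mann_whitney(a, b)
        u_exp, p_exp = mw_oracle(a, b)
        assert res.statistic == pytest.approx(u_exp)
        assert res.p_raw == pytest.approx(p_exp)

    @pytest.mark.parametrize("n", [5, 60])
    def test_exchangeability_of_two_sided_p(self, n):
        rng = np.random.default_rng(n)
        a, b = rng.normal(size=n), rng.normal(1.0, 1.0, size=n)
        assert mann_whitney(a, b).p_raw == pytest.approx(mann_whitney(b, a).p_raw)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_detects_location_shift_large_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.5, 1, 200)
        assert mann_whitney(a, b).p_raw < 0.001


class TestSpreadTests:
    def test_equal_samples_give_f_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = variance_f_test(x, x)
        assert res.statistic == 1.0
        assert res.p_raw == pytest.approx(1.0)

    def test_known_spread_ratio_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0, 3, 100)
        assert variance_f_test(a, b).p_raw < 0.001
        assert levene_test(a, b).p_raw < 0.001

    def test_f_is_symmetric_in_group_order(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 40)
        assert variance_f_test(a, b).p_raw == pytest.approx(
            variance_f_test(b, a).p_raw
        )

    def test_levene_identical_samples(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert levene_test(x, x).p_raw == pytest.approx(1.0)

    def test_levene_centering_options_differ_on_skewed_data(self):
        rng = np.random.default_rng(9)
        a = np.exp(rng.normal(size=60))  # skewed
        b = rng.normal(1.0, 1.0, 60)
        p_mean = levene_test(a, b, center="mean").p_raw
        p_median = levene_test(a, b, center="median").p_raw
        assert 0 <= p_mean <= 1 and 0 <= p_median <= 1
        assert p_mean != p_median
        with pytest.raises(ValueError):
            levene_test(a, b, center="mode")

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 1.0], [2.0, 2.0])


class TestBonferroni:
    def test_single_test_unchanged(self):
        assert bonferroni_adjust([0.01]) == pytest.approx([0.01])

    def test_direct_arithmetic(self):
        assert bonferroni_adjust([0.01, 0.04, 0.2]) == pytest.approx(
            [0.03, 0.12, 0.6]
        )

    def test_capped_at_one(self):
        assert bonferroni_adjust([0.5, 0.9], family_size=6) == pytest.approx(
            [1.0, 1.0]
        )

    def test_monotone_and_never_decreases(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(size=20))
        adj = bonferroni_adjust(p, family_size=20)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


@pytest.mark.parametrize(
    "p,stars", [(0.2, 0), (0.049, 1), (0.009, 2), (0.0009, 3)]
)
def test_significance_star_mapping(p, stars):
    assert significance_stars(p) == stars


def _two_period_assemblage(rng, shift_neolithic_age=0, n=400):
    """Two sites, both periods; optional stochastic age shift in the Neolithic."""
    ages_m = rng.geometric(0.3, n).clip(1, 20)
    ages_n = np.maximum(rng.geometric(0.3, n).clip(1, 20) + shift_neolithic_age, 1)
    hinges = np.round(rng.uniform(2, 20, 2 * n), 1)
    return make_assemblage(
        hinges=hinges,
        ages=np.concatenate([ages_m, ages_n]),
        periods=["Mesolithic"] * n + ["Neolithic"] * n,
        sites=(["A", "B"] * (n // 2)) * 2,
    )


class TestCompareByPeriod:
    def test_identical_period_distributions_not_significant(self):
        vals_h = [2.0, 4.0, 6.0, 8.0, 10.0] * 8
        vals_a = [1, 2, 3, 4, 5] * 8
        asm = make_assemblage(
            hinges=vals_h + vals_h,
            ages=vals_a + vals_a,
            periods=["Mesolithic"] * 40 + ["Neolithic"] * 40,
        )
        out = compare_by_period(asm, variables=["hinge", "age"])
        pooled = out[out["level"] == "pooled"]
        assert (pooled["stars"] == 0).all()
        mw = pooled[pooled["test"] == "mann_whitney_u"]
        assert (mw["p_adjusted"] > 0.9).all()

    def test_stochastically_younger_neolithic_detected(self):
        rng = np.random.default_rng(12)
        asm = _two_period_assemblage(rng, shift_neolithic_age=-1, n=500)
        out = compare_by_period(asm, variables=["age"])
        pooled = out[(out["level"] == "pooled") & (out["variable"] == "age")]
        assert pooled["p_raw"].iloc[0] < 0.001

    def test_only_sites_with_both_periods_qualify(self):
        rng = np.random.default_rng(6)
        n = 200
        # 10 sites; only 6 get Neolithic shells
        sites = [f"S{i % 10}" for i in range(n)] + [f"S{i % 6}" for i in range(n)]
        asm = make_assemblage(
            hinges=np.round(rng.uniform(2, 20, 2 * n), 1),
            ages=rng.integers(1, 10, 2 * n),
            periods=["Mesolithic"] * n + ["Neolithic"] * n,
            sites=sites,
        )
        out = compare_by_period(asm, variables=["hinge"])
        site_rows = out[out["level"] == "site"]
        assert len(site_rows) == 6
        # Bonferroni family is the six site tests of this variable
        assert np.allclose(
            site_rows["p_adjusted"], np.minimum(1.0, 6 * site_rows["p_raw"])
        )

    def test_missing_period_raises(self):
        asm = make_assemblage(hinges=[2.0, 3.0], ages=[1, 2])
        with pytest.raises(ValueError, match="period"):
            compare_by_period(asm)

    def test_residual_variable_needs_residual_table(self):
        rng = np.random.default_rng(13)
        asm = _two_period_assemblage(rng, n=50)
        resid = pd.DataFrame(
            {
                "shell_id": asm.records["shell_id"],
                "residual_mm": rng.normal(0, 1, asm.n_total),
            }
        )
        out = compare_by_period(asm, residuals=resid)
        assert "residual" in set(out["variable"])
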