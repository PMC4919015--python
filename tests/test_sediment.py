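"""Sediment-statistics contracts: rank tests, DSCF Monte Carlo, trend fits."""

import math

import numpy as np
import pytest

from seagrass_metals import (
    SimulationConfig,
    annual_summary,
    d13c_trend,
    experienced_temperature_days,
    kruskal_wallis,
    simulate_sediment_cores,
    steel_dwass_mc,
)
from seagrass_metals.sediment import dscf_pair_statistic, significance_stars

from ._oracles import dscf_exact_pvalues, kruskal_statistic_reference


class TestAnnualSummary:
    def test_constant_values(self):
        s = annual_summary(np.full(8, 3.7))
        assert s["mean"] == pytest.approx(3.7)
        assert s["log_sd"] == 0.0

    def test_geometric_mean_arithmetic(self):
        s = annual_summary(np.array([1.0, math.e**2]))
        assert s["mean"] == pytest.approx(math.e)

    def test_lognormal_geometric_mean(self, rng):
        v = np.exp(rng.standard_normal(10_000))
        assert annual_summary(v)["mean"] == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            annual_summary(np.array([1.0, 0.0]))


class TestKruskalWallis:
    def test_fully_tied_degenerate(self):
        r = kruskal_wallis([np.full(5, 2.0), np.full(4, 2.0), np.full(6, 2.0)])
        assert r == {"chi2": 0.0, "df": 2.0, "p": 1.0}

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 3.0, 5.0], [2.0, 4.0], [6.0, 7.0, 8.0]],
            [[1.0, 1.0, 2.0], [2.0, 3.0], [3.0, 3.0, 4.0]],  # ties
            [[5.0, 2.0], [9.0, 1.0, 4.0], [3.0, 8.0]],
        ],
    )
    def test_statistic_matches_reference_formula(self, groups):
        arrs = [np.array(g) for g in groups]
        r = kruskal_wallis(arrs)
        assert r["chi2"] == pytest.approx(kruskal_statistic_reference(arrs), rel=1e-10)
        assert r["df"] == len(groups) - 1

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.lognormal(m, 0.5, 8) for m in (0.0, 0.3, 0.8)]
        raw = kruskal_wallis(groups)
        logged = kruskal_wallis([np.log(g) for g in groups])
        assert raw["chi2"] == pytest.approx(logged["chi2"], rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestSteelDwass:
    def test_mc_matches_exhaustive_enumeration(self, rng):
        groups = [rng.normal(0, 1, 3), rng.normal(1.0, 1, 3), rng.normal(0, 1, 4)]
        res = steel_dwass_mc(groups, n_iter=10_000, seed=3)
        exact = dscf_exact_pvalues(groups)
        for p_mc, p_ex in zip(res.p_values, exact):
            se = math.sqrt(p_ex * (1 - p_ex) / 10_000) + 1e-4
            assert abs(p_mc - p_ex) < 3 * se

    def test_pair_statistic_matches_oracle_formula(self, rng):
        from ._oracles import _pair_stat

        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 9)
        assert dscf_pair_statistic(a, b) == pytest.approx(_pair_stat(a, b), rel=1e-12)

    def test_identical_groups_rarely_significant(self, rng):
        # quick type-I sanity at reduced repetition count (full calibration
        # runs in the acceptance suite)
        rejections = 0
        for rep in range(40):
            groups = [rng.standard_normal(10) for _ in range(3)]
            res = steel_dwass_mc(groups, n_iter=2_000, seed=rep)
            rejections += any(p < 0.05 for p in res.p_values)
        assert rejections <= 7

    def test_large_offset_detected(self, rng):
        # leaf/epiphyte lead sits ~20-fold below surface sediment
        leaf = rng.lognormal(math.log(1.0), 0.3, 10)
        epi = rng.lognormal(math.log(1.0), 0.3, 10)
        surface = rng.lognormal(math.log(20.0), 0.3, 12)
        res = steel_dwass_mc(
            {"leaf": leaf, "epiphytes": epi, "surface": surface}, n_iter=10_000, seed=1
        )
        p = dict(zip(res.pairs, res.p_values))
        assert p[("leaf", "surface")] < 0.001
        assert p[("epiphytes", "surface")] < 0.001
        assert p[("leaf", "epiphytes")] > 0.05

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.lognormal(m, 0.4, 6) for m in (0.0, 0.5, 1.0)]
        a = steel_dwass_mc(groups, n_iter=2_000, seed=9)
        b = steel_dwass_mc([np.log(g) for g in groups], n_iter=2_000, seed=9)
        assert a.p_values == b.p_values
        assert a.statistics == pytest.approx(b.statistics)

    def test_seeded_reproducibility(self, rng):
        groups = [rng.standard_normal(8) for _ in range(3)]
        a = steel_dwass_mc(groups, n_iter=1_000, seed=11)
        b = steel_dwass_mc(groups, n_iter=1_000, seed=11)
        assert a.p_values == b.p_values

    def test_low_iteration_count_refused(self, rng):
        with pytest.raises(ValueError, match="unstable"):
            steel_dwass_mc([rng.standard_normal(5)] * 3, n_iter=50)


class TestTrendFit:
    def test_flat_noiseless_slope_zero(self, default_config):
        import dataclasses

        tc = default_config.sediment_trend
        flat = {
            pool: {el: (p[0], 0.0, 0.0) for el, p in els.items()}
            for pool, els in tc.params.items()
        }
        cfg = SimulationConfig(
            seed=2, sediment_trend=dataclasses.replace(tc, params=flat)
        )
        fit = d13c_trend(simulate_sediment_cores(cfg), "zn", "eelgrass")
        # residuals are exactly zero, so the t statistic is 0/0; the slope
        # estimate must vanish and no positive trend may be declared
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert not fit.significant_positive

    def test_vegetated_pool_trend_detected_reference_flat(self, default_config):
        sed = simulate_sediment_cores(default_config)
        eel = d13c_trend(sed, "cu", "eelgrass")
        ref = d13c_trend(sed, "cu", "reference")
        assert eel.significant_positive
        assert not ref.significant_positive

    def test_estimates_match_normal_equations(self, rng):
        import pandas as pd

        n = 15
        d13c = rng.uniform(-22, -10, n)
        y = np.exp(1.0 + 0.1 * d13c + 0.2 * rng.standard_normal(n))
        df = pd.DataFrame({"pool": "eelgrass", "d13c": d13c, "cu": y})
        fit = d13c_trend(df, "cu", "eelgrass")
        ly = np.log(y)
        slope = np.cov(d13c, ly, ddof=1)[0, 1] / np.var(d13c, ddof=1)
        intercept = ly.mean() - slope * d13c.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_slope_recovery_rate(self, rng):
        # generated slope recovered within 3 SE in nearly all repetitions
        import pandas as pd

        hits = 0
        for rep in range(50):
            d13c = rng.uniform(-22, -10, 12)
            y = np.exp(1.5 + 0.06 * d13c + 0.15 * rng.standard_normal(12))
            df = pd.DataFrame({"pool": "eelgrass", "d13c": d13c, "cu": y})
            fit = d13c_trend(df, "cu", "eelgrass")
            se = 0.15 / (d13c.std(ddof=1) * math.sqrt(12))
            hits += abs(fit.slope - 0.06) < 3 * se
        assert hits >= 45

    def test_constant_d13c_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"pool": "eelgrass", "d13c": [-15.0] * 5, "cu": [1.0] * 5})
        with pytest.raises(ValueError, match="constant"):
            d13c_trend(df, "cu", "eelgrass")


class TestExperiencedTemperature:
    @pytest.mark.parametrize(
        "interval,factor,expected", [(14.9, 2.5, 37), (10, 2, 20), (1, 1, 1)]
    )
    def test_worked_examples(self, interval, factor, expected):
        assert experienced_temperature_days(interval, factor) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            experienced_temperature_days(0.0, 2.5)


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.02) == "*"
    assert significance_stars(0.2) == ""
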