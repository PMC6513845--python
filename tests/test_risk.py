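"""Daily-intake and ILCR Monte-Carlo simulations and risk classification."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pahrisk import (
    LognormalSpec,
    NormalSpec,
    RiskCategory,
    RiskModel,
    classify_risk,
    percentile_95,
    quantile,
    simulate_di,
    simulate_ilcr,
)
from .conftest import HOURS_70_YEARS, make_group, point_et, point_lognormal


class TestDailyIntake:
    def test_all_degenerate_point_case(self):
        """TEQ 2.4 ng/m^3, IR 10 m^3/day, ET 12 h/day -> DI = 12.0 ng/day."""
        res = simulate_di(point_lognormal(2.4), make_group(), n=100, seed=0)
        assert np.allclose(res.samples, 2.4 * 10.0 * 12.0 / 24.0)
        assert res.median == pytest.approx(12.0)
        assert res.iqr == pytest.approx(0.0)

    def test_full_day_limit_reduces_to_teq_times_ir(self):
        teq = LognormalSpec(0.3, 0.5)
        group = make_group(et=point_et(24.0))
        res = simulate_di(teq, group, n=2000, seed=1)
        assert np.allclose(res.di, res.draws["teq"].to_numpy() * group.ir_m3_day)

    def test_median_matches_scaled_lognormal_closed_form(self):
        """With point IR/ET, median DI -> exp(mu) * IR * ET / 24."""
        teq = LognormalSpec(0.8, 0.6)
        group = make_group(et=point_et(6.0))
        res = simulate_di(teq, group, n=100_000, seed=2)
        expected = math.exp(0.8) * group.ir_m3_day * 6.0 / 24.0
        assert res.median == pytest.approx(expected, rel=0.02)


class TestILCR:
    def test_all_degenerate_scalar_oracle(self):
        """Every sample equals the hand-computed Eq.-3 scalar.

        TEQ 1 ng/m^3 (= 1000 pg/m^3), IR 10, CF 1e-9, ED 70, ET 24, EF 365,
        CSF 3.14, BW 60, AT 70 y in hours.
        """
        group = make_group(et=point_et(24.0))
        res = simulate_ilcr(point_lognormal(1.0), group, n=500, seed=0)
        expected = (1000.0 * 10.0 * 1e-9 * 70.0 * 24.0 * 365.0 * 3.14) / (
            60.0 * 70.0 * 365.0 * 24.0
        )
        assert expected == pytest.approx(5.2333e-7, rel=1e-4)  # independent arithmetic
        assert np.allclose(res.ilcr, expected, rtol=1e-12)

    def test_linearity_in_teq(self):
        g = make_group()
        a = simulate_ilcr(point_lognormal(1.0), g, n=200, seed=3)
        b = simulate_ilcr(point_lognormal(2.0), g, n=200, seed=3)
        assert np.allclose(b.ilcr, 2.0 * a.ilcr)

    def test_reciprocal_in_adult_bw(self):
        a = simulate_ilcr(point_lognormal(1.0), make_group(bw=60.0), n=200, seed=3)
        b = simulate_ilcr(point_lognormal(1.0), make_group(bw=120.0), n=200, seed=3)
        assert np.allclose(b.ilcr, 0.5 * a.ilcr)

    def test_teq_only_stochastic_matches_closed_form_quantile(self):
        """With only TEQ stochastic, 95th ILCR = constant * q95(TEQ)."""
        teq = LognormalSpec(0.5, 0.7)
        group = make_group()
        res = simulate_ilcr(teq, group, n=100_000, seed=4)
        const = (
            1000.0 * group.ir_m3_day * group.cf_mg_per_pg * group.ed_years
            * 12.0 * group.ef_days_year * 3.14 / (60.0 * group.at_hours)
        )
        assert res.p95 == pytest.approx(const * quantile(teq, 0.95), rel=0.02)

    def test_bw_drawn_only_for_children(self, stochastic_child_group):
        child = simulate_ilcr(LognormalSpec(0.0, 0.3), stochastic_child_group, n=500, seed=5)
        adult = simulate_ilcr(LognormalSpec(0.0, 0.3), make_group(), n=500, seed=5)
        assert child.draws["bw"].nunique() > 1
        assert adult.draws["bw"].nunique() == 1

    def test_di_ilcr_rank_consistency(self):
        """With degenerate CSF and BW, DI and ILCR are perfectly rank
        correlated through their shared TEQ*ET draws."""
        teq = LognormalSpec(0.2, 0.6)
        group = make_group(et=NormalSpec(6.0, 2.0, lower=0.0, upper=24.0))
        res = RiskModel(teq, group).fit(5000, seed=6)
        assert np.array_equal(np.argsort(res.di), np.argsort(res.ilcr))

    @pytest.mark.parametrize(
        "param,direction",
        [("ir", +1), ("ed", +1), ("ef", +1), ("bw", -1), ("at_hours", -1)],
    )
    def test_p95_monotone_in_exposure_factors(self, param, direction):
        """Paired simulations sharing seeds: the 95th ILCR moves with each
        factor in the direction the formula dictates."""
        teq = LognormalSpec(0.4, 0.5)
        base = dict(ir=10.0, ed=30.0, ef=240.0, bw=60.0, at_hours=HOURS_70_YEARS)
        lo = simulate_ilcr(teq, make_group(**base), n=4000, seed=7)
        bumped = dict(base)
        bumped[param] = base[param] * 1.5
        hi = simulate_ilcr(teq, make_group(**bumped), n=4000, seed=7)
        assert direction * (hi.p95 - lo.p95) > 0

    def test_p95_monotone_in_distribution_parameters(self):
        teq = LognormalSpec(0.4, 0.5)
        g_lo = make_group(et=NormalSpec(3.0, 1.0, lower=0, upper=24),
                          csf=point_lognormal(3.14))
        g_hi = make_group(et=NormalSpec(5.0, 1.0, lower=0, upper=24),
                          csf=point_lognormal(3.14))
        lo = simulate_ilcr(teq, g_lo, n=4000, seed=8)
        hi = simulate_ilcr(teq, g_hi, n=4000, seed=8)
        assert hi.p95 > lo.p95
        g_csf = make_group(et=NormalSpec(3.0, 1.0, lower=0, upper=24),
                           csf=point_lognormal(6.0))
        assert simulate_ilcr(teq, g_csf, n=4000, seed=8).p95 > lo.p95

    def test_seasonal_teq_ordering_propagates_to_di(self):
        """Winter > shoulder > summer TEQ specs produce the same ordering of
        median DI."""
        group = make_group(et=NormalSpec(4.0, 1.5, lower=0, upper=24))
        specs = {
            "winter": LognormalSpec(1.2, 0.5),
            "spring": LognormalSpec(0.5, 0.5),
            "summer": LognormalSpec(0.0, 0.5),
        }
        medians = {
            k: simulate_di(v, group, n=5000, seed=9).median for k, v in specs.items()
        }
        assert medians["winter"] > medians["spring"] > medians["summer"]


class TestPercentile:
    def test_type7_hand_check_1_to_100(self):
        g = make_group()
        res = simulate_ilcr(point_lognormal(1.0), g, n=100, seed=0)
        res = replace(res, ilcr=np.arange(1.0, 101.0))
        assert percentile_95(res) == pytest.approx(95.05)

    def test_constant_samples(self):
        res = simulate_ilcr(point_lognormal(1.0), make_group(), n=50, seed=0)
        assert percentile_95(res) == pytest.approx(res.ilcr[0])

    def test_single_sample_rejected(self):
        res = simulate_ilcr(point_lognormal(1.0), make_group(), n=1, seed=0)
        with pytest.raises(ValueError):
            percentile_95(res)


class TestRiskBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (4.8e-7, RiskCategory.ACCEPTABLE),
            (0.0, RiskCategory.ACCEPTABLE),
            (1e-6, RiskCategory.POTENTIAL),   # boundary belongs to potential
            (1e-5, RiskCategory.POTENTIAL),
            (1e-4, RiskCategory.POTENTIAL),   # boundary belongs to potential
            (2e-4, RiskCategory.CONCERN),
        ],
    )
    def test_band_assignment(self, value, band):
        assert classify_risk(value) is band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(-1e-9)

    def test_result_classify_uses_p95(self):
        res = simulate_ilcr(point_lognormal(1.0), make_group(), n=100, seed=0)
        assert res.classify() is classify_risk(res.p95)


class TestModelObject:
    def test_summary_contains_headline_statistics(self, stochastic_adult_group):
        res = RiskModel(LognormalSpec(0.5, 0.6), stochastic_adult_group).fit(2000, 1)
        s = res.summary()
        for col in ("median", "q1", "q3", "iqr", "p95", "risk_band", "seed"):
            assert col in s.columns
        assert s["n_iterations"].iloc[0] == 2000

    def test_from_teq_series_fits_log_scale(self):
        x = np.exp(np.random.default_rng(0).normal(0.7, 0.4, 5000))
        model = RiskModel.from_teq_series(x, make_group())
        assert model.teq.mu == pytest.approx(0.7, abs=0.03)
        assert model.teq.sigma == pytest.approx(0.4, abs=0.03)

    def test_from_teq_moments_round_trip(self):
        model = RiskModel.from_teq_moments(2.8, 2.8, make_group())
        assert model.teq.mean == pytest.approx(2.8, rel=1e-12)
        assert model.teq.sd == pytest.approx(2.8, rel=1e-9)

    def test_group_validation(self):
        with pytest.raises(ValueError):
            make_group(ir=-1.0)
        with pytest.raises(ValueError):
            make_group(ef=400.0)
        with pytest.raises(ValueError):
            make_group(et=NormalSpec(25.0, 1.0))

    def test_at_years_conversion(self):
        from pahrisk import PopulationGroup
        from pahrisk.congeners import PopulationStratum

        g = PopulationGroup.with_at_years(
            at_years=70.0,
            stratum=PopulationStratum("HZ", "adult", "male"),
            ir_m3_day=10.0,
            et=point_et(12.0),
            bw_kg=60.0,
            ed_years=70.0,
            ef_days_year=365.0,
        )
        assert g.at_hours == pytest.approx(70.0 * 365.0 * 24.0)
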