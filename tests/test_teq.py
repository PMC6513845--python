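"""TEQ computation, composition summaries, and diagnostic-ratio screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahrisk import (
    CONGENER_NAMES,
    TEFTable,
    classify_source,
    compute_teq,
    default_ratio_thresholds,
    diagnostic_ratios,
    nisbet_lagoy_tefs,
    ring_class_fractions,
    summarize_teq,
)
from pahrisk.teq import RATIO_NAMES, RatioThresholds
from .conftest import table_from_conc


@pytest.fixture(scope="module")
def tefs():
    return nisbet_lagoy_tefs(dba_tef=1.0)


class TestTEFTable:
    def test_bap_is_unity_and_all_present(self, tefs):
        assert tefs["BaP"] == 1.0
        assert set(tefs.tefs) == set(CONGENER_NAMES)
        assert all(v > 0 for v in tefs.tefs.values())

    def test_dba_is_configurable_not_hardcoded(self):
        assert nisbet_lagoy_tefs(dba_tef=5.0)["DBA"] == 5.0

    def test_bap_must_be_one(self, tefs):
        broken = dict(tefs.tefs)
        broken["BaP"] = 0.5
        with pytest.raises(ValueError, match="BaP"):
            TEFTable(broken)


class TestComputeTEQ:
    def test_pure_bap_defines_the_unit(self, tefs):
        out = compute_teq(table_from_conc({"BaP": 1.0}), tefs)
        assert out["teq_ng_m3"].iloc[0] == pytest.approx(1.0)

    def test_all_zero(self, tefs):
        out = compute_teq(table_from_conc({}), tefs)
        assert out["teq_ng_m3"].iloc[0] == 0.0

    def test_hand_summed_mixture(self, tefs):
        # 2.0*1 (BaP) + 10.0*0.1 (BaA) + 1.0*1 (DBA) = 4.0
        out = compute_teq(table_from_conc({"BaP": 2.0, "BaA": 10.0, "DBA": 1.0}), tefs)
        assert out["teq_ng_m3"].iloc[0] == pytest.approx(4.0, rel=1e-12)

    def test_missing_tef_names_congener(self):
        partial = {n: 0.001 for n in CONGENER_NAMES}
        partial["BaP"] = 1.0
        del partial["Chr"]
        with pytest.raises(ValueError, match="Chr"):
            TEFTable(partial)

    @settings(max_examples=25, deadline=None)
    @given(
        conc_a=st.dictionaries(st.sampled_from(CONGENER_NAMES), st.floats(0, 100), min_size=1),
        conc_b=st.dictionaries(st.sampled_from(CONGENER_NAMES), st.floats(0, 100), min_size=1),
        alpha=st.floats(0, 10),
        beta=st.floats(0, 10),
    )
    def test_linearity(self, tefs, conc_a, conc_b, alpha, beta):
        """TEQ(aA + bB) == a*TEQ(A) + b*TEQ(B) on aligned tables."""
        mix = {
            n: alpha * conc_a.get(n, 0.0) + beta * conc_b.get(n, 0.0)
            for n in CONGENER_NAMES
        }
        t_mix = compute_teq(table_from_conc(mix), tefs)["teq_ng_m3"].iloc[0]
        t_a = compute_teq(table_from_conc(conc_a), tefs)["teq_ng_m3"].iloc[0]
        t_b = compute_teq(table_from_conc(conc_b), tefs)["teq_ng_m3"].iloc[0]
        assert t_mix == pytest.approx(alpha * t_a + beta * t_b, rel=1e-9, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        conc=st.dictionaries(
            st.sampled_from(CONGENER_NAMES), st.floats(1e-3, 100), min_size=16, max_size=16
        )
    )
    def test_teq_bounded_by_tef_extremes(self, tefs, conc):
        teq = compute_teq(table_from_conc(conc), tefs)["teq_ng_m3"].iloc[0]
        s16 = sum(conc.values())
        assert min(tefs.tefs.values()) * s16 <= teq <= max(tefs.tefs.values()) * s16

    def test_scheme_swap_rescales_congenerwise(self, tefs):
        """Swapping TEF tables rescales exactly as an explicit loop oracle."""
        conc = {n: float(i + 1) for i, n in enumerate(CONGENER_NAMES)}
        other = nisbet_lagoy_tefs(dba_tef=5.0)
        t1 = compute_teq(table_from_conc(conc), tefs)["teq_ng_m3"].iloc[0]
        t2 = compute_teq(table_from_conc(conc), other)["teq_ng_m3"].iloc[0]
        oracle1 = sum(conc[n] * tefs.tefs[n] for n in CONGENER_NAMES)
        oracle2 = sum(conc[n] * other.tefs[n] for n in CONGENER_NAMES)
        assert t1 == pytest.approx(oracle1, rel=1e-12)
        assert t2 == pytest.approx(oracle2, rel=1e-12)


class TestSummarize:
    def _series(self, values, season="winter"):
        date = {"winter": "2015-01-12", "summer": "2015-07-12"}[season]
        frames = [
            compute_teq(
                table_from_conc({"BaP": v}, sample_id=f"s{i}-{season}", date=date),
                nisbet_lagoy_tefs(),
            )
            for i, v in enumerate(values)
        ]
        return pd.concat(frames, ignore_index=True)

    def test_constant_series(self):
        out = summarize_teq(self._series([2.5, 2.5, 2.5]))
        assert out["mean"].iloc[0] == pytest.approx(2.5)
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_two_sample_hand_computation(self):
        out = summarize_teq(self._series([1.0, 3.0]))
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sd"].iloc[0] == pytest.approx(math.sqrt(2.0))

    def test_annual_pools_seasons(self):
        series = pd.concat(
            [self._series([1.0, 3.0], "winter"), self._series([2.0], "summer")],
            ignore_index=True,
        )
        out = summarize_teq(series, by="annual")
        assert out["n"].iloc[0] == 3
        assert out["mean"].iloc[0] == pytest.approx(2.0)

    def test_empty_series_warns(self):
        with pytest.warns(UserWarning):
            out = summarize_teq(self._series([1.0]).iloc[0:0])
        assert out.empty


class TestRingFractions:
    def test_only_bap_gives_full_high_share(self):
        out = ring_class_fractions(table_from_conc({"BaP": 1.0}))
        assert out["high_ring_share"].iloc[0] == pytest.approx(1.0)

    def test_equal_low_high_mass(self):
        out = ring_class_fractions(table_from_conc({"Nap": 1.0, "BaP": 1.0}))
        assert out["high_ring_share"].iloc[0] == pytest.approx(0.5)
        assert out["low_ring_share"].iloc[0] == pytest.approx(0.5)

    def test_shares_sum_to_one(self):
        out = ring_class_fractions(
            table_from_conc({n: float(i + 1) for i, n in enumerate(CONGENER_NAMES)})
        )
        total = out["high_ring_share"] + out["low_ring_share"]
        assert total.iloc[0] == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ring_class_fractions(table_from_conc({"BaP": 1.0}).iloc[0:0])


class TestDiagnosticRatios:
    def test_equal_fle_pyr_means_unity(self):
        out = diagnostic_ratios(table_from_conc({"Fle": 2.0, "Pyr": 2.0}))
        assert out["Fle/Pyr"].iloc[0] == pytest.approx(1.0)

    def test_equal_bap_chr_gives_half(self):
        out = diagnostic_ratios(table_from_conc({"BaP": 1.5, "Chr": 1.5}))
        assert out["BaP/(BaP+Chr)"].iloc[0] == pytest.approx(0.5)

    def test_zero_denominator_is_undefined_not_exception(self):
        out = diagnostic_ratios(table_from_conc({"BaP": 1.0, "BghiP": 0.0}))
        assert np.isnan(out["BaP/BghiP"].iloc[0])

    def test_computed_on_group_means_not_per_sample_ratios(self):
        # two samples: (Fle, Pyr) = (1, 2) and (3, 2): mean ratio 4/4 = 1,
        # whereas the mean of per-sample ratios would be (0.5 + 1.5)/2 = 1.0
        # -> distinguish with asymmetric values: (1, 4) and (3, 2)
        t = pd.concat(
            [
                table_from_conc({"Fle": 1.0, "Pyr": 4.0}, sample_id="a"),
                table_from_conc({"Fle": 3.0, "Pyr": 2.0}, sample_id="b"),
            ],
            ignore_index=True,
        )
        out = diagnostic_ratios(t)
        assert out["Fle/Pyr"].iloc[0] == pytest.approx((1 + 3) / (4 + 2))


class TestClassifySource:
    def _ratios(self, fle_pyr, bap_bghip, bap_frac):
        return pd.DataFrame(
            {
                "city": ["X"],
                "Fle/Pyr": [fle_pyr],
                "BaP/BghiP": [bap_bghip],
                "BaP/(BaP+Chr)": [bap_frac],
            }
        )

    def test_unanimous(self):
        out = classify_source(self._ratios(0.8, 0.4, 0.45), default_ratio_thresholds())
        assert out["consensus"].iloc[0] == "gasoline emission"

    def test_majority_two_vs_one(self):
        out = classify_source(self._ratios(0.8, 0.9, 0.45), default_ratio_thresholds())
        assert out["consensus"].iloc[0] == "gasoline emission"

    def test_three_way_tie_is_mixed(self):
        thresholds = RatioThresholds(
            {
                "Fle/Pyr": ((0.0, 10.0, "gasoline emission"),),
                "BaP/BghiP": ((0.0, 10.0, "diesel emission"),),
                "BaP/(BaP+Chr)": ((0.0, 10.0, "coal combustion"),),
            }
        )
        out = classify_source(self._ratios(1.0, 1.0, 0.5), thresholds)
        assert out["consensus"].iloc[0] == "mixed"

    def test_value_outside_intervals_unclassified(self):
        thresholds = RatioThresholds({r: ((0.0, 0.1, "x"),) for r in RATIO_NAMES})
        out = classify_source(self._ratios(5.0, 5.0, 0.9), thresholds)
        for r in RATIO_NAMES:
            assert out[f"source[{r}]"].iloc[0] == "unclassified"
        assert out["consensus"].iloc[0] == "unclassified"

    def test_undefined_ratio_does_not_vote(self):
        out = classify_source(
            self._ratios(0.8, float("nan"), 0.45), default_ratio_thresholds()
        )
        assert out["source[BaP/BghiP]"].iloc[0] == "undefined"
        assert out["consensus"].iloc[0] == "gasoline emission"

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RatioThresholds({"Fle/Pyr": ((0.0, 1.0, "a"), (0.5, 2.0, "b"))})
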