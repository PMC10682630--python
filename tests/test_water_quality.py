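"""Summary statistics, censoring policy, guideline screening, percent change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquarisk.censoring import CensorPolicy, substitute
from aquarisk.synthetic import GeneratorConfig, ParameterTarget, generate_wells
from aquarisk.water_quality import (
    ParameterProfile,
    SummaryStats,
    percent_change,
    screen_guidelines,
    summarize,
    summary_table,
)


class TestSummarize:
    def test_hand_checkable_set(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.mean, s.median, s.min, s.max, s.n) == (3, 3, 1, 5, 5)
        assert s.fraction_censored == 0.0

    def test_all_censored_network(self):
        # arsenic-style row: every well below a 16 ug/L detection limit
        s = summarize(np.full(115, 16.0), censored=np.ones(115, bool))
        assert s.all_censored
        assert s.fraction_censored == 1.0
        assert s.max == s.min == 16.0

    def test_half_lod_substitution(self):
        s = summarize([10.0, 4.0, 6.0], censored=[False, True, False])
        assert s.mean == pytest.approx(6.0)  # mean of {10, 2, 6}

    @pytest.mark.parametrize(
        "policy,expected_mean",
        [("half_lod", 6.0), ("full_lod", 20 / 3), ("zero", 16 / 3)],
    )
    def test_policy_selectable(self, policy, expected_mean):
        s = summarize([10.0, 4.0, 6.0], censored=[False, True, False], censor_policy=policy)
        assert s.mean == pytest.approx(expected_mean)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_mixed_units_rejected(self):
        df = pd.DataFrame(
            {
                "well_id": ["W1", "W2"],
                "governorate": ["Gaza", "Gaza"],
                "parameter": ["Sr", "Sr"],
                "value": [1.0, 2.0],
                "units": ["mg/L", "ug/L"],
                "censored": [False, False],
            }
        )
        with pytest.raises(ValueError, match="mixed units"):
            summary_table(df)

    def test_recovers_generator_targets(self):
        # summary of unclipped synthetic output matches the generation target
        cfg = GeneratorConfig(
            parameters=[ParameterTarget(id="NO3", units="mg/L", mean=112.0, sd=74.0)],
            governorate_counts={"Gaza": 20_000},
            seed=0,
        )
        tab = summary_table(generate_wells(cfg))
        row = tab.iloc[0]
        assert row["mean"] == pytest.approx(112.0, rel=0.02)
        assert row["sd"] == pytest.approx(74.0, rel=0.03)


class TestScreening:
    no3 = ParameterProfile(id="NO3", units="mg/L", guideline=50.0)

    def test_mean_above_guideline_flagged(self):
        stats = SummaryStats(n=115, max=365, min=16, mean=112, median=93, sd=74)
        rec = screen_guidelines(self.no3, stats=stats)
        assert rec.status == "screened"
        assert rec.mean_above_guideline

    def test_boundary_equality_not_flagged(self):
        stats = SummaryStats(n=10, max=60, min=40, mean=50.0, median=50, sd=5)
        assert not screen_guidelines(self.no3, stats=stats).mean_above_guideline

    def test_all_wells_below(self):
        rec = screen_guidelines(self.no3, values=np.full(20, 25.0))
        assert rec.exceedance_fraction == 0.0
        assert not rec.mean_above_guideline

    def test_no_guideline_is_explicit(self):
        sr = ParameterProfile(id="Sr", units="ug/L")  # no WHO guideline value
        rec = screen_guidelines(sr, values=[1.0])
        assert rec.status == "not_screenable"
        assert rec.mean_above_guideline is None

    @given(guideline=st.floats(1.0, 500.0))
    def test_exceedance_monotone_in_guideline(self, guideline):
        values = np.linspace(5.0, 400.0, 80)
        lower = screen_guidelines(
            ParameterProfile(id="x", units="mg/L", guideline=guideline), values=values
        ).exceedance_fraction
        higher = screen_guidelines(
            ParameterProfile(id="x", units="mg/L", guideline=guideline * 1.5), values=values
        ).exceedance_fraction
        assert higher <= lower


class TestPercentChange:
    @pytest.mark.parametrize("old,new,expected", [(100, 131, 31.0), (100, 70, -30.0), (7, 7, 0.0)])
    def test_campaign_change_arithmetic(self, old, new, expected):
        assert percent_change(old, new) == pytest.approx(expected)

    @given(a=st.floats(0.1, 1e4), b=st.floats(0.1, 1e4))
    def test_reversal_identity(self, a, b):
        # 100*(b-a)/a = -[100*(a-b)/b] * b/a
        assert percent_change(a, b) == pytest.approx(
            -percent_change(b, a) * b / a, rel=1e-9
        )

    def test_nonpositive_baseline_rejected(self):
        for old in (0.0, -5.0):
            with pytest.raises(ValueError):
                percent_change(old, 10.0)


class TestInvariantsAndUnits:
    def test_summary_stats_order_invariants(self):
        with pytest.raises(ValueError):
            SummaryStats(n=3, max=1.0, min=2.0, mean=1.5, median=1.5, sd=0.1)
        with pytest.raises(ValueError):
            SummaryStats(n=3, max=5.0, min=1.0, mean=9.0, median=3.0, sd=0.1)

    def test_microgram_conversion(self):
        sr = ParameterProfile(id="Sr", units="ug/L")
        assert sr.to_mg_per_l(2521.0) == pytest.approx(2.521)

    def test_nonconcentration_units_not_convertible(self):
        ec = ParameterProfile(id="EC", units="uS/cm")
        assert not ec.convertible
        with pytest.raises(ValueError, match="mg/L"):
            ec.to_mg_per_l(5202.0)

    def test_substitute_shape_mismatch(self):
        with pytest.raises(ValueError):
            substitute(np.ones(3), np.zeros(2, bool), CensorPolicy.HALF_LOD)
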