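"""Waste adjustment, gap tables and population-weighted summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fvgap import recommendations, waste_gap
from fvgap.errors import AlignmentError, FvGapError, GroupingError
from fvgap.market_model import simulate
from fvgap.waste_gap import WasteScheme, apply_waste, gap_table, summarize


class TestApplyWaste:
    def test_uniform_33_percent_arithmetic(self):
        assert apply_waste(600.0, WasteScheme.uniform(0.33)) == pytest.approx(402.0)

    def test_regional_anchor_28_percent(self):
        scheme = WasteScheme.regional({"Europe and North America": 0.28})
        c = apply_waste(555.56, scheme, region="Europe and North America")
        assert c == pytest.approx(400.0, abs=0.01)

    def test_zero_scheme_is_identity(self):
        assert apply_waste(123.4, WasteScheme.zero()) == 123.4

    def test_missing_region_is_a_lookup_error(self):
        scheme = WasteScheme.regional({"South Asia": 0.15})
        with pytest.raises(FvGapError, match="missing from regional waste table"):
            apply_waste(100.0, scheme, region="Atlantis")

    def test_invalid_shares_rejected(self):
        with pytest.raises(FvGapError):
            WasteScheme.uniform(1.0)
        with pytest.raises(FvGapError):
            WasteScheme.regional({"x": -0.1})

    @given(a=st.floats(0, 2000), w=st.floats(0, 0.99))
    @settings(derandomize=True, max_examples=100)
    def test_consumption_below_availability_and_monotone_in_waste(self, a, w):
        c = apply_waste(a, WasteScheme.uniform(w))
        assert 0 <= c <= a
        assert apply_waste(a, WasteScheme.uniform(min(w + 0.005, 0.99))) <= c


@pytest.fixture(scope="module")
def gap_inputs(small_world):
    avail = pd.concat(
        [simulate(small_world, s, years=[2015, 2030, 2050]).availability
         for s in ("SSP1", "SSP2")],
        ignore_index=True,
    )
    targets = pd.concat(
        [recommendations.target_series(small_world, s) for s in ("SSP1", "SSP2")],
        ignore_index=True,
    )
    return avail, targets


class TestGapTable:
    def test_tie_with_minimum_target_counts_as_passing(self, small_world):
        avail = pd.DataFrame(
            [{"country": "C001", "year": 2015, "scenario": "SSP1", "availability": 400.0}]
        )
        targets = pd.DataFrame(
            [{"country": "C001", "year": 2015, "scenario": "SSP1",
              "minimum_target": 400.0, "age_weighted_target": 550.0}]
        )
        gap = gap_table(avail, targets, WasteScheme.zero(), small_world)
        assert bool(gap["pass_min"].iloc[0]) is True
        assert bool(gap["pass_age"].iloc[0]) is False

    def test_zero_target_passes_everywhere(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        degenerate = targets.assign(minimum_target=0.0)
        gap = gap_table(avail, degenerate, WasteScheme.uniform(0.33), small_world)
        assert gap["pass_min"].all()

    def test_consumption_below_every_target_fails_everywhere(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        tiny = avail.assign(availability=1.0)
        gap = gap_table(tiny, targets, WasteScheme.zero(), small_world)
        assert not gap["pass_min"].any()
        assert not gap["pass_age"].any()

    def test_ratio_flag_coherence(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        gap = gap_table(avail, targets, WasteScheme.uniform(0.15), small_world)
        assert ((gap["ratio_min"] >= 1) == gap["pass_min"]).all()
        assert ((gap["ratio_age"] >= 1) == gap["pass_age"]).all()
        assert (gap["consumption"] <= gap["availability"] + 1e-12).all()

    def test_misaligned_keys_raise_alignment_error(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        with pytest.raises(AlignmentError):
            gap_table(avail, targets.query("year != 2030"), WasteScheme.zero(), small_world)

    def test_scheme_ordering_of_passing_counts(self, small_world, gap_inputs):
        """More waste can only shrink the passing set."""
        avail, targets = gap_inputs
        counts = [
            gap_table(avail, targets, scheme, small_world)["pass_min"].sum()
            for scheme in (WasteScheme.zero(), WasteScheme.uniform(0.15),
                           WasteScheme.uniform(0.33))
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestSummarize:
    def test_equal_population_weighted_mean(self, small_world, gap_inputs):
        """Two equal-population countries at 300 and 500 average to 400."""
        avail = pd.DataFrame(
            [
                {"country": "C001", "year": 2015, "scenario": "SSP1", "availability": 300.0},
                {"country": "C002", "year": 2015, "scenario": "SSP1", "availability": 500.0},
            ]
        )
        targets = pd.DataFrame(
            [
                {"country": c, "year": 2015, "scenario": "SSP1",
                 "minimum_target": 400.0, "age_weighted_target": 550.0}
                for c in ("C001", "C002")
            ]
        )
        gap = gap_table(avail, targets, WasteScheme.zero(), small_world)
        # overwrite populations to be equal, then the weighted mean is plain
        world = small_world
        pop = world.population.copy()
        pop.loc[pop["country"].isin(["C001", "C002"]), "total"] = 1e7
        import copy

        w2 = copy.copy(world)
        w2.population = pop
        out = summarize(gap, w2, grouping="global")
        assert out["availability"].iloc[0] == pytest.approx(400.0)

    def test_regional_partition_sums_to_global(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        gap = gap_table(avail, targets, WasteScheme.uniform(0.15), small_world)
        reg = summarize(gap, small_world, grouping="region")
        glo = summarize(gap, small_world, grouping="global")
        keys = ["year", "scenario", "scheme"]
        for col in ("population", "population_pass_min", "n_pass_min", "n_countries"):
            s = reg.groupby(keys)[col].sum()
            g = glo.set_index(keys)[col]
            np.testing.assert_allclose(s.to_numpy(), g.reindex(s.index).to_numpy(),
                                       rtol=1e-9)

    def test_single_country_group_mean_equals_country_value(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        gap = gap_table(avail, targets, WasteScheme.zero(), small_world)
        reg = summarize(gap, small_world, grouping="region")
        singles = (
            small_world.countries.groupby("region")["country"]
            .agg(list)
            .loc[lambda s: s.str.len() == 1]
        )
        for region, (country,) in singles.items():
            row = reg.query("group == @region and year == 2050 and scenario == 'SSP1'")
            expected = gap.query(
                "country == @country and year == 2050 and scenario == 'SSP1'"
            )["availability"].iloc[0]
            assert row["availability"].iloc[0] == pytest.approx(expected)

    def test_unknown_grouping_rejected(self, small_world, gap_inputs):
        avail, targets = gap_inputs
        gap = gap_table(avail, targets, WasteScheme.zero(), small_world)
        with pytest.raises(FvGapError, match="grouping"):
            summarize(gap, small_world, grouping="continent")
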