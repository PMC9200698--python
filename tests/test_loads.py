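"""Censored load triples, load ratios and their aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortcutflux.hydrology import DischargeTriple, ExtrapolationWeights
from shortcutflux.loads import (
    CensoredConcentration,
    LoadCell,
    aggregate_ratios,
    event_load,
    extrapolate_catchment_load_ratio,
    load_ratio,
    uncertainty_attribution,
)


class TestEventLoad:
    def test_uncensored_substitution(self):
        f = event_load(DischargeTriple(100, 120, 150), CensoredConcentration(500, 20, False))
        assert f.as_tuple() == (50_000, 60_000, 75_000)

    def test_censored_bounds(self):
        f = event_load(DischargeTriple(100, 120, 150), CensoredConcentration(np.nan, 20, True))
        assert f.as_tuple() == (0.0, 0.0, 3_000.0)

    def test_from_measurement_censors_below_loq(self):
        assert CensoredConcentration.from_measurement(19.9, 20).censored
        assert not CensoredConcentration.from_measurement(20.0, 20).censored

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            CensoredConcentration(-1.0, 20, False)

    @settings(max_examples=500, derandomize=True)
    @given(
        st.tuples(*[st.floats(0, 1e6)] * 3),
        st.floats(0, 1e4),
        st.floats(1e-3, 100),
    )
    def test_ordering_always_holds(self, raw_q, value, loq):
        q = DischargeTriple(*sorted(raw_q))
        c = CensoredConcentration.from_measurement(value, loq)
        f = event_load(q, c)
        assert f.min <= f.mod <= f.high


class TestLoadRatio:
    def test_zero_inlets(self):
        inl = [event_load(DischargeTriple(1, 1, 1), CensoredConcentration(0, 20, False))] * 4
        stream = event_load(DischargeTriple(100, 100, 100), CensoredConcentration(50, 20, False))
        r = load_ratio(inl, stream)
        assert (r.min, r.mod, r.high) == (0.0, 0.0, 0.0)

    def test_equal_sums_give_unity_moderate(self):
        inl = [event_load(DischargeTriple(25, 25, 25), CensoredConcentration(10, 5, False))] * 4
        stream = event_load(DischargeTriple(100, 100, 100), CensoredConcentration(10, 5, False))
        assert load_ratio(inl, stream).mod == pytest.approx(1.0)

    def test_fully_censored_stream_flags_high_undefined(self):
        inl = [event_load(DischargeTriple(1, 1, 1), CensoredConcentration(50, 20, False))] * 4
        stream = event_load(DischargeTriple(100, 100, 100), CensoredConcentration(np.nan, 20, True))
        r = load_ratio(inl, stream)
        assert not r.defined[2] and np.isnan(r.high)
        assert r.defined[0]  # min uses the stream *high* (LOQ) bound


def _cell(eid, sub, q_inl, c_inl, q_st, c_st):
    return LoadCell(eid, sub, q_inl, c_inl, DischargeTriple(*q_st), c_st)


def _simple_cell(eid, sub, inl_conc, st_conc, v_inl=100.0, v_st=10_000.0):
    return _cell(
        eid,
        sub,
        [DischargeTriple(v_inl, v_inl, v_inl)] * 4,
        [CensoredConcentration(inl_conc, 20, False)] * 4,
        (v_st, v_st, v_st),
        CensoredConcentration(st_conc, 20, False),
    )


class TestAggregates:
    def test_single_cell_equals_cell_ratio(self):
        cell = _simple_cell(1, "a", 50, 100)
        agg = aggregate_ratios([cell])
        r = cell.ratio()
        assert agg.by_substance.mod == pytest.approx(r.mod)
        assert agg.by_sum.mod == pytest.approx(r.mod)

    def test_mean_of_two_cells_with_equal_stream_loads(self):
        # ratios 0.1 and 0.3 with identical stream loads -> mean 0.2
        c1 = _cell(
            1, "a",
            [DischargeTriple(100, 100, 100)] * 4, [CensoredConcentration(25, 20, False)] * 4,
            (1000, 1000, 1000), CensoredConcentration(100, 20, False),
        )  # 4*2500/1e5 = 0.1
        c2 = _cell(
            2, "a",
            [DischargeTriple(100, 100, 100)] * 4, [CensoredConcentration(75, 20, False)] * 4,
            (1000, 1000, 1000), CensoredConcentration(100, 20, False),
        )  # 0.3
        agg = aggregate_ratios([c1, c2])
        assert agg.by_substance.mod == pytest.approx(0.2)
        assert agg.by_sum.mod == pytest.approx(0.2)

    def test_dominant_substance_pulls_sum_ratio_down(self):
        """One substance dominating the stream sum with a small own ratio
        drives the sum aggregate below the per-substance mean."""
        minor = _cell(
            1, "minor",
            [DischargeTriple(10, 10, 10)] * 4, [CensoredConcentration(500, 20, False)] * 4,
            (1000, 1000, 1000), CensoredConcentration(100, 20, False),
        )  # ratio 20000/100000 = 0.2
        dominant = _cell(
            1, "dominant",
            [DischargeTriple(10, 10, 10)] * 4, [CensoredConcentration(50, 20, False)] * 4,
            (1000, 1000, 1000), CensoredConcentration(10_000, 20, False),
        )  # ratio 2000/1e7 = 2e-4; stream load dominates the sum
        agg = aggregate_ratios([minor, dominant])
        # independent recomputation from the definitions
        mean_expected = (0.2 + 2e-4) / 2
        sum_expected = (20_000 + 2_000) / (100_000 + 10_000_000)
        assert agg.by_substance.mod == pytest.approx(mean_expected)
        assert agg.by_sum.mod == pytest.approx(sum_expected)
        assert agg.by_sum.mod < agg.by_substance.mod

    def test_undefined_cells_excluded_and_counted(self):
        good = _simple_cell(1, "a", 50, 100)
        bad = _cell(
            2, "a",
            [DischargeTriple(10, 10, 10)] * 4, [CensoredConcentration(50, 20, False)] * 4,
            (100, 100, 100), CensoredConcentration(np.nan, 20, True),
        )
        agg = aggregate_ratios([good, bad])
        assert agg.n_cells == 1 and agg.n_excluded == 1

    def test_empty_cells_raise(self):
        with pytest.raises(ValueError):
            aggregate_ratios([])


class TestUncertaintyAttribution:
    def test_no_censoring_means_zero_loq_share(self):
        cells = [
            _cell(
                1, "a",
                [DischargeTriple(80, 100, 130)] * 4, [CensoredConcentration(50, 20, False)] * 4,
                (10_000, 10_000, 10_000), CensoredConcentration(100, 20, False),
            )
        ]
        shares = uncertainty_attribution(cells)
        assert shares["by_sum"]["loq_share"] == pytest.approx(0.0, abs=1e-12)
        assert shares["by_sum"]["discharge_share"] == pytest.approx(1.0)

    def test_exact_discharge_means_zero_discharge_share(self):
        cells = [
            _cell(
                1, "a",
                [DischargeTriple(100, 100, 100)] * 4,
                [CensoredConcentration(np.nan, 20, True)] * 2
                + [CensoredConcentration(50, 20, False)] * 2,
                (10_000, 10_000, 10_000), CensoredConcentration(100, 20, False),
            )
        ]
        shares = uncertainty_attribution(cells)
        assert shares["by_sum"]["discharge_share"] == pytest.approx(0.0, abs=1e-12)
        assert shares["by_sum"]["loq_share"] > 0

    def test_zero_total_spread_flagged(self):
        cells = [_simple_cell(1, "a", 50, 100)]
        shares = uncertainty_attribution(cells)
        assert shares["by_sum"]["loq_share"] is None

    def test_shares_match_toggling_oracle(self):
        """Brute-force oracle: recompute each partial spread by explicitly
        toggling one uncertainty source off at a time."""
        rng = np.random.default_rng(3)
        cells = []
        for eid in range(6):
            q_inl = [DischargeTriple(*sorted(rng.uniform(10, 500, 3))) for _ in range(4)]
            c_inl = [
                CensoredConcentration.from_measurement(rng.uniform(0, 100), 20.0) for _ in range(4)
            ]
            vs = rng.uniform(5_000, 50_000)
            c_st = CensoredConcentration.from_measurement(rng.uniform(10, 200), 20.0)
            cells.append(LoadCell(eid, "s", q_inl, c_inl, DischargeTriple(vs, vs, vs), c_st))
        shares = uncertainty_attribution(cells)

        def agg_spread(cells2):
            a = aggregate_ratios(cells2).by_sum
            return a.high - a.min

        def fix_conc(c):
            return CensoredConcentration(c.c_min, c.loq, False)

        def fix_q(q):
            return DischargeTriple(q.mod, q.mod, q.mod)

        total = agg_spread(cells)
        loq_only = agg_spread(
            [
                LoadCell(c.event_id, c.substance, [fix_q(q) for q in c.inlet_discharge],
                         c.inlet_conc, fix_q(c.stream_discharge), c.stream_conc)
                for c in cells
            ]
        )
        q_only = agg_spread(
            [
                LoadCell(c.event_id, c.substance, c.inlet_discharge,
                         [fix_conc(x) for x in c.inlet_conc], c.stream_discharge,
                         fix_conc(c.stream_conc))
                for c in cells
            ]
        )
        assert shares["by_sum"]["loq_share"] == pytest.approx(loq_only / total)
        assert shares["by_sum"]["discharge_share"] == pytest.approx(q_only / total)


class TestCatchmentExtrapolation:
    def test_unit_factor_preserves_ratios(self):
        w = ExtrapolationWeights(10, 10, 50, 50, 4, 4)
        cells = [_simple_cell(1, "a", 50, 100)]
        out = extrapolate_catchment_load_ratio(cells, w)
        base = aggregate_ratios(cells)
        for method in ("road_area", "agri_area", "count"):
            assert out[method].by_sum.mod == pytest.approx(base.by_sum.mod)

    def test_doubling_scale_doubles_sum_numerator(self):
        w = ExtrapolationWeights(10, 20, 50, 100, 4, 8)
        cells = [_simple_cell(1, "a", 50, 100)]
        out = extrapolate_catchment_load_ratio(cells, w)
        base = aggregate_ratios(cells)
        assert out["count"].by_sum.mod == pytest.approx(2 * base.by_sum.mod)
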