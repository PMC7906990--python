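"""Anxiety states, correction, and the five stimulus-parameter mappings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vretsim import (
    HIGH,
    LOW,
    REST,
    PhasePlan,
    StateLabel,
    correction,
    map_parameters,
    phase_at,
    sgf,
    sjf,
    spu,
    ss,
    static_schedule,
    sv,
)
from vretsim.controller import ZERO_PARAMS


class TestStatesAndCorrection:
    def test_band_definitions(self):
        assert REST.band == (0.92, 1.0)
        assert LOW.band == (0.70, 0.8)
        assert HIGH.band == (0.40, 0.5)

    def test_representative_is_lower_band_edge(self):
        assert (REST.representative, LOW.representative, HIGH.representative) == (
            0.92,
            0.70,
            0.40,
        )

    @pytest.mark.parametrize(
        "state,normalized,expected",
        [(LOW, 0.8, -0.1), (HIGH, 0.4, 0.0), (LOW, 0.35, 0.35)],
    )
    def test_correction_arithmetic(self, state, normalized, expected):
        assert correction(state, normalized).value == pytest.approx(expected)

    def test_negative_correction_means_calmer_than_desired(self):
        # calmer user (high normalized) => negative correction => stronger stimulus
        assert correction(LOW, 0.95).value < 0
        assert correction(LOW, 0.55).value > 0


class TestMappingAnchors:
    """The published on-target boundary values at c = 0 and c = -0.1."""

    @pytest.mark.parametrize(
        "func,c,expected,tol",
        [
            (lambda c: sgf(StateLabel.LOW, c), 0.0, 120.0, 1e-9),
            (lambda c: sgf(StateLabel.LOW, c), -0.1, 240.0, 1e-9),
            (lambda c: sgf(StateLabel.HIGH, c), 0.0, 320.0, 1e-9),
            (lambda c: sgf(StateLabel.HIGH, c), -0.1, 440.0, 1e-9),
            (sjf, 0.0, 0.035, 1e-9),
            (sjf, -0.1, 0.049, 1e-9),
            (spu, 0.0, 0.3265, 1e-4),
            (spu, -0.1, 0.4132, 1e-4),
            (ss, 0.0, 1.20, 1e-9),
            (ss, -0.1, 1.357, 1e-3),
            (sv, 0.0, 0.00471, 1e-5),
            (sv, -0.1, 0.00492, 1e-5),
        ],
    )
    def test_printed_anchor_values(self, func, c, expected, tol):
        # tolerance = one unit in the last printed digit (values are
        # truncated, not rounded, in the published table)
        assert func(c) == pytest.approx(expected, abs=tol)

    def test_anchors_to_four_significant_figures(self):
        assert spu(0.0) == pytest.approx(0.32653, abs=5e-5)
        assert spu(-0.1) == pytest.approx(0.41327, abs=5e-5)
        assert ss(-0.1) == pytest.approx(1.3572, abs=5e-4)
        assert sv(0.0) == pytest.approx(0.0047143, rel=1e-4)
        assert sv(-0.1) == pytest.approx(0.0049286, rel=1e-4)


class TestMappingShapes:
    def test_sgf_rest_is_zero(self):
        assert sgf(StateLabel.REST, -0.5) == 0.0

    def test_sgf_low_at_strong_extreme(self):
        assert sgf(StateLabel.LOW, -0.6) == pytest.approx(840.0)

    def test_sgf_clamps_at_zero(self):
        assert sgf(StateLabel.LOW, 0.5) == 0.0

    def test_sjf_clamps_at_zero(self):
        # unclamped value would be 0.035 - 0.14*0.3 = -0.007
        assert sjf(0.3) == 0.0

    def test_sjf_strong_extreme(self):
        assert sjf(-0.6) == pytest.approx(0.119)

    def test_spu_endpoints(self):
        assert spu(-0.6) == pytest.approx(1.0)
        assert spu(0.8) == pytest.approx(0.0)

    def test_ss_always_above_base(self):
        assert ss(1.0) == pytest.approx(0.48)
        assert ss(5.0) > 0.3

    def test_sv_strong_extreme(self):
        assert sv(-0.6) == pytest.approx(0.006)

    @given(c=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_spu_is_a_probability_everywhere(self, c):
        assert 0.0 <= spu(c) <= 1.0

    @pytest.mark.parametrize(
        "func",
        [
            lambda c: sgf(StateLabel.LOW, c),
            lambda c: sgf(StateLabel.HIGH, c),
            sjf,
            spu,
            ss,
            sv,
        ],
    )
    def test_monotone_non_increasing_on_stated_range(self, func):
        grid = np.linspace(-0.7, 0.6, 1301)
        vals = np.array([func(float(c)) for c in grid])
        assert np.all(np.diff(vals) <= 1e-12)


class TestBundles:
    def test_low_on_target_bundle(self):
        p = map_parameters(LOW, 0.0)
        assert p.sgf == pytest.approx(120)
        assert p.sjf == pytest.approx(0.035)
        assert p.spu == pytest.approx(0.3265, abs=5e-5)
        assert p.ss == pytest.approx(1.20)
        assert p.sv == pytest.approx(0.00471, abs=5e-6)

    def test_high_bundle_at_minus_point_one(self):
        p = map_parameters(HIGH, -0.1)
        assert p.astuple() == pytest.approx(
            (440, 0.049, 0.41327, 1.3572, 0.0049286), rel=1e-3
        )

    def test_strong_extreme_bundle(self):
        p = map_parameters(LOW, -0.6)
        assert p.sgf == pytest.approx(840)
        assert p.spu == pytest.approx(1.0)
        assert p.sv == pytest.approx(0.006)
        assert p.ss == pytest.approx(0.3 + 0.9 * 0.2 ** -0.6)
        assert p.sjf == pytest.approx(0.119)

    def test_rest_gives_zero_bundle(self):
        assert map_parameters(REST, -0.3) == ZERO_PARAMS

    def test_pure_function_bitwise_repeatable(self):
        a = map_parameters(HIGH, -0.2345)
        b = map_parameters(HIGH, -0.2345)
        assert a.astuple() == b.astuple()

    def test_static_schedule_equals_on_target_adaptive_bundles(self):
        assert static_schedule(LOW) == map_parameters(LOW, 0.0)
        assert static_schedule(HIGH) == map_parameters(HIGH, -0.1)
        assert static_schedule(REST) == ZERO_PARAMS

    def test_static_high_strictly_stronger_than_static_low(self):
        lo, hi = static_schedule(LOW), static_schedule(HIGH)
        assert hi.sgf > lo.sgf
        assert hi.ss > lo.ss
        assert hi.sjf > lo.sjf
        assert hi.spu > lo.spu
        assert hi.sv > lo.sv


class TestPhasePlan:
    def test_default_plan_totals_300s(self):
        plan = PhasePlan()
        assert plan.total_duration == 300.0
        labels = [s.label for s, _ in plan.phases]
        assert labels == [
            StateLabel.REST,
            StateLabel.LOW,
            StateLabel.REST,
            StateLabel.HIGH,
            StateLabel.REST,
        ]

    @pytest.mark.parametrize(
        "t,phase,label",
        [
            (0.0, 0, StateLabel.REST),
            (60.0, 1, StateLabel.LOW),
            (180.0, 3, StateLabel.HIGH),
            (299.99, 4, StateLabel.REST),
        ],
    )
    def test_phase_lookup(self, t, phase, label):
        idx, state = phase_at(t)
        assert (idx, state.label) == (phase, label)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            phase_at(300.0)
        with pytest.raises(ValueError):
            phase_at(-0.1)
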