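import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etqrs.nonlinear import FeatureSignal
from etqrs.pd_threshold import (
    CandidateDecision,
    PdParams,
    ThresholdState,
    advance_threshold,
    init_state,
    point_threshold,
    register_detection,
    screen_window,
)

FS = 360.0
P = PdParams()  # a=0.5, b=0.1, th_min=0.15, M=1.5


def literal_recursion(th_hist, params):
    """Brute-force iteration of the window-threshold recurrence."""
    new = th_hist[-1] - params.a * (th_hist[-1] - params.th_min) \
        - params.b * (th_hist[-1] - th_hist[-3])
    return th_hist + [new]


class TestParams:
    def test_defaults(self):
        assert (P.a, P.b, P.th_min, P.m_factor) == (0.5, 0.1, 0.15, 1.5)
        assert P.search_radius == 15

    def test_invalid(self):
        with pytest.raises(ValueError):
            PdParams(a=1.5)
        with pytest.raises(ValueError):
            PdParams(th_min=0.0)
        with pytest.raises(ValueError):
            PdParams(m_factor=0.5)


class TestInitState:
    def test_half_max_rule(self):
        s = np.zeros(1000)
        s[100] = 2.0
        st_ = init_state(FeatureSignal(s), P, FS)
        assert st_.th_prev == st_.th_cur == 1.0

    def test_all_zero_floors(self):
        st_ = init_state(FeatureSignal(np.zeros(1000)), P, FS)
        assert st_.th_prev == st_.th_cur == 0.15

    def test_first_derived_threshold(self):
        # hand evaluation: 1.0 - 0.5*(1.0-0.15) - 0.1*0 = 0.575
        s = np.zeros(1000)
        s[10] = 2.0
        st_ = init_state(FeatureSignal(s), P, FS)
        assert st_.th_next == pytest.approx(0.575)

    def test_only_first_two_seconds_used(self):
        s = np.zeros(1000)
        s[900] = 100.0  # beyond 2 s at 360 Hz
        st_ = init_state(FeatureSignal(s), P, FS)
        assert st_.th_cur == 0.15


class TestAdvanceThreshold:
    def test_floor_fixed_point(self):
        st_ = ThresholdState(0.15, 0.15, 0.15)
        out = advance_threshold(st_, P)
        assert out == ThresholdState(0.15, 0.15, 0.15)

    def test_hand_evaluated_step(self):
        # 0.575 - 0.5*(0.575-0.15) - 0.1*(0.575-1.0) = 0.405
        st_ = ThresholdState(1.0, 1.0, 0.575)
        out = advance_threshold(st_, P)
        assert out.th_prev == pytest.approx(1.0)
        assert out.th_cur == pytest.approx(0.575)
        assert out.th_next == pytest.approx(0.405)

    def test_floor_preserved_on_grid(self):
        grid = np.linspace(0.15, 5.0, 8)
        for p_ in (P, PdParams(a=0.3, b=0.25), PdParams(a=0.8, b=0.05)):
            for tp in grid:
                for tc in grid:
                    for tn in grid:
                        out = advance_threshold(
                            ThresholdState(tp, tc, tn), p_)
                        assert out.th_next >= p_.th_min - 1e-12
                        assert out.th_next <= max(tp, tc, tn) + 1e-12

    def test_matches_literal_recursion(self):
        # start (1, 1): TH[0]=TH[1]=1, iterate 30 windows both ways
        hist = [1.0, 1.0, 0.575]
        st_ = ThresholdState(1.0, 1.0, 0.575)
        for _ in range(30):
            hist = literal_recursion(hist, P)
            st_ = advance_threshold(st_, P)
            assert st_.th_next == pytest.approx(hist[-1], abs=1e-12)
            assert st_.th_cur == pytest.approx(hist[-2], abs=1e-12)

    def test_geometric_decay_to_floor(self):
        st_ = ThresholdState(1.0, 1.0, 0.575)
        for w in range(20):
            st_ = advance_threshold(st_, P)
        assert abs(st_.th_cur - P.th_min) < 0.01

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.floats(0.16, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_floor_preserved_under_fuzzed_detections(self, detections, feat):
        st_ = ThresholdState(1.0, 1.0, 0.575)
        for has_beat in detections:
            if has_beat:
                st_ = register_detection(st_, feat, P)
            st_ = advance_threshold(st_, P)
            for th in (st_.th_prev, st_.th_cur, st_.th_next):
                assert th >= P.th_min - 1e-12


class TestPointThreshold:
    def test_offset_zero(self):
        st_ = ThresholdState(0.9, 1.0, 0.5)
        assert point_threshold(st_, 0, 93) == pytest.approx(1.0)

    def test_offset_full_window(self):
        st_ = ThresholdState(0.9, 1.0, 0.5)
        assert point_threshold(st_, 93, 93) == pytest.approx(0.5)

    def test_midpoint(self):
        st_ = ThresholdState(0.9, 1.0, 0.5)
        assert point_threshold(st_, 46.5, 93) == pytest.approx(0.75)


class TestScreenWindow:
    def test_no_extremes(self):
        s = FeatureSignal(np.ones(100))
        out = screen_window(np.array([], dtype=int), s,
                            ThresholdState(1, 1, 1), P, 0, 93)
        assert out == CandidateDecision(False)

    def test_single_qualifying_extreme(self):
        s = np.zeros(100)
        s[50] = 10.0
        out = screen_window(np.array([50]), FeatureSignal(s),
                            ThresholdState(1.0, 1.0, 1.0), P, 0, 93)
        assert out.detected
        assert out.peak_index == 50
        assert out.peak_feature == 10.0

    def test_below_m_times_threshold_rejected(self):
        s = np.zeros(100)
        s[50] = 1.4  # threshold 1.0, M=1.5 -> needs > 1.5
        out = screen_window(np.array([50]), FeatureSignal(s),
                            ThresholdState(1.0, 1.0, 1.0), P, 0, 93)
        assert not out.detected

    def test_largest_feature_wins(self):
        s = np.zeros(200)
        s[40] = 3.0
        s[120] = 5.0
        out = screen_window(np.array([40, 120]), FeatureSignal(s),
                            ThresholdState(0.15, 0.15, 0.15), P, 0, 200)
        assert out.peak_index == 120
        assert out.peak_feature == 5.0

    def test_search_radius_rescues_offset_peak(self):
        # feature peak 10 samples away from the extreme still qualifies
        s = np.zeros(100)
        s[60] = 10.0
        out = screen_window(np.array([50]), FeatureSignal(s),
                            ThresholdState(1.0, 1.0, 1.0), P, 0, 93)
        assert out.detected

    def test_beyond_search_radius_ignored(self):
        s = np.zeros(100)
        s[70] = 10.0  # 20 samples away > search_radius 15
        out = screen_window(np.array([50]), FeatureSignal(s),
                            ThresholdState(1.0, 1.0, 1.0), P, 0, 93)
        assert not out.detected


class TestRegisterDetection:
    def test_table_detection_branch(self):
        # th_cur <- 4.0; th_next = 4.0 - 0.5*3.85 - 0.1*3.0 = 1.775
        st_ = ThresholdState(1.0, 2.0, 0.5)
        out = register_detection(st_, 4.0, P)
        assert out.th_cur == pytest.approx(4.0)
        assert out.th_next == pytest.approx(1.775)
        assert out.th_prev == pytest.approx(1.0)

    def test_feature_at_floor(self):
        st_ = ThresholdState(1.0, 2.0, 0.5)
        out = register_detection(st_, P.th_min, P)
        expected = P.th_min - 0.1 * (P.th_min - 1.0)
        assert out.th_next == pytest.approx(expected)

    def test_b_term_vanishes(self):
        st_ = ThresholdState(2.0, 2.0, 0.5)
        out = register_detection(st_, 2.0, P)
        assert out.th_next == pytest.approx(2.0 - 0.5 * (2.0 - 0.15))

    def test_nonpositive_feature_rejected(self):
        with pytest.raises(ValueError):
            register_detection(ThresholdState(1, 1, 1), 0.0, P)
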