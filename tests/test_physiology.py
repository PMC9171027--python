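"""MAP extraction, the hyperemic pressure rule, frame-count velocimetry and
the caFFR/caIMR index formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caphys.physiology import (
    Constants,
    ContrastPassage,
    DiastoleWindow,
    PressureTrace,
    compute_indices,
    detect_diastole,
    diastolic_velocity,
    hyperemic_aortic_pressure,
    mean_aortic_pressure,
    run_case,
)
from caphys.synthetic import generate_case_fixture


def sine_trace(n_cycles=4, period=0.8, mean=100.0, amp=20.0, fs=200.0):
    t = np.arange(0.0, n_cycles * period, 1.0 / fs)
    return PressureTrace(
        time=t,
        pressure=mean + amp * np.sin(2 * np.pi * t / period),
        cycle_markers=np.arange(n_cycles + 1) * period,
    )


class TestMeanAorticPressure:
    def test_constant_trace_with_markers(self):
        t = np.arange(0.0, 3.2, 0.005)
        trace = PressureTrace(t, np.full(t.size, 100.0), cycle_markers=np.arange(5) * 0.8)
        assert mean_aortic_pressure(trace) == pytest.approx(100.0)

    def test_sinusoid_averages_to_mean_over_integer_cycles(self):
        assert mean_aortic_pressure(sine_trace()) == pytest.approx(100.0, abs=1e-6)

    def test_two_cycles_rejected(self):
        with pytest.raises(ValueError, match="3"):
            mean_aortic_pressure(sine_trace(n_cycles=2))

    def test_non_uniform_sampling_rejected(self):
        t = np.concatenate([np.arange(0, 1, 0.005), np.arange(1, 3.2, 0.01)])
        with pytest.raises(ValueError, match="uniform"):
            PressureTrace(t, np.full(t.size, 100.0))

    def test_detected_cycles_match_markers(self):
        """Peak-based segmentation gives the same MAP as explicit markers."""
        marked = sine_trace(n_cycles=6)
        unmarked = PressureTrace(marked.time, marked.pressure)
        assert mean_aortic_pressure(unmarked) == pytest.approx(
            mean_aortic_pressure(marked), abs=0.1
        )


class TestHyperemicRule:
    @pytest.mark.parametrize(
        "map_mmhg,expected",
        [(100.0, 80.0), (95.0, 76.0), (90.0, 76.5), (120.0, 96.0), (94.99, 80.7415)],
    )
    def test_piecewise_rule(self, map_mmhg, expected):
        assert hyperemic_aortic_pressure(map_mmhg) == pytest.approx(expected)

    def test_non_positive_map_rejected(self):
        with pytest.raises(ValueError):
            hyperemic_aortic_pressure(0.0)


class TestDetectDiastole:
    def test_planted_notch_recovered_within_one_sample(self, clean_case):
        trace, window_gt = clean_case.trace, clean_case.window
        window = detect_diastole(trace)
        assert abs(window.t_start - window_gt.t_start) <= trace.dt + 1e-12

    def test_window_contained_in_cycle(self, clean_case):
        window = detect_diastole(clean_case.trace)
        assert window.duration < 0.8

    def test_flat_trace_rejected(self):
        t = np.arange(0.0, 3.2, 0.005)
        with pytest.raises(ValueError, match="constant"):
            detect_diastole(PressureTrace(t, np.full(t.size, 90.0)))


class TestDiastolicVelocity:
    def test_simple_quotient(self):
        passage = ContrastPassage(np.array([0.0, 0.15, 0.3]), np.array([0.0, 15.0, 30.0]))
        v = diastolic_velocity(passage, DiastoleWindow(0.0, 0.3))
        assert v == pytest.approx(100.0)

    def test_frame_rate_arithmetic(self):
        # 4 inter-frame intervals at 15 fps = 0.2667 s covering 24 mm -> 90 mm/s
        t = np.arange(5) / 15.0
        passage = ContrastPassage(t, np.linspace(0.0, 24.0, 5))
        v = diastolic_velocity(passage, DiastoleWindow(t[0], t[-1]))
        assert v == pytest.approx(90.0, rel=1e-6)

    def test_zero_displacement_flags_degenerate_flow(self):
        passage = ContrastPassage(np.array([0.0, 0.1, 0.2]), np.array([5.0, 5.0, 5.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            v = diastolic_velocity(passage, DiastoleWindow(0.0, 0.2))
        assert v == 0.0

    def test_too_few_frames_rejected(self):
        passage = ContrastPassage(np.array([0.0, 0.5]), np.array([0.0, 10.0]))
        with pytest.raises(ValueError, match="frames"):
            diastolic_velocity(passage, DiastoleWindow(0.1, 0.2))


class TestComputeIndices:
    def test_caffr_arithmetic(self):
        res = compute_indices(80.0, 8.0, 100.0)
        assert res.ca_ffr == pytest.approx(0.9)
        assert res.pd_hyp_mmHg == pytest.approx(72.0)

    def test_caimr_with_printed_constants(self):
        # Pa_hyp 80, dP 0, Vd 100, K 1.1, L 75 -> 80*75/110
        res = compute_indices(80.0, 0.0, 100.0)
        assert res.ca_imr == pytest.approx(80.0 * 75.0 / 110.0)
        assert res.ca_imr == pytest.approx(54.545, abs=1e-3)
        assert res.abnormal

    @given(
        pa=st.floats(40.0, 150.0),
        dp_frac=st.floats(0.0, 0.9),
        vd=st.floats(20.0, 400.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_both_printed_forms_agree(self, pa, dp_frac, vd):
        """caIMR via Pa_hyp*caFFR*L/(K*Vd) equals (Pa_hyp-dP)*L/(K*Vd)."""
        dp = dp_frac * pa
        res = compute_indices(pa, dp, vd)
        via_ffr = pa * res.ca_ffr * 75.0 / (1.1 * vd)
        assert via_ffr == pytest.approx(res.ca_imr, rel=1e-12)

    def test_monotone_decreasing_in_dp(self):
        grid = np.linspace(0.0, 60.0, 13)
        ffr = [compute_indices(80.0, d, 100.0).ca_ffr for d in grid]
        imr = [compute_indices(80.0, d, 100.0).ca_imr for d in grid]
        assert np.all(np.diff(ffr) < 0)
        assert np.all(np.diff(imr) < 0)

    def test_inverse_proportional_to_velocity(self):
        a = compute_indices(80.0, 5.0, 100.0).ca_imr
        b = compute_indices(80.0, 5.0, 200.0).ca_imr
        assert b == pytest.approx(a / 2.0, rel=1e-12)

    def test_constants_propagate_linearly(self):
        base = compute_indices(80.0, 5.0, 100.0).ca_imr
        double_l = compute_indices(80.0, 5.0, 100.0, Constants(L=150.0)).ca_imr
        double_k = compute_indices(80.0, 5.0, 100.0, Constants(K=2.2)).ca_imr
        assert double_l == pytest.approx(2.0 * base, rel=1e-12)
        assert double_k == pytest.approx(base / 2.0, rel=1e-12)

    def test_non_physical_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            compute_indices(80.0, 90.0, 100.0)
        with pytest.raises(ValueError, match="Vdiastole"):
            compute_indices(80.0, 5.0, 0.0)


class TestRunCase:
    def test_zero_stenosis_caffr_near_unity(self):
        fx = generate_case_fixture(0.0, 100.0, 100.0, 0.0, seed=3)
        res = run_case(fx.centerline, fx.trace, fx.passage)
        assert res.ca_ffr >= 0.99

    def test_round_trip_recovers_ground_truth(self, clean_case):
        res = run_case(clean_case.centerline, clean_case.trace, clean_case.passage)
        gt = clean_case.ground_truth
        assert res.ca_imr == pytest.approx(gt.ca_imr, rel=0.05)
        assert res.ca_ffr == pytest.approx(gt.ca_ffr, rel=0.01)
        assert res.map_mmHg == pytest.approx(gt.map_mmHg, rel=0.01)

    def test_abnormal_flag_above_threshold(self, clean_case):
        res = run_case(clean_case.centerline, clean_case.trace, clean_case.passage)
        assert res.ca_imr > 40.0
        assert res.abnormal

    def test_explicit_window_bypasses_detection(self, clean_case):
        res = run_case(
            clean_case.centerline, clean_case.trace, clean_case.passage,
            window=clean_case.window,
        )
        assert res.v_diastole_mm_s == pytest.approx(100.0, rel=1e-9)

    def test_errors_carry_stage_labels(self, clean_case):
        bad = ContrastPassage(np.array([0.0, 0.05]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match=r"\[diastolic_velocity\]"):
            run_case(clean_case.centerline, clean_case.trace, bad)

    def test_provenance_records_intermediates(self, clean_case):
        res = run_case(clean_case.centerline, clean_case.trace, clean_case.passage)
        for key in ("MAP_mmHg", "Vdiastole_mm_s", "dP_total_mmHg", "constants"):
            assert key in res.provenance
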