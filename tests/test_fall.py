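import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radarfall as rf
from radarfall.fall import (
    DetectorConfig,
    TraceGapError,
    TransitionEvent,
    ZmaxTrace,
    classify_transition,
    detect_events,
    find_descents,
    zmax_trace,
)
from radarfall.preprocessing import NormalizedFrame


def trace_from_z(z, fps=30.0, smooth_window=1):
    z = np.asarray(z, dtype=float)
    return ZmaxTrace(zmax=z, velocity=np.diff(z) * fps, fps=fps)


def frames_from_z(z):
    """One-point NormalizedFrames whose z_max follows ``z``."""
    out = []
    for i, zi in enumerate(z):
        pts = np.zeros((500, 3))
        pts[0] = [0.0, 3.0, zi]
        out.append(NormalizedFrame(points=pts, n_real=1, source_index=i))
    return out


class TestZmaxTrace:
    def test_constant_height_zero_velocity(self):
        tr = zmax_trace(frames_from_z([1.8] * 50), fps=30)
        assert np.allclose(tr.velocity, 0.0)
        assert len(tr.velocity) == 49

    def test_linear_fall_velocity(self):
        z = np.linspace(1.8, 0.2, 21)  # 20 steps
        tr = zmax_trace(frames_from_z(z), fps=30, smooth_window=1)
        assert np.allclose(tr.velocity, -2.4)

    def test_linear_slow_velocity(self):
        z = np.linspace(1.8, 0.2, 86)  # 85 steps
        tr = zmax_trace(frames_from_z(z), fps=30, smooth_window=1)
        assert np.allclose(tr.velocity, -(1.6 / 85) * 30)

    def test_pad_rows_excluded_from_max(self):
        nf = frames_from_z([0.7])[0]  # pad rows are (0,0,0)
        assert zmax_trace([nf], fps=30).zmax[0] == 0.7

    def test_empty_frame_raises_gap_error(self):
        pts = np.zeros((500, 3))
        empty = NormalizedFrame(points=pts, n_real=0)
        with pytest.raises(TraceGapError):
            zmax_trace([empty], fps=30)

    def test_smoothing_reduces_single_frame_spike(self):
        z = np.full(40, 1.8)
        z[20] = 1.95
        raw = zmax_trace(frames_from_z(z), fps=30, smooth_window=1)
        smooth = zmax_trace(frames_from_z(z), fps=30, smooth_window=3)
        assert np.abs(smooth.velocity).max() < np.abs(raw.velocity).max()


class TestFindDescents:
    def test_flat_trace_no_candidates(self):
        assert find_descents(trace_from_z([1.8] * 60)) == []

    def test_single_drop_one_interval(self):
        z = np.concatenate([np.full(10, 1.8), np.linspace(1.8, 0.2, 20), np.full(10, 0.2)])
        (start, end), = find_descents(trace_from_z(z))
        assert start >= 9 and z[start] >= 1.2
        assert z[end] <= 0.5

    def test_bump_does_not_split_interval(self):
        # descend to 1.0, momentary 0.05 rise, then to the floor
        z = np.concatenate([
            np.full(5, 1.8), np.linspace(1.8, 1.0, 30),
            [1.02, 1.05, 1.02], np.linspace(1.0, 0.2, 30), np.full(5, 0.2),
        ])
        intervals = find_descents(trace_from_z(z))
        assert len(intervals) == 1

    def test_full_reascent_splits_intervals(self):
        # two complete stand->floor descents with a recovery between them
        drop = np.linspace(1.8, 0.2, 25)
        rise = np.linspace(0.2, 1.8, 25)
        z = np.concatenate([np.full(5, 1.8), drop, np.full(10, 0.2), rise,
                            np.full(10, 1.8), drop, np.full(5, 0.2)])
        assert len(find_descents(trace_from_z(z))) == 2

    def test_generated_fall_covers_scripted_drop(self, tiny_sequence):
        seq, script = tiny_sequence
        trace = zmax_trace(seq, smooth_window=3)
        (start, end), = find_descents(trace)
        assert trace.zmax[start] >= 1.2
        assert trace.zmax[end] <= 0.5


class TestClassifyTransition:
    @pytest.mark.parametrize(
        "frames,peak,expected",
        [
            (20, 2.32, "fall"),
            (80, 0.80, "lying_down"),
            (30, 1.88, "fall"),
            (25, 1.59, "fall"),
            (90, 0.65, "lying_down"),
            (50, 1.00, "lying_down"),  # ambiguous zone resolves by speed
            (50, 1.30, "fall"),
            (50, 1.20, "lying_down"),  # exact tie at v_fall is conservative
        ],
    )
    def test_rule(self, frames, peak, expected):
        assert classify_transition(frames, peak) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_transition(-1, 1.0)
        with pytest.raises(ValueError):
            classify_transition(10, -0.5)

    @settings(deadline=None, max_examples=200)
    @given(
        duration=st.integers(1, 120),
        peak=st.floats(0, 3, allow_nan=False),
        bump=st.floats(0, 1.0, allow_nan=False),
    )
    def test_monotone_in_peak_speed(self, duration, peak, bump):
        before = classify_transition(duration, peak)
        after = classify_transition(duration, peak + bump)
        assert not (before == "fall" and after == "lying_down")

    @settings(deadline=None, max_examples=200)
    @given(
        duration=st.integers(1, 120),
        extra=st.integers(0, 120),
        peak=st.floats(0, 3, allow_nan=False),
    )
    def test_monotone_in_duration(self, duration, extra, peak):
        before = classify_transition(duration, peak)
        after = classify_transition(duration + extra, peak)
        assert not (before == "lying_down" and after == "fall")


class TestDetectEvents:
    def test_generated_fall_yields_one_fall_event(self, gen_cfg):
        rng = np.random.default_rng(17)
        script = rf.MotionScript("fall", 25, 1.8, 0.2, 2.2, bump=False)
        seq = rf.generate_transition_sequence(script, gen_cfg, rng)
        events = detect_events(seq)
        assert [e.label for e in events] == ["fall"]
        assert events[0].peak_speed > 1.2

    def test_generated_slow_lying_yields_one_lying_event(self, gen_cfg):
        rng = np.random.default_rng(18)
        script = rf.MotionScript("slow_lying", 85, 1.8, 0.2, 0.7, bump=True)
        seq = rf.generate_transition_sequence(script, gen_cfg, rng)
        events = detect_events(seq)
        assert [e.label for e in events] == ["lying_down"]
        assert events[0].peak_speed <= 0.8

    def test_static_posture_sequence_empty(self, gen_cfg):
        rng = gen_cfg.rng()
        frames = [rf.sample_posture_frame(rf.PostureLabel.standing, gen_cfg, rng,
                                          index=i) for i in range(40)]
        seq = rf.Sequence(frames=frames, fps=30)
        assert detect_events(seq) == []


class TestConfigs:
    def test_detector_config_invariants(self):
        with pytest.raises(ValueError):
            DetectorConfig(z_high=0.4, z_low=0.5)
        with pytest.raises(ValueError):
            DetectorConfig(v_fall=0.5)
        with pytest.raises(ValueError):
            DetectorConfig(max_fall_frames=70, min_slow_frames=60)
        with pytest.raises(ValueError):
            DetectorConfig(smooth_window=2)

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            TransitionEvent(10, 10, 1.0, 1.0, "fall")
        e = TransitionEvent(10, 30, 2.0, 1.6, "fall")
        assert e.duration_frames == 21
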