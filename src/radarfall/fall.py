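"""Rule-based discrimination of falls from slow lying-down movements.

The discriminant is the per-frame body-top height z_max (largest z among
a frame's real points) and its finite-difference velocity
``v_t = (z_t - z_{t-1}) * fps``.  A slow, controlled lying-down movement
descends in stages over ~80–90 frames with |v| <= 0.8 m/s (often with a
momentary z_max rise while the trunk leans forward), whereas a fall is a
single uncontrolled drop over ~20–30 frames with peak |v| around
1.5–2.4 m/s.

The empirical envelopes leave a gap (0.8 vs ~1.5 m/s; 30 vs 80 frames);
the default decision thresholds sit inside that gap and are exposed in
:class:`DetectorConfig`.  Ambiguous intervals resolve by peak speed,
with exact ties going to ``lying_down`` (false fall alarms are the
costlier error in a monitoring deployment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Sequence
from .preprocessing import NormalizedFrame

__all__ = [
    "ZmaxTrace",
    "DetectorConfig",
    "TransitionEvent",
    "TraceGapError",
    "zmax_trace",
    "find_descents",
    "classify_transition",
    "detect_events",
]


class TraceGapError(ValueError):
    """A frame with zero real points interrupts the z_max trace."""


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds.

    ``z_high``/``z_low`` bracket a descent (it must start above the
    standing band's floor and end below the lying band's ceiling);
    ``v_fall`` is the peak-speed threshold separating falls from the
    <= 0.8 m/s slow-lying envelope; the frame-count cut-offs sit between
    the 20–30-frame fall and 80–90-frame slow-lying envelopes.
    """

    fps: float = 30.0
    z_high: float = 1.2
    z_low: float = 0.5
    v_fall: float = 1.2
    max_fall_frames: int = 45
    min_slow_frames: int = 60
    smooth_window: int = 3
    v_slow: float = 0.8  # slow-lying velocity envelope

    def __post_init__(self) -> None:
        if self.z_high <= self.z_low:
            raise ValueError("z_high must exceed z_low")
        if self.v_fall <= self.v_slow:
            raise ValueError("v_fall must exceed the slow-lying envelope (0.8 m/s)")
        if self.max_fall_frames >= self.min_slow_frames:
            raise ValueError("max_fall_frames must be below min_slow_frames")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd count")


@dataclass(frozen=True)
class ZmaxTrace:
    """Per-frame body-top height and its (smoothed) velocity.

    ``velocity`` is aligned to frames 1..T-1 of ``zmax`` (the raw finite
    difference has one fewer entry); ``velocity[t-1]`` is the smoothed
    speed of the step into frame ``t``.
    """

    zmax: np.ndarray
    velocity: np.ndarray
    fps: float


@dataclass(frozen=True)
class TransitionEvent:
    """One classified descent interval."""

    start_frame: int
    end_frame: int
    peak_speed: float
    z_drop: float
    label: str  # "fall" | "lying_down"

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be non-negative")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _frame_zmax(frame) -> float:
    if isinstance(frame, NormalizedFrame):
        if frame.n_real == 0:
            raise TraceGapError(f"frame {frame.source_index} has no real points")
        return frame.z_max
    if len(frame) == 0:
        raise TraceGapError(f"frame {frame.index} has no points")
    return frame.z_max


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(v) == 0:
        return v
    pad = window // 2
    vp = np.pad(v, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(vp, kernel, mode="valid")


def zmax_trace(seq, fps: float | None = None, smooth_window: int = 3) -> ZmaxTrace:
    """Extract the z_max trace and its smoothed velocity.

    ``seq`` may be a :class:`~radarfall.core.Sequence` or an iterable of
    frames / NormalizedFrames (pad rows are excluded from the max via
    ``n_real``).  Velocity is the finite difference scaled by ``fps``,
    then smoothed with a centered moving average.
    """
    if isinstance(seq, Sequence):
        frames = seq.frames
        fps = seq.fps if fps is None else fps
    else:
        frames = list(seq)
        if fps is None:
            fps = 30.0
    z = np.array([_frame_zmax(f) for f in frames], dtype=float)
    raw_v = np.diff(z) * fps
    return ZmaxTrace(zmax=z, velocity=_smooth(raw_v, smooth_window), fps=fps)


def find_descents(trace: ZmaxTrace, cfg: DetectorConfig | None = None) -> list[tuple[int, int]]:
    """Maximal non-overlapping intervals where z_max crosses from above
    ``z_high`` down to below ``z_low``.

    A momentary rise back above ``z_high`` does not split an interval if
    it is brief (< ``smooth_window`` frames) or shallow (< 0.1 m above
    ``z_high``), tolerating the lean-forward bump of a slow lying-down.
    """
    cfg = cfg or DetectorConfig()
    z = trace.zmax
    intervals: list[tuple[int, int]] = []
    t = 0
    T = len(z)
    while t < T:
        if z[t] < cfg.z_high:
            t += 1
            continue
        # last frame still at/above z_high before the descent
        while t + 1 < T and z[t + 1] >= cfg.z_high:
            t += 1
        start = t
        u = t + 1
        end = None
        while u < T:
            if z[u] <= cfg.z_low:
                end = u
                break
            if z[u] >= cfg.z_high:
                # candidate re-ascent: tolerate if brief and shallow
                r = u
                while r < T and z[r] >= cfg.z_high:
                    r += 1
                rise_len = r - u
                rise_amp = z[u:r].max() - cfg.z_high
                if rise_len < cfg.smooth_window or rise_amp < 0.1:
                    u = r
                    continue
                break
            u += 1
        if end is not None:
            intervals.append((start, end))
            t = end + 1
        else:
            t = u if u > t else t + 1
    return intervals


def classify_transition(duration_frames: int, peak_speed: float,
                        cfg: DetectorConfig | None = None) -> str:
    """Label a descent from its duration and peak |z_max velocity|.

    ``fall`` iff the peak speed reaches ``v_fall`` and the movement was
    short (<= ``max_fall_frames``); ``lying_down`` iff the peak speed
    stays inside the slow envelope (<= 0.8 m/s) and the movement was
    long (>= ``min_slow_frames``); otherwise peak speed alone decides,
    with an exact tie at ``v_fall`` going to ``lying_down``.
    """
    cfg = cfg or DetectorConfig()
    if duration_frames < 0 or peak_speed < 0:
        raise ValueError("duration and peak speed must be non-negative")
    if peak_speed >= cfg.v_fall and duration_frames <= cfg.max_fall_frames:
        return "fall"
    if peak_speed <= cfg.v_slow and duration_frames >= cfg.min_slow_frames:
        return "lying_down"
    return "fall" if peak_speed > cfg.v_fall else "lying_down"


def detect_events(seq, cfg: DetectorConfig | None = None) -> list[TransitionEvent]:
    """Full detector: z_max trace -> descent intervals -> per-interval
    features -> rule classification.  Events are emitted in time order."""
    cfg = cfg or DetectorConfig()
    trace = zmax_trace(seq, fps=cfg.fps if not isinstance(seq, Sequence) else None,
                       smooth_window=cfg.smooth_window)
    events = []
    for start, end in find_descents(trace, cfg):
        # velocity[t-1] is the step into frame t
        seg_v = trace.velocity[max(start, 1) - 1:end]
        peak = float(np.abs(seg_v).max()) if len(seg_v) else 0.0
        duration = end - start + 1
        label = classify_transition(duration, peak, cfg)
        events.append(
            TransitionEvent(
                start_frame=start,
                end_frame=end,
                peak_speed=peak,
                z_drop=float(trace.zmax[start] - trace.zmax[end]),
                label=label,
            )
        )
    return events
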