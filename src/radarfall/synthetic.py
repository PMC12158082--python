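"""Synthetic 4D-radar point-cloud generator.

Emulates the acquisition geometry of a ceiling-height (2 m) mmWave
imaging radar watching a 7 m x 7 m area at 30 frames/s: a person at a
configurable range produces a sparse cloud of body-surface detections
whose count shrinks with distance, and whole movements (lying down
slowly vs. falling) produce characteristic body-top height (z_max)
trajectories.

The generator is deliberately coarse — a capsule stack (head / torso /
legs), not a kinematic skeleton — because the downstream classifier only
needs class-separable silhouettes and z-profiles.  Every output is a
pure function of (arguments, seed).

Motion kinematics are constrained so generated sequences respect the
empirical envelopes of the two movement classes:

* slow lying-down: 80–90 frames, |z_max velocity| <= 0.8 m/s throughout,
  multi-stage descent (stand -> sit -> lean, with an optional momentary
  z_max rise while leaning forward) ending near the floor;
* fall: 20–30 frames, single fast drop with peak |z_max velocity| in
  [1.5, 2.4] m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Frame, PostureLabel, RadarPoint, Sequence

__all__ = [
    "GeneratorConfig",
    "MotionScript",
    "BodySegmentModel",
    "POSTURE_TOP_BANDS",
    "point_count_range",
    "acquisition_frame_count",
    "sample_posture_frame",
    "generate_transition_sequence",
    "generate_labeled_dataset",
    "sample_motion_script",
]

#: measured point-cloud count bounds per frame, by target range (m)
_COUNT_TABLE = {
    1: (900, 1500),
    2: (800, 1400),
    3: (700, 1400),
    4: (700, 1300),
    5: (600, 1200),
    6: (400, 1100),
    7: (200, 900),
}

#: body-top (crown) height band per posture, meters
POSTURE_TOP_BANDS = {
    PostureLabel.standing: (1.6, 2.0),
    PostureLabel.sitting: (0.8, 1.3),
    PostureLabel.lying: (0.2, 0.5),
}


def point_count_range(distance_m: float) -> tuple[int, int]:
    """Bounds on points per frame for a target at ``distance_m`` meters.

    Integer distances return the measured bounds; non-integer distances
    interpolate linearly between neighbouring rows.
    """
    if not (1.0 <= distance_m <= 7.0):
        raise ValueError(f"distance must be in [1, 7] m, got {distance_m}")
    lo_d = int(np.floor(distance_m))
    hi_d = int(np.ceil(distance_m))
    if lo_d == hi_d:
        return _COUNT_TABLE[lo_d]
    w = distance_m - lo_d
    lo = (1 - w) * _COUNT_TABLE[lo_d][0] + w * _COUNT_TABLE[hi_d][0]
    hi = (1 - w) * _COUNT_TABLE[lo_d][1] + w * _COUNT_TABLE[hi_d][1]
    return int(round(lo)), int(round(hi))


def acquisition_frame_count(fps: float = 30.0, seconds: float = 50.0) -> int:
    """Frames captured per posture in one acquisition session
    (default 30 frames/s for 50 s -> 1500)."""
    if fps <= 0 or seconds <= 0:
        raise ValueError("fps and seconds must be positive")
    return int(round(fps * seconds))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic acquisition.

    ``distance_m`` is the target's range from the radar (governs point
    counts); ``noise_sd`` the Gaussian jitter on point positions (m);
    ``dropout_rate`` the probability of losing a below-knee point at
    very close range (< 1.5 m), emulating the lower-body loss seen there.
    """

    seed: int = 0
    fps: float = 30.0
    distance_m: float = 3.0
    noise_sd: float = 0.02
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not (1.0 <= self.distance_m <= 7.0):
            raise ValueError("distance_m must be in [1, 7]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class MotionScript:
    """Ground-truth plan for one whole-body transition.

    ``peak_speed`` is the magnitude of the fastest z_max descent the
    trace will contain (the generated trace hits it exactly on the
    descent plateau).  ``bump`` adds the momentary z_max rise seen while
    leaning the upper body forward before the final descent of a slow
    lying-down movement.
    """

    kind: str  # "slow_lying" | "fall"
    duration_frames: int
    zmax_start: float
    zmax_end: float
    peak_speed: float
    bump: bool = True
    bump_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("slow_lying", "fall"):
            raise ValueError(f"kind must be slow_lying|fall, got {self.kind!r}")
        if self.zmax_end >= self.zmax_start:
            raise ValueError("zmax_end must be below zmax_start")
        if self.kind == "slow_lying":
            if not (80 <= self.duration_frames <= 90):
                raise ValueError("slow_lying duration must be 80-90 frames")
            if not (0.0 < self.peak_speed <= 0.8):
                raise ValueError("slow_lying peak speed must be <= 0.8 m/s")
        else:
            if not (20 <= self.duration_frames <= 30):
                raise ValueError("fall duration must be 20-30 frames")
            if not (1.5 <= self.peak_speed <= 2.4):
                raise ValueError("fall peak speed must be in [1.5, 2.4] m/s")

    def validate_feasible(self, fps: float) -> None:
        """The scripted drop must fit inside the scripted duration at the
        scripted peak speed (plus stage/bump overhead for slow lying)."""
        dz = self.zmax_start - self.zmax_end
        need = dz * fps / self.peak_speed
        if self.kind == "slow_lying" and self.bump:
            need += 10  # bump up+down frames
        if need > self.duration_frames - 1:
            raise ValueError(
                f"script infeasible: dropping {dz:.2f} m at {self.peak_speed} m/s "
                f"needs ~{need:.0f} frames > {self.duration_frames}"
            )


@dataclass(frozen=True)
class BodySegmentModel:
    """Coarse capsule-stack body: vertical segments (z_lo, z_hi, radius,
    weight) around a body axis, horizontal for the lying posture."""

    posture: PostureLabel
    top: float  # crown height, m
    segments: tuple = field(default=())
    horizontal: bool = False

    @staticmethod
    def for_posture(posture: PostureLabel, top: float) -> "BodySegmentModel":
        band = POSTURE_TOP_BANDS.get(posture)
        if band is None:
            raise ValueError(f"cannot build body model for posture {posture}")
        if not (band[0] <= top <= band[1]):
            raise ValueError(f"top {top} outside {posture.value} band {band}")
        if posture == PostureLabel.standing:
            segs = (
                (0.00 * top, 0.50 * top, 0.13, 0.30),  # legs
                (0.45 * top, 0.85 * top, 0.18, 0.50),  # torso
                (0.86 * top, 1.00 * top, 0.10, 0.20),  # head
            )
            return BodySegmentModel(posture, top, segs)
        if posture == PostureLabel.sitting:
            segs = (
                (0.10, 0.45, 0.25, 0.35),              # lap/legs block
                (0.40, 0.88 * top, 0.18, 0.45),        # torso
                (0.85 * top, 1.00 * top, 0.10, 0.20),  # head
            )
            return BodySegmentModel(posture, top, segs)
        # lying: one horizontal slab
        segs = ((0.0, top, 0.85, 1.0),)
        return BodySegmentModel(posture, top, segs, horizontal=True)

    def sample_points(self, n: int, center_xy: tuple[float, float],
                      noise_sd: float, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n`` surface-ish points; the crown point (exactly at
        ``top``) is always included so the frame's z_max equals ``top``."""
        cx, cy = center_xy
        weights = np.array([s[3] for s in self.segments])
        counts = rng.multinomial(max(n - 1, 0), weights / weights.sum())
        pts = []
        for (z_lo, z_hi, radius, _), m in zip(self.segments, counts):
            if m == 0:
                continue
            z = rng.uniform(z_lo, z_hi, m)
            theta = rng.uniform(0, 2 * np.pi, m)
            r = radius * np.sqrt(rng.uniform(0.3, 1.0, m))
            if self.horizontal:
                # body stretched along x, lying on the floor
                x = cx + rng.uniform(-0.85, 0.85, m)
                y = cy + r * np.sin(theta) * 0.4
            else:
                x = cx + r * np.cos(theta)
                y = cy + r * np.sin(theta)
            pts.append(np.column_stack([x, y, z]))
        out = np.vstack(pts) if pts else np.empty((0, 3))
        out += rng.normal(0.0, noise_sd, out.shape)
        np.clip(out[:, 2], 0.0, self.top, out=out[:, 2])
        crown = np.array([[cx, cy, self.top]])
        out = np.vstack([crown, out])
        return out


def _points_to_frame(index: int, pts: np.ndarray) -> Frame:
    return Frame(index=index,
                 points=[RadarPoint(float(x), float(y), float(z)) for x, y, z in pts])


def sample_posture_frame(
    posture: PostureLabel,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    index: int = 0,
) -> Frame:
    """One static-posture frame at the configured range.

    Point count is uniform within :func:`point_count_range`; below 1.5 m
    range, below-knee points are dropped with ``cfg.dropout_rate``
    (close-range lower-body loss).
    """
    if posture not in POSTURE_TOP_BANDS:
        raise ValueError(f"cannot generate posture {posture!r}")
    if rng is None:
        rng = cfg.rng()
    lo, hi = point_count_range(cfg.distance_m)
    n = int(rng.integers(lo, hi + 1))
    band = POSTURE_TOP_BANDS[posture]
    top = float(rng.uniform(*band))
    body = BodySegmentModel.for_posture(posture, top)
    cx = float(rng.uniform(-0.5, 0.5))
    pts = body.sample_points(n, (cx, cfg.distance_m), cfg.noise_sd, rng)
    if cfg.distance_m < 1.5 and cfg.dropout_rate > 0:
        low = pts[:, 2] < 0.5
        drop = low & (rng.random(len(pts)) < cfg.dropout_rate)
        drop[0] = False  # never drop the crown
        kept = pts[~drop]
        # keep the count within the measured bounds despite dropout
        while len(kept) < lo:
            kept = np.vstack([kept, kept[rng.integers(1, len(kept))]])
        pts = kept
    else:
        pts = pts[:n] if len(pts) > n else pts
    return _points_to_frame(index, pts)


def _descent_deltas(dz: float, peak: float, fps: float) -> np.ndarray:
    """Per-frame z deltas for a linear descent of ``dz`` meters whose
    finite-difference speed plateaus at exactly ``peak`` m/s."""
    step = peak / fps
    n_full = int(dz / step)
    rem = dz - n_full * step
    deltas = [-step] * n_full
    if rem > 1e-12:
        deltas.append(-rem)
    return np.array(deltas)


def _bump_deltas(amp: float, n: int = 10) -> np.ndarray:
    """Raised-cosine momentary rise of ``amp`` meters over ``n`` frames
    (net zero displacement)."""
    t = np.linspace(0, 2 * np.pi, n + 1)
    z = amp * 0.5 * (1 - np.cos(t))
    return np.diff(z)


def zmax_profile(script: MotionScript, cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """The scripted per-frame z_max trace (length = duration_frames).

    Jitter is added to the ideal trace but per-frame increments are
    clipped to ``peak_speed / fps``, so the finite-difference velocity
    never exceeds the scripted peak and equals it exactly on the descent
    plateau.
    """
    script.validate_feasible(cfg.fps)
    if rng is None:
        rng = cfg.rng()
    D = script.duration_frames
    z0, z1 = script.zmax_start, script.zmax_end
    if script.kind == "fall":
        deltas = _descent_deltas(z0 - z1, script.peak_speed, cfg.fps)
    else:
        z_sit = z1 + 0.5 * (z0 - z1)
        parts = [_descent_deltas(z0 - z_sit, script.peak_speed, cfg.fps)]
        if script.bump:
            parts.append(_bump_deltas(script.bump_amplitude))
        parts.append(_descent_deltas(z_sit - z1, script.peak_speed, cfg.fps))
        deltas = np.concatenate(parts)
    if len(deltas) > D - 1:
        raise ValueError("script infeasible after discretization")
    # distribute hold frames: small lead-in at z0, pauses between stages
    # folded into a trailing hold at z1
    lead = (D - 1 - len(deltas)) // 3
    trail = D - 1 - len(deltas) - lead
    deltas = np.concatenate([np.zeros(lead), deltas, np.zeros(trail)])
    # bounded jitter: never let an increment exceed the scripted peak
    step_cap = script.peak_speed / cfg.fps
    jitter = rng.normal(0.0, min(cfg.noise_sd, 0.004), D - 1)
    deltas = np.clip(deltas + jitter, -step_cap, step_cap)
    z = z0 + np.concatenate([[0.0], np.cumsum(deltas)])
    return np.clip(z, 0.05, None)


def generate_transition_sequence(
    script: MotionScript,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> Sequence:
    """Generate a labeled point-cloud sequence following ``script``.

    Each frame's cloud is a morph between the standing and lying body
    models whose crown sits exactly on the scripted z_max trace, so the
    sequence's measured z_max/velocity trace obeys the script envelopes.
    """
    if rng is None:
        rng = cfg.rng()
    z = zmax_profile(script, cfg, rng)
    lo, hi = point_count_range(cfg.distance_m)
    cx = float(rng.uniform(-0.5, 0.5))
    frames = []
    z_top_stand = script.zmax_start
    for t, z_top in enumerate(z):
        n = int(rng.integers(lo, hi + 1))
        # morph fraction: 1 = fully upright, 0 = flat on the floor
        u = float(np.clip((z_top - 0.3) / max(z_top_stand - 0.3, 1e-9), 0.0, 1.0))
        body = _morph_body(z_top, u)
        pts = body.sample_points(n, (cx, cfg.distance_m), cfg.noise_sd, rng)
        frames.append(_points_to_frame(t, pts))
    return Sequence(frames=frames, fps=cfg.fps, label=script.kind)


def _morph_body(top: float, upright: float) -> BodySegmentModel:
    """Body model at an intermediate crouch: vertical capsules squashed
    to the current crown height, widening toward the lying silhouette."""
    top = max(top, 0.08)
    if upright < 0.15:
        segs = ((0.0, top, 0.5 + 0.35 * (1 - upright), 1.0),)
        return BodySegmentModel(PostureLabel.lying, top, segs, horizontal=True)
    spread = 0.18 + 0.3 * (1 - upright)
    segs = (
        (0.00 * top, 0.55 * top, spread, 0.45),
        (0.50 * top, 0.90 * top, spread * 0.9, 0.35),
        (0.88 * top, 1.00 * top, 0.10, 0.20),
    )
    return BodySegmentModel(PostureLabel.standing, top, segs)


def sample_motion_script(kind: str, rng: np.random.Generator,
                         fps: float = 30.0, bump: bool = True) -> MotionScript:
    """Draw a random but feasible script from the movement-class
    envelopes (slow: 80–90 frames, peak <= 0.8 m/s; fall: 20–30 frames,
    peak 1.5–2.4 m/s)."""
    if kind == "slow_lying":
        duration = int(rng.integers(80, 91))
        overhead = (10 if bump else 0) + 4  # bump frames + discretization slack
        z1 = float(rng.uniform(0.2, 0.35))
        dz_max = 0.8 * (duration - 1 - overhead) / fps
        z0 = float(rng.uniform(1.7, min(2.0, z1 + dz_max)))
        peak_min = (z0 - z1) * fps / (duration - 1 - overhead)
        peak = float(rng.uniform(max(0.62, peak_min), 0.8))
        return MotionScript("slow_lying", duration, z0, z1, peak, bump=bump)
    if kind == "fall":
        z0 = float(rng.uniform(1.6, 2.0))
        z1 = float(rng.uniform(0.15, 0.3))
        dz = z0 - z1
        # the drop must fit inside at most 30 frames at the chosen peak
        peak_min = max(1.5, dz * fps / 28.0)
        peak = float(rng.uniform(peak_min, 2.4))
        drop_frames = int(np.ceil(dz * fps / peak)) + 1
        duration = int(min(30, max(20, drop_frames + int(rng.integers(2, 7)))))
        return MotionScript("fall", duration, z0, z1, peak, bump=False)
    raise ValueError(f"kind must be slow_lying|fall, got {kind!r}")


def generate_labeled_dataset(
    n_per_class: int, cfg: GeneratorConfig
) -> tuple[list[Frame], list[PostureLabel]]:
    """Balanced labeled posture frames (``n_per_class`` each of standing,
    sitting, lying), deterministically shuffled under ``cfg.seed``."""
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = cfg.rng()
    frames: list[Frame] = []
    labels: list[PostureLabel] = []
    for posture in (PostureLabel.standing, PostureLabel.sitting, PostureLabel.lying):
        for _ in range(n_per_class):
            frames.append(sample_posture_frame(posture, cfg, rng, index=len(frames)))
            labels.append(posture)
    order = rng.permutation(len(frames))
    frames = [frames[i] for i in order]
    labels = [labels[i] for i in order]
    for i, f in enumerate(frames):
        f.index = i
    return frames, labels
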