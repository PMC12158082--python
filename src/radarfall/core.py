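"""Domain types and tabular I/O for radar point-cloud frames.

A 4D imaging radar reports each detection as a point ``(x, y, z)`` in a
floor-anchored frame (``z`` is height above the floor, in meters), with
optional Doppler velocity, relative Doppler power and a timestamp.  One
update cycle yields a :class:`Frame`; a time-ordered run of frames at a
fixed frame rate is a :class:`Sequence`.

The canonical interchange format is a CSV "frame table" with one row per
point (columns ``frame, x, y, z`` plus optional ``v, power, t``).  Trial
summaries used to score the rule-based fall detector are small CSV
fixtures of :class:`TrialRecord` rows.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

__all__ = [
    "PostureLabel",
    "RadarPoint",
    "Frame",
    "Sequence",
    "TrialRecord",
    "BoundsError",
    "FrameTableError",
    "COVERAGE_BOUNDS",
    "read_frame_table",
    "write_frame_table",
    "read_trial_table",
    "load_trial_fixture",
    "parse_range",
    "write_pcd",
    "write_ply",
]

#: Coverage of the monitored area: 7 m x 7 m floor patch in front of the
#: radar (x lateral, radar-centered; y forward), radar mounted at 2 m so
#: a detection cannot plausibly sit much above it.
COVERAGE_BOUNDS = {"x": (-3.5, 3.5), "y": (0.0, 7.0), "z": (0.0, 2.5)}


class BoundsError(ValueError):
    """A point lies outside the radar's monitored volume."""


class FrameTableError(ValueError):
    """A frame-table CSV is malformed (missing column, bad cell)."""


class PostureLabel(str, Enum):
    """Posture classes. ``unknown`` is a curation bucket for ambiguous
    captures, never a classifier output class."""

    standing = "standing"
    sitting = "sitting"
    lying = "lying"
    unknown = "unknown"


@dataclass(frozen=True)
class RadarPoint:
    """One radar detection: position in meters, optional Doppler fields."""

    x: float
    y: float
    z: float
    v: float | None = None
    power: float | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates: {(self.x, self.y, self.z)}")

    def check_bounds(self) -> None:
        for name, value in (("x", self.x), ("y", self.y), ("z", self.z)):
            lo, hi = COVERAGE_BOUNDS[name]
            if not (lo <= value <= hi):
                raise BoundsError(
                    f"{name}={value} outside monitored volume [{lo}, {hi}]"
                )


@dataclass
class Frame:
    """The set of points from one radar update cycle.

    Point order carries no semantics before canonicalization.
    """

    index: int
    points: list[RadarPoint] = field(default_factory=list)
    timestamp: float | None = None

    def __len__(self) -> int:
        return len(self.points)

    def xyz(self) -> np.ndarray:
        """Coordinates as an ``(N, 3)`` float array (copy)."""
        if not self.points:
            return np.empty((0, 3), dtype=float)
        return np.array([(p.x, p.y, p.z) for p in self.points], dtype=float)

    @property
    def z_max(self) -> float:
        if not self.points:
            raise ValueError(f"frame {self.index} has no points")
        return max(p.z for p in self.points)


@dataclass
class Sequence:
    """Time-ordered frames at a fixed frame rate.

    ``label`` optionally records the ground-truth motion kind for
    synthetic sequences (``slow_lying``, ``fall``, or a static posture).
    """

    frames: list[Frame]
    fps: float = 30.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class TrialRecord:
    """One summarized trial of a lying-down-slowly or fall movement.

    ``lo``/``hi`` bound either the z_max excursion (variant ``zmax``,
    meters) or the z_max velocity excursion (variant ``velocity``, m/s)
    over the trial; ``frames`` is the number of frames the movement
    spanned; ``state`` is the ground truth and ``detection`` what the
    monitoring system reported.
    """

    volunteer: int
    lo: float
    hi: float
    frames: int
    state: str
    detection: str
    variant: str

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"lo {self.lo} > hi {self.hi}")
        if self.frames <= 0:
            raise ValueError("frames must be positive")
        if self.state not in ("lying", "fall"):
            raise ValueError(f"state must be lying|fall, got {self.state!r}")
        if self.detection not in ("lying", "fall"):
            raise ValueError(f"detection must be lying|fall, got {self.detection!r}")
        if self.variant not in ("zmax", "velocity"):
            raise ValueError(f"variant must be zmax|velocity, got {self.variant!r}")

    @property
    def peak_magnitude(self) -> float:
        """Largest absolute excursion endpoint (|lo| or |hi|)."""
        return max(abs(self.lo), abs(self.hi))


_OPTIONAL_COLS = ("v", "power", "t")

# accept ASCII '-', Unicode minus U+2212 and explicit '+'
_RANGE_RE = re.compile(r"^\s*([+\-−]?[\d.]+)\s*~\s*([+\-−]?[\d.]+)\s*$")


def parse_range(text: str) -> tuple[float, float]:
    """Parse a ``"lo~hi"`` excursion string into ``(lo, hi)`` floats.

    Accepts ASCII ``-``, Unicode minus and an optional leading ``+``,
    e.g. ``"−2.32~+2.10"`` -> ``(-2.32, 2.10)``.
    """
    m = _RANGE_RE.match(str(text))
    if m is None:
        raise ValueError(f"malformed range string: {text!r}")
    lo, hi = (float(g.replace("−", "-")) for g in m.groups())
    return lo, hi


def read_frame_table(path: str | Path, bounds_check: bool = False) -> Sequence:
    """Read a frame-table CSV into a :class:`Sequence`.

    The CSV must have header columns ``frame, x, y, z``; optional columns
    ``v, power, t`` populate the corresponding :class:`RadarPoint` fields.
    Rows are grouped by their ``frame`` value; frames are emitted in
    ascending index order.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FrameTableError(f"{path}: missing mandatory column(s) {missing}")
    for col in ("frame", "x", "y", "z", *(c for c in _OPTIONAL_COLS if c in df.columns)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FrameTableError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0]}"
            )
        df[col] = coerced
    if bounds_check:
        offending: list[int] = []
        for name, (lo, hi) in COVERAGE_BOUNDS.items():
            offending += list(df.index[(df[name] < lo) | (df[name] > hi)])
        if offending:
            raise BoundsError(
                f"{path}: {len(offending)} row(s) outside monitored volume: "
                f"{sorted(set(offending))[:10]}"
            )

    frames = []
    for idx, grp in df.groupby("frame", sort=True):
        pts = [
            RadarPoint(
                x=row.x,
                y=row.y,
                z=row.z,
                v=getattr(row, "v", None) if "v" in df.columns else None,
                power=getattr(row, "power", None) if "power" in df.columns else None,
                t=getattr(row, "t", None) if "t" in df.columns else None,
            )
            for row in grp.itertuples(index=False)
        ]
        frames.append(Frame(index=int(idx), points=pts))
    return Sequence(frames=frames)


def write_frame_table(seq: Sequence, path: str | Path) -> None:
    """Write a :class:`Sequence` as a frame-table CSV (re-readable by
    :func:`read_frame_table`). Optional columns appear only when at least
    one point carries the field."""
    rows = []
    for frame in seq:
        for p in frame.points:
            rows.append(
                {"frame": frame.index, "x": p.x, "y": p.y, "z": p.z,
                 "v": p.v, "power": p.power, "t": p.t}
            )
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "z", "v", "power", "t"])
    for col in _OPTIONAL_COLS:
        if df.empty or df[col].isna().all():
            df = df.drop(columns=[col])
    if df.empty:
        df = pd.DataFrame(columns=["frame", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_trial_table(path: str | Path) -> list[TrialRecord]:
    """Read a trial-summary CSV into :class:`TrialRecord` rows.

    Two layouts are accepted: numeric ``lo``/``hi`` columns, or a single
    ``range`` column holding ``"lo~hi"`` strings (parsed with
    :func:`parse_range`).  Mandatory columns: ``volunteer, frames, state,
    detection, variant``.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"volunteer", "frames", "state", "detection", "variant"}
    missing = required - set(df.columns)
    if missing:
        raise FrameTableError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        if "range" in df.columns:
            try:
                lo, hi = parse_range(row["range"])
            except ValueError as exc:
                raise FrameTableError(f"{path}: row {i}, column 'range': {exc}") from exc
        else:
            if "lo" not in df.columns or "hi" not in df.columns:
                raise FrameTableError(f"{path}: need either lo/hi or range column")
            lo, hi = float(row["lo"]), float(row["hi"])
        records.append(
            TrialRecord(
                volunteer=int(row["volunteer"]),
                lo=lo,
                hi=hi,
                frames=int(row["frames"]),
                state=row["state"],
                detection=row["detection"],
                variant=row["variant"],
            )
        )
    return records


def load_trial_fixture(variant: str) -> list[TrialRecord]:
    """Load one of the packaged trial-summary fixtures.

    ``variant="zmax"`` gives the 20 trials summarized by z_max excursion;
    ``variant="velocity"`` the same trials summarized by z_max-velocity
    excursion (10 slow-lying + 10 fall each).
    """
    if variant not in ("zmax", "velocity"):
        raise ValueError(f"variant must be zmax|velocity, got {variant!r}")
    ref = resources.files("radarfall.data") / f"trials_{variant}.csv"
    with resources.as_file(ref) as p:
        return read_trial_table(p)


def write_pcd(points: np.ndarray | Iterable[TypingSequence[float]], path: str | Path) -> None:
    """Write an ``(N, 3)`` xyz array as PCD v0.7 ASCII."""
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float).reshape(-1, 3)
    n = len(pts)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for x, y, z in pts:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")


def write_ply(points: np.ndarray | Iterable[TypingSequence[float]], path: str | Path) -> None:
    """Write an ``(N, 3)`` xyz array as PLY ASCII."""
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\nend_header\n"
        )
        for x, y, z in pts:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
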