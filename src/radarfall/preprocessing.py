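"""Canonicalization of variable-size point-cloud frames.

A convolutional classifier needs a fixed-size, consistently ordered
input, but a radar frame carries anywhere from a couple hundred to
~1500 points in arbitrary order.  The pipeline here makes every frame a
canonical 500x3 array:

1. keep xyz only (Doppler velocity/power/time dropped),
2. if the frame has more than 500 points, reduce it to the 500 centroids
   of a k-means clustering (Lloyd's algorithm minimizing within-cluster
   squared distance),
3. sort points lexicographically by (x, then y, then z) ascending so the
   input order is canonical,
4. back-pad with (0, 0, 0) rows up to exactly 500.

Reduction/sorting happen before padding so the zero pad rows always
trail the real points (zeros would otherwise sort to the front).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Frame

__all__ = [
    "N_CANONICAL",
    "NormalizedFrame",
    "select_xyz",
    "lex_sort",
    "kmeans_reduce",
    "kmeans_objective",
    "zero_pad",
    "standardize_frame",
    "standardize_sequence",
]

#: canonical number of points per frame fed to the classifier
N_CANONICAL = 500


@dataclass(frozen=True)
class NormalizedFrame:
    """A fixed-size canonical frame: exactly ``n`` xyz rows, the first
    ``n_real`` being real points in lexicographic order, the rest exactly
    (0, 0, 0)."""

    points: np.ndarray  # (n, 3) float
    n_real: int
    source_index: int = 0

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not (0 <= self.n_real <= len(self.points)):
            raise ValueError("n_real out of range")
        if len(self.points) > self.n_real and np.any(self.points[self.n_real:]):
            raise ValueError("pad rows must be exactly (0, 0, 0)")

    @property
    def z_max(self) -> float:
        """Largest height among the real (non-pad) points."""
        if self.n_real == 0:
            raise ValueError("frame has no real points")
        return float(self.points[: self.n_real, 2].max())


def select_xyz(frame: Frame | np.ndarray) -> np.ndarray:
    """Return the frame's coordinates as an ``(N, 3)`` array, dropping
    Doppler velocity, power and time.  Idempotent on arrays."""
    if isinstance(frame, Frame):
        return frame.xyz()
    pts = np.asarray(frame, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] < 3:
        raise ValueError(f"expected (N, >=3) array, got {pts.shape}")
    return pts[:, :3].copy()


def lex_sort(points: np.ndarray) -> np.ndarray:
    """Order points ascending by x, breaking ties by y, then z.

    The sort is stable: points with identical coordinates keep their
    input order.  Comparisons are exact (no epsilon).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    # np.lexsort is stable and sorts by the LAST key first
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order]


def kmeans_objective(points: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squared distances of ``points`` to their
    nearest centroid (the k-means objective)."""
    d2 = cdist(points, centroids, "sqeuclidean")
    return float(d2.min(axis=1).sum())


def _kmeanspp_init(pts: np.ndarray, k: int, rng: np.random.Generator,
                   n_candidates: int = 8) -> np.ndarray:
    """Greedy k-means++ seeding: first center uniform; each subsequent
    center is the best (lowest resulting potential) of several candidates
    drawn with probability proportional to squared distance from the
    nearest chosen center."""
    n = len(pts)
    centers = np.empty((k, 3), dtype=float)
    centers[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers[j:] = pts[rng.integers(n, size=k - j)]
            break
        cand = rng.choice(n, size=min(n_candidates, n), p=d2 / total)
        cand_d2 = cdist(pts, pts[cand], "sqeuclidean")
        potential = np.minimum(d2[:, None], cand_d2).sum(axis=0)
        best = int(potential.argmin())
        centers[j] = pts[cand[best]]
        d2 = np.minimum(d2, cand_d2[:, best])
    return centers


def kmeans_reduce(
    points: np.ndarray,
    k: int = N_CANONICAL,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    return_history: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Reduce an oversized point set to ``k`` cluster centroids.

    Lloyd's algorithm with k-means++-style seeding; the objective
    (within-cluster sum of squared distances) is non-increasing across
    iterations.  Empty clusters are re-seeded at the point currently
    farthest from its centroid.  Deterministic under ``seed``.

    With ``return_history=True`` also returns the per-iteration objective
    values (useful for auditing convergence).
    """
    pts = np.asarray(points, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if len(pts) <= k:
        raise ValueError(
            f"kmeans_reduce needs more than k={k} points, got {len(pts)}; pad instead"
        )
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(pts, k, rng)
    history: list[float] = []
    prev_assign = None
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = cdist(pts, centers, "sqeuclidean")
        assign = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(pts)), assign].sum())
        history.append(obj)
        # update step
        counts = np.bincount(assign, minlength=k)
        sums = np.zeros((k, 3))
        np.add.at(sums, assign, pts)
        empty = counts == 0
        nonempty = ~empty
        centers = centers.copy()
        centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        if empty.any():
            # re-seed each empty cluster at the farthest outlier
            far = np.argsort(d2[np.arange(len(pts)), assign])[::-1]
            for slot, pi in zip(np.flatnonzero(empty), far):
                centers[slot] = pts[pi]
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        if prev_obj - obj <= tol * max(abs(prev_obj), 1.0) and not empty.any():
            break
        prev_assign = assign
        prev_obj = obj
    if return_history:
        return centers, history
    return centers


def zero_pad(points: np.ndarray, n: int = N_CANONICAL) -> np.ndarray:
    """Back-pad an ordered point list with (0, 0, 0) rows to exactly
    ``n`` rows; the real points are untouched and keep their order."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) > n:
        raise ValueError(f"cannot pad {len(pts)} points down to {n}")
    out = np.zeros((n, 3), dtype=float)
    out[: len(pts)] = pts
    return out


def standardize_frame(
    frame: Frame | np.ndarray, n: int = N_CANONICAL, seed: int = 0
) -> NormalizedFrame:
    """Full canonicalization: xyz selection, k-means reduction when the
    frame holds more than ``n`` points, lexicographic ordering, zero
    back-padding to exactly ``n`` rows."""
    source_index = frame.index if isinstance(frame, Frame) else 0
    pts = select_xyz(frame)
    if len(pts) > n:
        pts = kmeans_reduce(pts, k=n, seed=seed)
    pts = lex_sort(pts)
    n_real = len(pts)
    return NormalizedFrame(points=zero_pad(pts, n), n_real=n_real,
                           source_index=source_index)


def standardize_sequence(frames, n: int = N_CANONICAL, seed: int = 0) -> list[NormalizedFrame]:
    """Canonicalize every frame of a sequence (or iterable of frames)."""
    return [standardize_frame(f, n=n, seed=seed) for f in frames]
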