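"""Unsupervised pixel-colour clustering and the centroid-replacement transform.

Every pixel of a tile is treated as an independent point in normalized RGB
space ([0, 1]^3; no spatial coordinates).  A clustering fit — Lloyd's
K-Means or flat-kernel Mean-Shift — partitions the colours, and the
transform replaces each pixel by its cluster centre, producing a quantized
tile whose palette exposes the image's colour structure to the downstream
networks.  Fitting is per-image: each tile's hidden structure is found
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ClusterParams",
    "QuantizedImage",
    "KMeansResult",
    "MeanShiftResult",
    "kmeans_fit",
    "meanshift_fit",
    "quantize_image",
    "quantize_dataset",
]


@dataclass(frozen=True)
class ClusterParams:
    """Configuration for the colour-clustering transform.

    ``method`` is ``"km"`` (K-Means; uses ``k``) or ``"ms"`` (Mean-Shift;
    uses ``bandwidth``, the flat-kernel radius in normalized colour units).
    """

    method: str = "km"
    k: int = 8
    bandwidth: float = 0.2
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.method not in ("km", "ms"):
            raise ValueError(f"method must be 'km' or 'ms', got {self.method!r}")
        if self.method == "km" and self.k < 1:
            raise ValueError("K must be >= 1")
        if self.method == "ms" and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


class KMeansResult(NamedTuple):
    centroids: np.ndarray  # (k, d)
    assignment: np.ndarray  # (n,) int
    inertia: float
    inertia_history: np.ndarray  # inertia after each Lloyd iteration
    n_iter: int


class MeanShiftResult(NamedTuple):
    modes: np.ndarray  # (m, d)
    assignment: np.ndarray  # (n,) int


@dataclass(frozen=True)
class QuantizedImage:
    """A tile whose pixels were replaced by their cluster-centre colours."""

    pixels: np.ndarray  # (H, W, 3)
    palette: np.ndarray  # (m, 3)
    assignment: np.ndarray  # (H, W) int


def _sq_dists(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances (n, m)."""
    return ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def _kpp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    closest = ((points - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = closest.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            centroids[i:] = centroids[0]
            break
        probs = closest / total
        centroids[i] = points[rng.choice(n, p=probs)]
        closest = np.minimum(closest, ((points - centroids[i]) ** 2).sum(axis=1))
    return centroids


def kmeans_fit(
    points, k: int, seed: int = 0, max_iter: int = 300, tol: float = 1e-4
) -> KMeansResult:
    """Lloyd's K-Means on points in colour space, k-means++ initialized.

    Iterates assign-to-nearest / recompute-means until the largest centroid
    movement drops below ``tol`` or ``max_iter`` is reached.  An empty
    cluster is re-seeded at the point farthest from its assigned centroid.
    Inertia (sum of squared distances to the assigned centroid) is recorded
    after every iteration and is non-increasing.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (n, d)")
    n = len(points)
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError(f"K={k} exceeds the number of points ({n})")

    rng = np.random.default_rng(seed)
    centroids = _kpp_init(points, k, rng)
    history: list[float] = []
    assignment = np.zeros(n, dtype=np.int64)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(points, centroids)
        assignment = d2.argmin(axis=1)
        new_centroids = centroids.copy()
        for j in range(k):
            mask = assignment == j
            if mask.any():
                new_centroids[j] = points[mask].mean(axis=0)
            else:
                # re-seed a dead centroid at the worst-fit point
                farthest = d2[np.arange(n), assignment].argmax()
                new_centroids[j] = points[farthest]
                assignment[farthest] = j
        inertia = float(
            ((points - new_centroids[assignment]) ** 2).sum()
        )
        history.append(inertia)
        move = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if move < tol:
            break
    # final tight assignment against the converged centroids
    assignment = _sq_dists(points, centroids).argmin(axis=1)
    inertia = float(((points - centroids[assignment]) ** 2).sum())
    return KMeansResult(centroids, assignment, inertia, np.array(history), it)


def _bin_seeds(points: np.ndarray, bin_size: float) -> np.ndarray:
    """One seed per occupied bin of a grid with pitch ``bin_size``."""
    binned = np.round(points / bin_size)
    uniq = np.unique(binned, axis=0)
    return uniq * bin_size


def meanshift_fit(
    points, bandwidth: float, tol: float = 1e-4, max_iter: int = 300
) -> MeanShiftResult:
    """Flat-kernel mean shift: hill-climb seeds to density modes.

    Each seed is repeatedly replaced by the mean of all points within
    ``bandwidth`` (Euclidean) until it moves less than ``tol``.  Converged
    modes closer than ``bandwidth / 2`` are merged (the mode supported by
    more points wins); every point is then assigned to its nearest
    surviving mode.  Deterministic given the input order.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (n, d)")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    seeds = _bin_seeds(points, bandwidth)
    bw2 = bandwidth**2
    modes = []
    support = []
    for seed in seeds:
        center = seed.copy()
        for _ in range(max_iter):
            within = ((points - center) ** 2).sum(axis=1) <= bw2
            if not within.any():
                break
            new_center = points[within].mean(axis=0)
            shift = np.sqrt(((new_center - center) ** 2).sum())
            center = new_center
            if shift < tol:
                break
        else:
            within = ((points - center) ** 2).sum(axis=1) <= bw2
        if within.any():
            modes.append(center)
            support.append(int(within.sum()))

    if not modes:  # cannot happen for non-empty input, defensive
        raise ValueError("mean shift produced no modes")
    modes_arr = np.array(modes)
    order = np.argsort(-np.array(support), kind="stable")
    kept: list[np.ndarray] = []
    merge_r2 = (bandwidth / 2.0) ** 2
    for i in order:
        cand = modes_arr[i]
        if all(((cand - m) ** 2).sum() > merge_r2 for m in kept):
            kept.append(cand)
    final = np.array(kept)
    assignment = _sq_dists(points, final).argmin(axis=1)
    return MeanShiftResult(final, assignment)


def quantize_image(img, params: ClusterParams) -> QuantizedImage:
    """Replace every pixel of one tile by its fitted cluster-centre colour."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"image must be (H, W, 3), got {img.shape}")
    h, w, _ = img.shape
    pts = img.reshape(-1, 3)
    if params.method == "km":
        res = kmeans_fit(pts, params.k, seed=params.seed, max_iter=params.max_iter, tol=params.tol)
        palette, assignment = res.centroids, res.assignment
    else:
        res = meanshift_fit(pts, params.bandwidth, tol=params.tol, max_iter=params.max_iter)
        palette, assignment = res.modes, res.assignment
    palette = np.clip(palette, 0.0, 1.0)
    pixels = palette[assignment].reshape(h, w, 3)
    return QuantizedImage(pixels=pixels, palette=palette, assignment=assignment.reshape(h, w))


def quantize_dataset(images: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Quantize a stack of tiles (n, H, W, 3) image by image."""
    return np.stack([quantize_image(img, params).pixels for img in images])
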