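"""K-means voxel classification of the reconstructed "true" volume.

The segmentation's final stage partitions the voxels of the dilated
region-of-interest into K = 3 intensity classes — background, vessel
boundary, vessel lumen — by minimizing the within-cluster sum of squares
(WCSS).  Lloyd iterations are started from k-means++ seeds; multiple
restarts with distinct sub-seeds keep the best WCSS, and the whole procedure
is deterministic given one integer seed.  Empty clusters are repaired by
reseeding to the point farthest from its assigned center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BinaryMask, CTAVolume

__all__ = ["ClusterResult", "kmeans", "classify_roi"]


@dataclass
class ClusterResult:
    labels: np.ndarray          # (n,) ints in {0..k-1}
    centers: np.ndarray         # (k, d)
    wcss: float                 # sum of squared distances to assigned centers
    n_iter: int
    degenerate: bool = False    # fewer distinct values than clusters


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    return pts


def _sq_dists(pts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances
    return ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def _kmeanspp(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = pts.shape[0]
    centers = np.empty((k, pts.shape[1]))
    centers[0] = pts[rng.integers(n)]
    closest = ((pts - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = closest.sum()
        if total <= 0:
            centers[i] = pts[rng.integers(n)]
        else:
            centers[i] = pts[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, ((pts - centers[i]) ** 2).sum(axis=1))
    return centers


def _lloyd(pts: np.ndarray, centers: np.ndarray, max_iter: int):
    labels = np.full(pts.shape[0], -1)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(pts, centers)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: reseed to the farthest point
        for c in range(centers.shape[0]):
            if not np.any(new_labels == c):
                far = d2[np.arange(len(pts)), new_labels].argmax()
                centers[c] = pts[far]
                d2 = _sq_dists(pts, centers)
                new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            return labels, centers, it
        labels = new_labels
        for c in range(centers.shape[0]):
            sel = labels == c
            if sel.any():  # duplicates can leave a repaired cluster empty
                centers[c] = pts[sel].mean(axis=0)
    return labels, centers, max_iter


def kmeans(
    points,
    k: int,
    rng_seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 10,
) -> ClusterResult:
    """Lloyd's K-means with k-means++ seeding and deterministic restarts.

    Raises
    ------
    ValueError
        If n < k or k < 1.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} points, got n={n}")
    degenerate = np.unique(pts, axis=0).shape[0] < k
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), r]))
        centers = _kmeanspp(pts, k, rng)
        labels, centers, n_iter = _lloyd(pts, centers.copy(), max_iter)
        wcss = float(((pts - centers[labels]) ** 2).sum())
        if best is None or wcss < best.wcss - 1e-12:
            best = ClusterResult(labels, centers, wcss, n_iter, degenerate)
    return best


def classify_roi(
    true_vol: CTAVolume,
    roi: BinaryMask,
    k: int = 3,
    rng_seed: int = 0,
    with_result: bool = False,
):
    """Classify ROI voxels of the reconstructed volume into K intensity classes.

    Clusters are ordered by center intensity: lowest -> background, middle ->
    vessel boundary, highest -> vessel lumen.  The three masks partition the
    ROI and ``vessel = lumen ∪ boundary``.

    Returns
    -------
    (lumen, boundary, background, vessel) : BinaryMask
        With ``with_result=True`` the :class:`ClusterResult` (cluster order
        remapped to background=0 < boundary ... < lumen=k-1) is appended.

    Raises
    ------
    ValueError
        If the ROI is empty or smaller than k voxels.
    """
    if true_vol.shape != roi.shape:
        raise ValueError("volume and ROI shapes differ")
    coords = np.nonzero(roi.values)
    n = coords[0].size
    if n == 0:
        raise ValueError("ROI is empty")
    if n < k:
        raise ValueError(f"ROI has {n} voxels, fewer than k={k}")
    intensities = true_vol.values[coords]
    res = kmeans(intensities, k, rng_seed=rng_seed)
    order = np.argsort(res.centers[:, 0], kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    ranked_labels = rank[res.labels]
    res = ClusterResult(ranked_labels, res.centers[order], res.wcss,
                        res.n_iter, res.degenerate)

    def mask_of(cond: np.ndarray) -> BinaryMask:
        grid = np.zeros(roi.shape, dtype=bool)
        grid[coords] = cond
        return BinaryMask(grid, roi.spacing)

    background = mask_of(ranked_labels == 0)
    lumen = mask_of(ranked_labels == k - 1)
    boundary = mask_of((ranked_labels > 0) & (ranked_labels < k - 1))
    vessel = BinaryMask(lumen.values | boundary.values, roi.spacing)
    out = (lumen, boundary, background, vessel)
    return out + (res,) if with_result else out
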