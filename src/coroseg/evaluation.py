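"""Segmentation evaluation: overlap metric, Hausdorff distance, centerline
extraction and cross-sectional diameter measurement.

The overlap metric OM = 2|A ∩ B| / (|A| + |B|) (the Dice coefficient) is
reported volumetrically ("3D OM") and as the mean of per-slice values over
slices where the reference is non-empty ("2D OM").  The Hausdorff distance
is computed between the boundary-voxel centers of the two masks, in mm.
Centerlines come from topology-preserving 3D medial-axis thinning; the
skeleton is traced into polylines split at junction voxels.  Vessel calibre
at a centerline point is estimated from the cross-section area A of the mask
on the plane orthogonal to the local tangent: the equivalent-circle radius
is sqrt(A/π) and the diameter twice that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .volume import BinaryMask

__all__ = ["Centerline", "EvalReport", "overlap_metric", "overlap_metric_2d",
           "hausdorff", "boundary_voxels", "extract_centerline",
           "measure_diameters", "evaluate"]

_SIX = ndimage.generate_binary_structure(3, 1)   # 6-connectivity cross
_TWENTYSIX = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Centerline:
    """Ordered 3D polylines (voxel coordinates) with branch points."""

    polylines: list[np.ndarray]
    branch_points: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return sum(len(p) for p in self.polylines)

    def all_points(self) -> np.ndarray:
        return np.concatenate([np.asarray(p) for p in self.polylines], axis=0)


@dataclass
class EvalReport:
    om: float
    hausdorff_mm: float
    diameters_mm: list[tuple[float, float]]


def overlap_metric(a: BinaryMask, b: BinaryMask) -> float:
    """OM = 2|a ∩ b| / (|a| + |b|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def overlap_metric_2d(pred: BinaryMask, truth: BinaryMask) -> float:
    """Mean per-slice OM over slices where the reference is non-empty."""
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    oms = []
    for k in range(truth.shape[2]):
        t = truth.values[:, :, k]
        if not t.any():
            continue
        p = pred.values[:, :, k]
        oms.append(2.0 * int((p & t).sum()) / (int(p.sum()) + int(t.sum())))
    if not oms:
        raise ValueError("reference mask is empty on every slice")
    return float(np.mean(oms))


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Voxels of the mask with at least one background 6-neighbor (indices)."""
    eroded = ndimage.binary_erosion(mask.values, structure=_SIX, border_value=0)
    return np.argwhere(mask.values & ~eroded)


def hausdorff(a: BinaryMask, b: BinaryMask, spacing=None) -> float:
    """Bidirectional Hausdorff distance between mask boundaries, in mm.

    Raises
    ------
    ValueError
        If either mask is empty or shapes differ.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.count() == 0 or b.count() == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    spacing = np.asarray(spacing if spacing is not None else a.spacing, dtype=float)
    x = boundary_voxels(a) * spacing
    y = boundary_voxels(b) * spacing
    return float(max(directed_hausdorff(x, y)[0], directed_hausdorff(y, x)[0]))


def _trace_polylines(skel: np.ndarray) -> Centerline:
    coords = [tuple(c) for c in np.argwhere(skel)]
    coord_set = set(coords)

    def neighbors(p):
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if q in coord_set:
                        out.append(q)
        return out

    degree = {p: len(neighbors(p)) for p in coords}
    junctions = sorted(p for p, d in degree.items() if d >= 3)
    endpoints = sorted(p for p, d in degree.items() if d <= 1)
    nodes = set(junctions) | set(endpoints)

    polylines: list[np.ndarray] = []
    used_edges: set[frozenset] = set()

    def walk(start, first):
        """Follow the chain from start through first until the next node."""
        path = [start, first]
        used_edges.add(frozenset((start, first)))
        prev, curr = start, first
        while curr not in nodes:
            nxt = [q for q in neighbors(curr)
                   if frozenset((curr, q)) not in used_edges]
            if not nxt:
                break
            nxt = sorted(nxt)[0]
            used_edges.add(frozenset((curr, nxt)))
            path.append(nxt)
            prev, curr = curr, nxt
        return path

    for start in sorted(nodes):
        for first in sorted(neighbors(start)):
            if frozenset((start, first)) in used_edges:
                continue
            polylines.append(np.asarray(walk(start, first)))
    # isolated voxels
    for p in coords:
        if degree[p] == 0:
            polylines.append(np.asarray([p]))
    # pure cycles (no endpoints/junctions on them)
    visited = {tuple(q) for line in polylines for q in map(tuple, line)}
    for p in coords:
        if p in visited or degree[p] != 2:
            continue
        first = sorted(neighbors(p))[0]
        path = walk(p, first)
        polylines.append(np.asarray(path))
        visited.update(map(tuple, path))
    return Centerline(polylines, junctions)


def extract_centerline(mask: BinaryMask) -> Centerline:
    """Medial-axis centerline by topology-preserving 3D thinning.

    The skeleton is traced into 26-connected polylines; voxels with three or
    more skeleton neighbours are junctions and reported as branch points.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    from skimage.morphology import skeletonize

    if mask.count() == 0:
        raise ValueError("cannot extract a centerline from an empty mask")
    skel = skeletonize(mask.values)
    if not skel.any():  # tiny masks can thin away entirely; keep one voxel
        skel = np.zeros_like(mask.values)
        skel[tuple(np.argwhere(mask.values)[0])] = True
    return _trace_polylines(skel)


def _orthonormal_plane(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def measure_diameters(
    mask: BinaryMask,
    centerline: Centerline,
    spacing=None,
    step: int = 1,
    sample_mm: float = 0.2,
    max_radius_mm: float = 6.0,
    circle_equivalent_diameter: bool = False,
) -> list[tuple[float, float]]:
    """Estimate vessel calibre along the centerline from cross-section areas.

    At every ``step``-th centerline point the local tangent is the central
    difference of the neighbouring points (one-sided at the ends).  The mask
    is resampled (nearest neighbour) on a square grid of pitch ``sample_mm``
    on the plane orthogonal to the tangent; the cross-section area A is the
    hit count of the in-plane connected component containing the centerline
    point times the sample area.  The reported value is sqrt(A/π) — the
    equivalent-circle radius — or 2*sqrt(A/π) when
    ``circle_equivalent_diameter`` is set.

    Returns a list of (arc-length position in mm, value in mm) pairs.

    Raises
    ------
    ValueError
        If a centerline point lies outside the mask.
    """
    spacing = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    grid = mask.values
    half = int(np.ceil(max_radius_mm / sample_mm))
    offsets = np.arange(-half, half + 1) * sample_mm
    ou, ov = np.meshgrid(offsets, offsets, indexing="ij")
    out: list[tuple[float, float]] = []
    for line in centerline.polylines:
        pts = np.asarray(line, dtype=float)
        if len(pts) == 0:
            continue
        mm = pts * spacing
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(mm, axis=0), axis=1))])
        for i in range(0, len(pts), step):
            p = pts[i]
            pi = tuple(int(round(c)) for c in p)
            if not all(0 <= c < s for c, s in zip(pi, grid.shape)):
                raise ValueError(f"centerline point {pi} outside the grid")
            if not grid[pi]:
                raise ValueError(f"centerline point {pi} outside the mask")
            if len(pts) == 1:
                tangent = np.array([0.0, 0.0, 1.0])
            elif i == 0:
                tangent = mm[1] - mm[0]
            elif i == len(pts) - 1:
                tangent = mm[-1] - mm[-2]
            else:
                tangent = mm[i + 1] - mm[i - 1]
            u, v = _orthonormal_plane(tangent)
            plane_mm = (mm[i][:, None, None]
                        + u[:, None, None] * ou[None]
                        + v[:, None, None] * ov[None])
            plane_vox = plane_mm / spacing[:, None, None]
            hits = ndimage.map_coordinates(grid.astype(np.uint8), plane_vox,
                                           order=0, mode="constant", cval=0)
            lab, _ = ndimage.label(hits, structure=np.ones((3, 3), dtype=bool))
            center_lab = lab[half, half]
            if center_lab == 0:
                area = 0.0
            else:
                area = float((lab == center_lab).sum()) * sample_mm**2
            value = np.sqrt(area / np.pi)
            if circle_equivalent_diameter:
                value *= 2.0
            out.append((float(arc[i]), float(value)))
    return out


def evaluate(
    pred: BinaryMask,
    truth: BinaryMask,
    spacing=None,
    with_diameters: bool = False,
) -> EvalReport:
    """Bundle OM, Hausdorff distance and (optionally) diameters of ``pred``."""
    diam: list[tuple[float, float]] = []
    if with_diameters:
        diam = measure_diameters(pred, extract_centerline(pred), spacing)
    return EvalReport(
        om=overlap_metric(pred, truth),
        hausdorff_mm=hausdorff(pred, truth, spacing),
        diameters_mm=diam,
    )
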