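"""Initial coronary segmentation: seed detection and capped 3D region growing.

Seeds are found automatically from the per-slice bright-structure masks: the
aorta changes little between adjacent axial slices, so the first connected
component that appears in a slice (the set difference against the previous
slice) adjacent to the persisting aorta marks a coronary ostium.

Growing uses the 26-connected neighbourhood with a running-mean homogeneity
criterion: a candidate voxel is merged when its intensity differs from the
mean of the already-merged region by at most tau.  To control leakage, a
single pass is capped at 12000 voxels; when the cap is hit the criterion is
tightened (tau scaled by ``tighten_factor``) and growing restarts from the
seeds, up to ``max_restarts`` times, after which the capped result of the
last pass is returned with a warning.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CTAVolume

__all__ = ["SeedSet", "GrowParams", "GrowInfo", "NoSeedError", "detect_seeds",
           "detect_seeds_all", "grow", "dilate", "auto_tau",
           "bright_structure_mask"]

# fixed lexicographic enumeration of the 26-neighbourhood
_NEIGHBORS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_EIGHT = np.ones((3, 3), dtype=bool)


class NoSeedError(RuntimeError):
    """No slice pair yields a qualifying new component (manual seed needed)."""


@dataclass
class SeedSet:
    """Seed voxels for region growing plus the slice where they were found."""

    voxels: list[tuple[int, int, int]]
    slice_index: int

    def __post_init__(self) -> None:
        self.voxels = [tuple(int(c) for c in v) for v in self.voxels]


@dataclass
class GrowParams:
    """Homogeneity threshold and leakage-control parameters."""

    tau: float
    cap: int = 12000
    max_restarts: int = 5
    tighten_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if not 0 < self.tighten_factor < 1:
            raise ValueError("tighten_factor must lie in (0, 1)")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be non-negative")


@dataclass
class GrowInfo:
    """Diagnostics of a grow() call."""

    tau_used: float
    n_restarts: int
    capped: bool
    n_voxels: int


def _new_components(prev: np.ndarray, curr: np.ndarray, min_new_area: int):
    """Connected components of curr \\ prev (8-connected, in-plane) that are
    large enough and adjacent to the persisting structure."""
    diff = curr & ~prev
    if not diff.any():
        return []
    persisting = curr & prev
    lab, n = ndimage.label(diff, structure=_EIGHT)
    out = []
    for c in range(1, n + 1):
        comp = lab == c
        if comp.sum() < min_new_area:
            continue
        touch = ndimage.binary_dilation(comp, structure=_EIGHT) & persisting
        if touch.any():
            out.append(comp)
    return out


def detect_seeds(aorta_masks: BinaryMask, min_new_area: int = 5) -> SeedSet:
    """Detect ostium seeds from the first qualifying adjacent-slice pair.

    Scans slice pairs (k, k+1) in ascending k and returns the voxels of every
    connected component of ``mask[k+1] \\ mask[k]`` with area >=
    ``min_new_area`` that touches the persisting aorta, with
    ``slice_index = k + 1``.

    Raises
    ------
    NoSeedError
        If no slice pair qualifies.
    """
    for seeds in _iter_seed_sets(aorta_masks, min_new_area):
        return seeds
    raise NoSeedError("no adjacent-slice difference component qualifies as a seed")


def detect_seeds_all(aorta_masks: BinaryMask, min_new_area: int = 5) -> SeedSet:
    """Union of qualifying new components over *all* adjacent-slice pairs.

    Coronary branches arise at different z positions; scanning every pair
    collects one seed group per ostium.  ``slice_index`` is the first
    qualifying slice.

    Raises
    ------
    NoSeedError
        If no slice pair qualifies.
    """
    voxels: list[tuple[int, int, int]] = []
    first = None
    for seeds in _iter_seed_sets(aorta_masks, min_new_area):
        if first is None:
            first = seeds.slice_index
        voxels.extend(seeds.voxels)
    if first is None:
        raise NoSeedError("no adjacent-slice difference component qualifies as a seed")
    return SeedSet(sorted(set(voxels)), first)


def _iter_seed_sets(aorta_masks: BinaryMask, min_new_area: int):
    if min_new_area < 1:
        raise ValueError("min_new_area must be positive")
    m = aorta_masks.values
    for k in range(m.shape[2] - 1):
        comps = _new_components(m[:, :, k], m[:, :, k + 1], min_new_area)
        if not comps:
            continue
        voxels = []
        for comp in comps:
            ii, jj = np.nonzero(comp)
            voxels.extend((int(i), int(j), k + 1) for i, j in zip(ii, jj))
        yield SeedSet(sorted(voxels), k + 1)


def _grow_once(vals, seeds, tau, cap, forbidden):
    shape = vals.shape
    region = np.zeros(shape, dtype=bool)
    enqueued = np.zeros(shape, dtype=bool)
    total = 0.0
    count = 0
    queue = deque()
    for v in seeds:
        if region[v]:
            continue
        region[v] = True
        enqueued[v] = True
        total += vals[v]
        count += 1
        if count >= cap:
            return region, count, True
    for v in sorted(seeds):
        queue.append(v)
    capped = False
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in _NEIGHBORS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                continue
            if enqueued[nx, ny, nz]:
                continue
            enqueued[nx, ny, nz] = True
            if forbidden is not None and forbidden[nx, ny, nz]:
                continue
            if abs(vals[nx, ny, nz] - total / count) <= tau:
                region[nx, ny, nz] = True
                total += vals[nx, ny, nz]
                count += 1
                queue.append((nx, ny, nz))
                if count >= cap:
                    return region, count, True
    return region, count, capped


def grow(
    volume: CTAVolume,
    seeds: SeedSet,
    params: GrowParams,
    forbidden: BinaryMask | None = None,
    full_output: bool = False,
):
    """Capped 26-connected region growing from seed voxels.

    A FIFO queue with fixed lexicographic neighbour enumeration makes the
    result bit-for-bit reproducible.  The region mean is updated after every
    accepted voxel; a voxel rejected once is not reconsidered.  ``forbidden``
    marks voxels growing may never enter (e.g. a known aorta mask).

    Returns the grown :class:`BinaryMask`, plus a :class:`GrowInfo` when
    ``full_output`` is set.

    Raises
    ------
    ValueError
        If the seed set is empty.
    IndexError
        If a seed lies outside the grid.
    """
    if not seeds.voxels:
        raise ValueError("empty seed set")
    vals = volume.values
    for v in seeds.voxels:
        if not all(0 <= c < s for c, s in zip(v, vals.shape)):
            raise IndexError(f"seed {v} outside volume of shape {vals.shape}")
    forb = forbidden.values if forbidden is not None else None
    seed_list = [v for v in seeds.voxels if forb is None or not forb[v]]
    if not seed_list:
        raise ValueError("all seeds lie inside the forbidden mask")
    tau = params.tau
    restarts = 0
    while True:
        region, count, capped = _grow_once(vals, seed_list, tau, params.cap, forb)
        if not capped or restarts >= params.max_restarts:
            break
        restarts += 1
        tau *= params.tighten_factor
    if capped:
        warnings.warn(
            f"region growing still capped at {params.cap} voxels after "
            f"{restarts} restart(s); returning the capped result",
            RuntimeWarning,
            stacklevel=2,
        )
    mask = BinaryMask(region, volume.spacing)
    if full_output:
        return mask, GrowInfo(tau, restarts, capped, count)
    return mask


def dilate(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological dilation by ``radius`` steps of the 26-neighbourhood
    (a Chebyshev ball of the given radius).

    Raises
    ------
    ValueError
        If radius < 1.
    """
    if radius < 1:
        raise ValueError("dilation radius must be >= 1")
    out = ndimage.binary_dilation(
        mask.values, structure=np.ones((3, 3, 3), dtype=bool), iterations=radius
    )
    return BinaryMask(out, mask.spacing)


def auto_tau(volume: CTAVolume, slice_index: int, fraction: float = 0.25) -> float:
    """Default homogeneity threshold: a fraction of the robust intensity
    range (1st..99th percentile) of the seed slice."""
    sl = volume.values[:, :, slice_index]
    lo, hi = np.percentile(sl, [1, 99])
    rng = float(hi - lo)
    if rng <= 0:
        raise ValueError("seed slice has no intensity range")
    return fraction * rng


def bright_structure_mask(volume: CTAVolume, threshold: float | None = None) -> BinaryMask:
    """Threshold the volume into bright structures (aorta + vessels).

    This is a pragmatic stand-in for a dedicated aorta detector: with a
    contrast-enhanced acquisition, Otsu's threshold separates the enhanced
    blood pool from myocardium/background.  Used to build the per-slice
    masks that seed detection differences.
    """
    from skimage.filters import threshold_otsu

    t = float(threshold) if threshold is not None else float(
        threshold_otsu(volume.values)
    )
    return BinaryMask(volume.values > t, volume.spacing)
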