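"""Core in-memory containers: scalar CTA volumes and aligned binary masks.

Index convention used throughout the package: a volume is a 3D array whose
axes ``(i, j, k)`` correspond to the spatial axes ``(x, y, z)``; a "slice" is
a fixed-``k`` plane (the axial plane of a CT acquisition).  Voxel centers sit
at ``index * spacing + origin`` in millimetres.  Values are kept as floating
point internally regardless of any on-disk integer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTAVolume", "BinaryMask"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return spacing


@dataclass
class CTAVolume:
    """A 3D scalar grid (Hounsfield-unit-like intensities) with voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Intensities; stored as float64.
    spacing : (dx, dy, dz)
        Voxel spacing in mm, all positive.
    origin : (x0, y0, z0), optional
        Physical position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"a CTA volume must be 3-dimensional, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "CTAVolume":
        return CTAVolume(self.values.copy(), self.spacing, self.origin)


@dataclass
class BinaryMask:
    """A 3D {0, 1} grid aligned to a :class:`CTAVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"a mask must be 3-dimensional, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0 or 1")
            arr = arr.astype(bool)
        self.values = arr
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.spacing)
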