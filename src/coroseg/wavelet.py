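"""One-level (and multi-level) 3D discrete wavelet transform and the
vessel-texture discrimination search.

The decomposition is the separable filter-bank DWT: low- and high-pass
filtering with downsampling by two along x, then y, then z, producing eight
subbands labelled ``LLL`` ... ``HHH``.  The letter at position 1 is the
filter applied along the x axis (array axis 0), position 3 along z (axis 2).
For the orthonormal Haar filters the transform is an isometry, so the total
subband energy equals the input energy (Parseval) and the inverse transform
reconstructs the input exactly.  Axes of odd length are zero-padded by one
sample before filtering; the original shape is recorded so the inverse crops
back exactly, and zero padding keeps Parseval exact for odd shapes as well.

Vessels are line-like 3D patterns, so the texture content of a vessel volume
is probed by comparing the per-channel coefficient energy (l2-norm) across
the seven detail channels, increasing the decomposition level until one
channel dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pywt

from .volume import CTAVolume

__all__ = [
    "WaveletSpec",
    "SubbandSet",
    "TextureResult",
    "NoTextureError",
    "BAND_LABELS",
    "DETAIL_LABELS",
    "dwt3",
    "idwt3",
    "channel_energy",
    "texture_search",
]

BAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
DETAIL_LABELS = tuple(b for b in BAND_LABELS if b != "LLL")

_SQRT2 = math.sqrt(2.0)


class NoTextureError(ValueError):
    """Raised when a volume has no detail energy at all (constant input)."""


def _quadrature_mirror(h: tuple[float, ...]) -> tuple[float, ...]:
    # g_m = (-1)^m h_{1-m}
    idx = range(1 - (len(h) - 1), 2)
    return tuple((-1.0) ** m * h[1 - m] for m in idx)


@dataclass(frozen=True)
class WaveletSpec:
    """An orthonormal two-channel filter pair (h_m, g_m).

    The high-pass filter is derived from the low-pass one by the quadrature
    mirror relation g_m = (-1)^m h_{1-m}.  Orthonormality requires
    sum(h**2) == 1 and sum(h) == sqrt(2); the Haar pair is
    h = (1/sqrt(2), 1/sqrt(2)).
    """

    low_pass: tuple[float, ...]
    high_pass: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        h = tuple(float(c) for c in self.low_pass)
        object.__setattr__(self, "low_pass", h)
        if abs(sum(c * c for c in h) - 1.0) > 1e-9 or abs(sum(h) - _SQRT2) > 1e-9:
            raise ValueError(
                "low-pass filter must satisfy sum(h^2)=1 and sum(h)=sqrt(2)"
            )
        if self.high_pass is None:
            object.__setattr__(self, "high_pass", _quadrature_mirror(h))
        else:
            object.__setattr__(
                self, "high_pass", tuple(float(c) for c in self.high_pass)
            )

    @classmethod
    def haar(cls) -> "WaveletSpec":
        return cls(low_pass=(1.0 / _SQRT2, 1.0 / _SQRT2))

    def to_pywt(self) -> pywt.Wavelet:
        rec_lo = list(self.low_pass)
        rec_hi = list(self.high_pass)
        return pywt.Wavelet(
            "coroseg-custom",
            filter_bank=[rec_lo[::-1], rec_hi[::-1], rec_lo, rec_hi],
        )


@dataclass
class SubbandSet:
    """The eight one-level 3D DWT subbands plus bookkeeping metadata."""

    bands: dict[str, np.ndarray]
    level: int
    original_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_LABELS):
            raise ValueError(f"expected bands {BAND_LABELS}, got {sorted(self.bands)}")
        expected = tuple(-(-s // 2) for s in self.original_shape)
        for label, band in self.bands.items():
            if band.shape != expected:
                raise ValueError(
                    f"band {label} has shape {band.shape}, expected {expected}"
                )

    def copy(self) -> "SubbandSet":
        return SubbandSet(
            {k: v.copy() for k, v in self.bands.items()},
            self.level,
            self.original_shape,
            self.spacing,
        )


def _pywt_key(label: str) -> str:
    return "".join("a" if c == "L" else "d" for c in label)


def _as_array(volume) -> tuple[np.ndarray, tuple]:
    if isinstance(volume, CTAVolume):
        return volume.values, volume.spacing
    arr = np.asarray(volume, dtype=np.float64)
    return arr, (1.0, 1.0, 1.0)


def dwt3(volume, spec: WaveletSpec | None = None) -> SubbandSet:
    """One-level separable 3D DWT with downsampling by 2 along each axis.

    Parameters
    ----------
    volume : CTAVolume or ndarray
    spec : WaveletSpec, optional
        Defaults to Haar.

    Raises
    ------
    ValueError
        If any axis has fewer than 2 samples.
    """
    arr, spacing = _as_array(volume)
    if arr.ndim != 3:
        raise ValueError("dwt3 expects a 3D input")
    if any(s < 2 for s in arr.shape):
        raise ValueError(f"every axis must have >= 2 samples, got shape {arr.shape}")
    spec = spec or WaveletSpec.haar()
    coeffs = pywt.dwtn(arr, spec.to_pywt(), mode="zero")
    bands = {label: coeffs[_pywt_key(label)] for label in BAND_LABELS}
    return SubbandSet(bands, level=1, original_shape=arr.shape, spacing=spacing)


def idwt3(subbands: SubbandSet, spec: WaveletSpec | None = None) -> CTAVolume:
    """Inverse 3D DWT; crops zero-padded axes back to the original shape."""
    spec = spec or WaveletSpec.haar()
    coeffs = {_pywt_key(label): band for label, band in subbands.bands.items()}
    rec = pywt.idwtn(coeffs, spec.to_pywt(), mode="zero")
    rec = rec[tuple(slice(0, s) for s in subbands.original_shape)]
    return CTAVolume(rec, subbands.spacing)


def channel_energy(coeffs: np.ndarray) -> float:
    """l2-norm of all coefficients of one frequency channel: E(C) = ||C||_2."""
    return float(np.linalg.norm(np.asarray(coeffs, dtype=np.float64).ravel()))


class TextureResult(NamedTuple):
    """Outcome of the vessel-texture discrimination search."""

    channel: str
    level: int
    dominant: bool
    energies: dict


def texture_search(
    volume,
    max_levels: int = 3,
    dominance_ratio: float = 1.5,
    spec: WaveletSpec | None = None,
) -> TextureResult:
    """Find the detail channel carrying the dominant texture energy.

    At each level (starting from 1), the approximation band of the previous
    level is decomposed and the size-normalized l2-norm ``||C||_2 / |C|`` of
    each of the seven detail channels is compared.  The search stops when the
    maximum exceeds ``dominance_ratio`` times the second largest; otherwise
    one more level is tried.  If no channel ever dominates, the argmax at
    ``max_levels`` is returned with ``dominant=False``.

    Raises
    ------
    NoTextureError
        If the input is constant (all detail energies zero at level 1).
    """
    if dominance_ratio <= 1:
        raise ValueError("dominance_ratio must exceed 1")
    arr, _ = _as_array(volume)
    current = arr
    result = None
    for level in range(1, max_levels + 1):
        if any(s < 2 for s in current.shape):
            break
        sb = dwt3(current, spec)
        energies = {
            label: channel_energy(sb.bands[label]) / sb.bands[label].size
            for label in DETAIL_LABELS
        }
        ranked = sorted(energies.items(), key=lambda kv: (-kv[1], kv[0]))
        (best, e1), (_, e2) = ranked[0], ranked[1]
        if e1 == 0.0:
            if level == 1:
                raise NoTextureError("constant volume: no detail energy in any channel")
            break
        result = TextureResult(best, level, e1 >= dominance_ratio * e2, energies)
        if result.dominant:
            return result
        current = sb.bands["LLL"]
    if result is None:  # pragma: no cover - max_levels >= 1 guards this
        raise NoTextureError("volume too small to decompose")
    return result
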