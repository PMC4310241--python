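"""Neutrosophic characterization of the HHH subband and the α-means operation.

Each HHH coefficient is mapped to a neutrosophic triple (T, F, U): T is the
min-max normalized local mean of the coefficient magnitude (how strongly the
neighbourhood carries boundary texture), F = 1 - T, and U is the min-max
normalized deviation of the coefficient from its local mean (how atypical,
hence uncertain, the coefficient is).  The α-means operation then replaces T
and F by their local window means wherever U >= α, reducing uncertainty, and
a "true" volume is reconstructed by the inverse DWT after re-weighting the
HHH band with the final T.

Two window conventions are provided.  ``centered`` (default) averages over
the w³ neighbourhood centered on the voxel with replicated borders — the
standard local mean.  ``literal`` uses the forward-shifted bounds
l ∈ [i, round(i + w/2)] (and likewise for the other axes), clamped at the
borders; for the default w = 3 this is the window [i, i+2]³ of exactly w³
samples, so the 1/w³ normalization is a proper mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTAVolume
from .wavelet import SubbandSet, WaveletSpec, idwt3

__all__ = ["AlphaParams", "NeutrosophicField", "local_mean", "to_neutrosophic",
           "alpha_means", "true_volume"]


@dataclass(frozen=True)
class AlphaParams:
    """Parameters of the neutrosophic transform.

    alpha : uncertainty threshold of the α-means operation, usually in (0, 1];
        0 smooths everywhere, values > 1 make α-means the identity.
        Default 0.2.
    window : odd window width w (voxels) of all local means.  Default 3.
    window_mode : "centered" or "literal" (forward-shifted bounds).
    magnitude_mode : "abs" averages |HHH| (default; the local mean is then a
        texture-strength measure), "raw" averages signed coefficients.
    """

    alpha: float = 0.2
    window: int = 3
    window_mode: str = "centered"
    magnitude_mode: str = "abs"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.window_mode not in ("centered", "literal"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.magnitude_mode not in ("abs", "raw"):
            raise ValueError(f"unknown magnitude_mode {self.magnitude_mode!r}")


@dataclass
class NeutrosophicField:
    """Per-voxel neutrosophic memberships over the HHH subband domain.

    T, F, U are grids in [0, 1] with T + F = 1 everywhere; ``stats`` records
    the normalization extrema (local-mean min/max, deviation min/max).
    """

    T: np.ndarray
    F: np.ndarray
    U: np.ndarray
    stats: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("T", "F", "U"):
            g = getattr(self, name)
            if g.shape != self.T.shape:
                raise ValueError("T, F, U must share one shape")
            if g.min() < -1e-12 or g.max() > 1 + 1e-12:
                raise ValueError(f"{name} not within [0, 1]")

    def copy(self) -> "NeutrosophicField":
        return NeutrosophicField(self.T.copy(), self.F.copy(), self.U.copy(),
                                 self.stats)


def _raw_local_mean(band: np.ndarray, params: AlphaParams) -> np.ndarray:
    w = params.window
    if params.window_mode == "centered":
        return ndimage.uniform_filter(band, size=w, mode="nearest")
    # literal forward-shifted bounds l in [i, i + round(w/2)], round half up
    upper = (w + 1) // 2
    out = np.zeros_like(band)
    idx = [np.arange(n) for n in band.shape]
    for dx in range(upper + 1):
        ix = np.minimum(idx[0] + dx, band.shape[0] - 1)
        for dy in range(upper + 1):
            iy = np.minimum(idx[1] + dy, band.shape[1] - 1)
            for dz in range(upper + 1):
                iz = np.minimum(idx[2] + dz, band.shape[2] - 1)
                out += band[np.ix_(ix, iy, iz)]
    return out / float(w**3)


def local_mean(band: np.ndarray, params: AlphaParams | None = None) -> np.ndarray:
    """Local window mean of an HHH subband (the HHH̄ field).

    Raises
    ------
    ValueError
        If the band is smaller than the window along any axis.
    """
    params = params or AlphaParams()
    band = np.asarray(band, dtype=np.float64)
    if any(s < params.window for s in band.shape):
        raise ValueError(
            f"band shape {band.shape} smaller than window {params.window}"
        )
    if params.magnitude_mode == "abs":
        band = np.abs(band)
    return _raw_local_mean(band, params)


def _minmax(grid: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:  # degenerate normalization: defined as the zero grid
        return np.zeros_like(grid), lo, hi
    return (grid - lo) / (hi - lo), lo, hi


def to_neutrosophic(band: np.ndarray, params: AlphaParams | None = None) -> NeutrosophicField:
    """Map an HHH subband to memberships T (true), F (false), U (uncertain).

    T is the min-max normalized local mean; F = 1 - T; U is the min-max
    normalized absolute deviation |HHH - HHH̄|.  A degenerate normalization
    (max == min) yields the zero grid for that member.
    """
    params = params or AlphaParams()
    band = np.asarray(band, dtype=np.float64)
    hbar = local_mean(band, params)
    T, h_lo, h_hi = _minmax(hbar)
    F = 1.0 - T
    delta = np.abs(band - hbar)
    U, d_lo, d_hi = _minmax(delta)
    return NeutrosophicField(T, F, U, (h_lo, h_hi, d_lo, d_hi))


def alpha_means(
    field: NeutrosophicField,
    band: np.ndarray,
    params: AlphaParams | None = None,
) -> NeutrosophicField:
    """Apply the α-means operation once.

    Where U >= α, T and F are replaced by their w³ local means; elsewhere
    they are unchanged.  U is then recomputed as the min-max normalization of
    |T̄ - T̄̄| (the deviation of the smoothed T from its own local mean), and
    the invariant T + F = 1 is re-enforced by setting F = 1 - T.  If no voxel
    reaches the threshold the field is returned unchanged.

    Raises
    ------
    ValueError
        If field and band shapes do not match.
    """
    params = params or AlphaParams()
    band = np.asarray(band, dtype=np.float64)
    if field.T.shape != band.shape:
        raise ValueError(
            f"field shape {field.T.shape} does not match band shape {band.shape}"
        )
    replace = field.U >= params.alpha
    if not replace.any():
        return field.copy()
    mean_params = AlphaParams(params.alpha, params.window, params.window_mode, "raw")
    t_bar = _raw_local_mean(field.T, mean_params)
    T = np.where(replace, t_bar, field.T)
    F = 1.0 - T
    t_bar_bar = _raw_local_mean(t_bar, mean_params)
    U, _, _ = _minmax(np.abs(t_bar - t_bar_bar))
    return NeutrosophicField(np.clip(T, 0.0, 1.0), np.clip(F, 0.0, 1.0), U,
                             field.stats)


def true_volume(
    subbands: SubbandSet,
    field: NeutrosophicField,
    mode: str = "weight",
    spec: WaveletSpec | None = None,
) -> CTAVolume:
    """Reconstruct the volume carrying the "true" subset by inverse DWT.

    mode="weight" (default) multiplies each HHH coefficient by its final T
    membership; mode="rescale" replaces the HHH magnitude by T mapped back to
    the local-mean intensity range, keeping the coefficient sign.  All other
    subbands are left untouched.

    Raises
    ------
    ValueError
        If the field shape does not equal the HHH band shape, or mode is
        unknown.
    """
    hhh = subbands.bands["HHH"]
    if field.T.shape != hhh.shape:
        raise ValueError(
            f"field shape {field.T.shape} does not match HHH shape {hhh.shape}"
        )
    if mode == "weight":
        new_hhh = hhh * field.T
    elif mode == "rescale":
        h_lo, h_hi = field.stats[0], field.stats[1]
        new_hhh = np.sign(hhh) * (field.T * (h_hi - h_lo) + h_lo)
    else:
        raise ValueError(f"unknown true_volume mode {mode!r}")
    out = subbands.copy()
    out.bands["HHH"] = new_hhh
    return idwt3(out, spec)
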