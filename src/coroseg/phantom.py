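"""Synthetic CTA-like phantoms with known vessel geometry.

The phantom emulates a contrast-enhanced coronary CTA acquisition: a bright
vertical aorta cylinder, a small tree of tapering bright tubes leaving the
aortic wall at distinct heights (the coronary branches), a darker uniform
background standing in for myocardium, and additive Gaussian noise.  Voxel
spacing defaults to 0.625 mm isotropic — the slice thickness of the clinical
acquisitions the method targets — and branch radii span the 1–3 mm calibre
range of real coronaries.

Voxel membership is decided by whether the voxel *center* lies within the
analytic tube radius of the nearest centerline sample — no anti-aliasing —
so the noise-free phantom is exactly two-valued and the ground truth is
unambiguous for metric tests.  Branch paths are piecewise linear with a
predominant downward (+z) component, as real coronaries descend from their
ostia; each path is stored as the ground-truth centerline together with the
local tube radius.  The ground-truth vessel mask excludes the aorta
interior (a coronary begins at its ostium on the aortic wall), and stored
centerlines are trimmed to clear the aorta by one local radius so mask,
centerline and radii stay mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .evaluation import Centerline
from .volume import BinaryMask, CTAVolume

__all__ = ["PhantomConfig", "PhantomTruth", "make_phantom", "add_noise",
           "write_phantom"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise parameters of a synthetic CTA phantom."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.625, 0.625, 0.625)
    aorta_radius_mm: float = 12.0
    vessel_radii_mm: tuple[float, ...] = (3.0, 2.65, 2.35, 2.0)
    n_branches: int = 4
    branch_length_mm: float = 35.0
    taper_ratio: float = 0.5
    intensity_background: float = 50.0
    intensity_vessel: float = 350.0
    noise_sigma: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise ValueError("shape must be 3 integers, each >= 16")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.aorta_radius_mm <= 0 or any(r <= 0 for r in self.vessel_radii_mm):
            raise ValueError("all radii must be positive")
        if not 0 < self.taper_ratio <= 1:
            raise ValueError("taper_ratio must lie in (0, 1]")
        if self.intensity_vessel <= self.intensity_background:
            raise ValueError("intensity_vessel must exceed intensity_background")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_branches < 0:
            raise ValueError("n_branches must be non-negative")
        ext_x = (self.shape[0] - 1) * self.spacing[0]
        ext_y = (self.shape[1] - 1) * self.spacing[1]
        if 2 * self.aorta_radius_mm >= min(ext_x, ext_y):
            raise ValueError(
                "invalid geometry: aorta of radius "
                f"{self.aorta_radius_mm} mm does not fit in the volume"
            )


@dataclass
class PhantomTruth:
    """A phantom volume with its complete ground truth.

    ``centerlines``/``radii_mm`` are the in-mask truth (trimmed to clear the
    aorta, voxel coordinates); ``paths_mm``/``path_radii_mm`` are the full
    analytic branch paths in mm, including the portion crossing the aortic
    wall, from which the masks were digitized.
    """

    volume: CTAVolume
    vessel_mask: BinaryMask
    aorta_mask: BinaryMask
    centerlines: Centerline
    radii_mm: list[np.ndarray] = field(default_factory=list)
    paths_mm: list[np.ndarray] = field(default_factory=list)
    path_radii_mm: list[np.ndarray] = field(default_factory=list)
    config: PhantomConfig | None = None


def add_noise(volume: CTAVolume, sigma: float, rng_seed: int = 0) -> CTAVolume:
    """Additive zero-mean Gaussian noise; sigma = 0 returns an identical copy.

    Raises
    ------
    ValueError
        If sigma is negative.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = volume.copy()
    if sigma > 0:
        rng = np.random.default_rng(rng_seed)
        out.values += rng.normal(0.0, sigma, size=out.shape)
    return out


def _branch_path(config: PhantomConfig, b: int, rng: np.random.Generator):
    """Piecewise-linear centerline samples (mm) and radii of one branch."""
    sp = np.asarray(config.spacing)
    ext = (np.asarray(config.shape) - 1) * sp
    cx, cy = ext[0] / 2, ext[1] / 2
    n = config.n_branches
    theta = 2 * np.pi * b / n + rng.normal(0.0, 0.15)
    z0 = (0.15 + 0.45 * (b / max(n - 1, 1))) * ext[2]
    r0 = config.vessel_radii_mm[b % len(config.vessel_radii_mm)]
    start = np.array([cx + config.aorta_radius_mm * np.cos(theta),
                      cy + config.aorta_radius_mm * np.sin(theta), z0])

    n_segments = 3
    seg_len = config.branch_length_mm / n_segments
    ds = 0.25 * float(sp.min())
    pts = [start]
    azim, dz = theta, 0.7
    for _ in range(n_segments):
        azim += rng.normal(0.0, 0.25)
        dz = float(np.clip(dz + rng.normal(0.0, 0.1), 0.5, 0.9))
        lat = np.sqrt(1.0 - dz**2)
        d = np.array([lat * np.cos(azim), lat * np.sin(azim), dz])
        n_steps = max(int(round(seg_len / ds)), 1)
        for _ in range(n_steps):
            pts.append(pts[-1] + d * ds)
    pts = np.asarray(pts)
    margin = r0 + float(sp.max())
    pts = np.clip(pts, margin, ext - margin)
    arc = np.concatenate([[0.0],
                          np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = max(arc[-1], 1e-9)
    radii = r0 * (1.0 - (1.0 - config.taper_ratio) * arc / total)
    return pts, radii


def make_phantom(config: PhantomConfig | None = None) -> PhantomTruth:
    """Generate a phantom volume with ground-truth masks and centerlines.

    Deterministic given ``config.rng_seed``.  The vessel tree is 26-connected
    to the aorta surface; intensities before noise are exactly
    ``background + (vessel - background) * indicator``.
    """
    config = config or PhantomConfig()
    sp = np.asarray(config.spacing)
    shape = tuple(int(s) for s in config.shape)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 1]))

    ext = (np.asarray(shape) - 1) * sp
    cx, cy = ext[0] / 2, ext[1] / 2
    xs = np.arange(shape[0]) * sp[0]
    ys = np.arange(shape[1]) * sp[1]
    aorta2d = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
               <= config.aorta_radius_mm**2)
    aorta = np.broadcast_to(aorta2d[:, :, None], shape).copy()

    tube = np.zeros(shape, dtype=bool)
    polylines: list[np.ndarray] = []
    radii_out: list[np.ndarray] = []
    per_branch: list = []
    if config.n_branches > 0:
        samples, radii = [], []
        for b in range(config.n_branches):
            pts, r = _branch_path(config, b, rng)
            samples.append(pts)
            radii.append(r)
            per_branch.append((pts, r))
        all_pts = np.concatenate(samples)
        all_r = np.concatenate(radii)
        tree = cKDTree(all_pts)
        rmax = float(all_r.max())
        lo = np.maximum(np.floor((all_pts.min(axis=0) - rmax) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((all_pts.max(axis=0) + rmax) / sp).astype(int) + 1,
                        shape)
        gx = np.arange(lo[0], hi[0]) * sp[0]
        gy = np.arange(lo[1], hi[1]) * sp[1]
        gz = np.arange(lo[2], hi[2]) * sp[2]
        centers = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1)
        dist, idx = tree.query(centers.reshape(-1, 3), k=1)
        member = (dist <= all_r[idx]).reshape(centers.shape[:3])
        tube[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = member

        axis_dist = np.linalg.norm(all_pts[:, :2] - np.array([cx, cy]), axis=1)
        offset = 0
        for pts, r in per_branch:
            ad = axis_dist[offset:offset + len(pts)]
            offset += len(pts)
            keep = ad >= config.aorta_radius_mm + r
            if not keep.any():
                continue
            # samples are 1/4 voxel apart; keep roughly one point per voxel
            kept = np.nonzero(keep)[0][::4]
            polylines.append(pts[kept] / sp)      # voxel coordinates
            radii_out.append(r[kept])

    vessel = tube & ~aorta
    indicator = tube | aorta
    values = config.intensity_background + (
        config.intensity_vessel - config.intensity_background
    ) * indicator.astype(np.float64)
    volume = CTAVolume(values, tuple(sp))
    if config.noise_sigma > 0:
        volume = add_noise(volume, config.noise_sigma, rng_seed=config.rng_seed)
    return PhantomTruth(
        volume=volume,
        vessel_mask=BinaryMask(vessel, tuple(sp)),
        aorta_mask=BinaryMask(aorta, tuple(sp)),
        centerlines=Centerline(polylines),
        radii_mm=radii_out,
        paths_mm=[pts for pts, _ in per_branch],
        path_radii_mm=[r for _, r in per_branch],
        config=config,
    )


def write_phantom(truth: PhantomTruth, outdir: str | Path) -> None:
    """Write volume + masks as NIfTI and the centerline truth as JSON."""
    from .io import write_mask, write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(truth.volume, outdir / "volume.nii.gz")
    write_mask(truth.vessel_mask, outdir / "vessel_mask.nii.gz")
    write_mask(truth.aorta_mask, outdir / "aorta_mask.nii.gz")
    sidecar = {
        "spacing_mm": list(truth.volume.spacing),
        "centerlines_voxels": [p.tolist() for p in truth.centerlines.polylines],
        "radii_mm": [r.tolist() for r in truth.radii_mm],
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar))
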