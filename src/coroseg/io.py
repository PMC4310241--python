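"""Volume and mask I/O in NIfTI-1 (.nii/.nii.gz) and MetaImage (.mha/.mhd).

NIfTI is handled by nibabel, MetaImage by SimpleITK.  Arrays follow the
package convention ``(i, j, k) = (x, y, z)``; SimpleITK's ``(z, y, x)``
array layout is transposed on the way in and out so that read/write is an
identity for values and spacing in both formats.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .volume import BinaryMask, CTAVolume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _format_of(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_META_SUFFIXES):
        return "meta"
    raise ValueError(
        f"unrecognized volume format for {path!r}; expected one of "
        f"{_NIFTI_SUFFIXES + _META_SUFFIXES}"
    )


def _read_array(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if _format_of(path) == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return data, spacing, origin
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got ndim={img.GetDimension()}")
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _write_array(arr: np.ndarray, spacing, origin, path, dtype) -> None:
    path = Path(path)
    arr = np.asarray(arr, dtype=dtype)
    if _format_of(path) == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(spacing)
        nib.save(img, str(path))
        return
    img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | os.PathLike) -> CTAVolume:
    """Read a 3D scalar volume; spacing is populated from the file header.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the image is not 3-dimensional or the format is unrecognized.
    """
    data, spacing, origin = _read_array(path)
    return CTAVolume(data, spacing, origin)


def write_volume(volume: CTAVolume, path: str | os.PathLike) -> None:
    """Write a volume as float64; round-trips bit-exactly through both formats."""
    _write_array(volume.values, volume.spacing, volume.origin, path, np.float64)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask stored as 8-bit {0, 1} labels."""
    data, spacing, _ = _read_array(path)
    return BinaryMask(data.astype(np.uint8), spacing)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit {0, 1} labels, preserving spacing in the header."""
    _write_array(mask.values.astype(np.uint8), mask.spacing, (0.0, 0.0, 0.0),
                 path, np.uint8)
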