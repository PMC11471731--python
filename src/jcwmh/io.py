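"""Reading and writing the raster formats the pipeline touches.

Supported formats:

* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel.  Spacing is taken from the
  header ``pixdim``; 3-D volumes require an explicit ``slice_index``.
* 8-bit grayscale PNG.  PNG carries no physical spacing, so it must be
  supplied explicitly — geometry is never silently defaulted.

On-disk conventions: binary masks are stored 0/255 in PNG and 0/1 in
NIfTI; probability maps stored as uint8 are linearly mapped 0–255 ↔ [0, 1]
on read/write.  Masks round-trip bit-exactly through both formats.
"""

from __future__ import annotations

import os
from typing import Literal

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .rasters import BinaryMask, IntensityImage, ProbabilityMap, VolumeGeometry

__all__ = ["read_raster", "write_raster", "write_overlay_png"]

Kind = Literal["intensity", "probability", "mask"]

_NIFTI_EXTS = (".nii", ".nii.gz")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_EXTS)


def read_raster(
    path: str,
    kind: Kind,
    *,
    geometry: VolumeGeometry | None = None,
    slice_index: int | None = None,
):
    """Read a 2-D raster of the given ``kind`` from NIfTI or PNG.

    Parameters
    ----------
    path : str
        File to read.  ``.nii``/``.nii.gz`` are NIfTI; anything else is
        treated as PNG.
    kind : {"intensity", "probability", "mask"}
        Governs the returned type and value normalisation: probability
        maps stored as integers are rescaled to [0, 1]; masks are
        binarized at > 0.
    geometry : VolumeGeometry, optional
        Required for PNG (which stores no spacing).  For NIfTI it
        overrides the header when given.
    slice_index : int, optional
        For NIfTI volumes with a third dimension, the slice to extract.

    Returns
    -------
    IntensityImage | ProbabilityMap | BinaryMask
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is None:
                raise ValueError(
                    f"{path} is a {data.shape} volume; a slice_index is required"
                )
            else:
                data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
        if geometry is None:
            zooms = img.header.get_zooms()
            thickness = float(zooms[2]) if len(zooms) > 2 else float("nan")
            geometry = VolumeGeometry(float(zooms[0]), float(zooms[1]), thickness)
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # RGB(A) PNG: use luminance-free first channel
            data = data[..., 0]
        if geometry is None:
            raise ValueError(
                f"{path}: PNG carries no spacing; pass geometry explicitly"
            )
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: NaN or infinite pixels")

    if kind == "mask":
        return BinaryMask(data > 0, geometry)
    if kind == "probability":
        fdata = data.astype(np.float64)
        if fdata.size and fdata.max() > 1.0:
            fdata = fdata / 255.0  # uint8 0-255 storage convention
        return ProbabilityMap(fdata, geometry)
    if kind == "intensity":
        return IntensityImage(data.astype(np.float64), geometry)
    raise ValueError(f"unknown raster kind {kind!r}")


def write_raster(img, path: str) -> None:
    """Write a raster to NIfTI or PNG; inverse of :func:`read_raster`.

    Masks round-trip bit-exactly.  Probability maps written to PNG are
    quantised to 8 bits (lossy); NIfTI stores them as float32.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    geom = img.geometry
    if _is_nifti(path):
        if isinstance(img, BinaryMask):
            data = img.pixels.astype(np.uint8)
        else:
            data = img.pixels.astype(np.float32)
        affine = np.diag([geom.spacing_x, geom.spacing_y, 1.0, 1.0])
        nifti = nib.Nifti1Image(data[:, :, None], affine)
        thickness = geom.slice_thickness
        if not np.isfinite(thickness):
            thickness = 1.0
        nifti.header.set_zooms((geom.spacing_x, geom.spacing_y, thickness))
        nib.save(nifti, path)
    else:
        if isinstance(img, BinaryMask):
            data = np.where(img.pixels, 255, 0).astype(np.uint8)
        elif isinstance(img, ProbabilityMap):
            data = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
        else:
            lo, hi = float(img.pixels.min()), float(img.pixels.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            data = np.round((img.pixels - lo) * scale).astype(np.uint8)
        iio.imwrite(path, data)


_DEFAULT_TINT = (255, 64, 64)


def write_overlay_png(
    image: IntensityImage,
    mask: BinaryMask,
    path: str,
    *,
    tint: tuple[int, int, int] = _DEFAULT_TINT,
    alpha: float = 0.6,
) -> None:
    """Export an RGB PNG with ``mask`` pixels tinted onto ``image``.

    Used for visual inspection of lesion / specialized-GM overlays on the
    FLAIR slice.
    """
    lo, hi = float(image.pixels.min()), float(image.pixels.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    gray = np.round((image.pixels - lo) * scale).astype(np.float64)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for c in range(3):
        channel = rgb[..., c]
        channel[mask.pixels] = (1 - alpha) * channel[mask.pixels] + alpha * tint[c]
    iio.imwrite(path, np.clip(np.round(rgb), 0, 255).astype(np.uint8))
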