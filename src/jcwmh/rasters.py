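"""Core 2-D raster containers shared by every stage of the pipeline.

Everything the pipeline touches is a per-slice 2-D grid with physical
in-plane spacing in millimetres: FLAIR intensity slices, tissue
probability maps (values in [0, 1]) and binary masks.  All distance and
area rules downstream are stated in mm, so geometry travels with every
image and mixing images of different geometry is an error.

Coordinate convention: row-major, 0-based indices; pixel (row, col) sits
at physical position (row * spacing_y, col * spacing_x) mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGeometry",
    "IntensityImage",
    "ProbabilityMap",
    "BinaryMask",
    "GeometryMismatchError",
]


class GeometryMismatchError(ValueError):
    """Raised when rasters with incompatible mm spacing are combined."""


@dataclass(frozen=True)
class VolumeGeometry:
    """In-plane voxel spacing (mm per voxel) plus informational thickness.

    Parameters
    ----------
    spacing_x, spacing_y : float
        Millimetres per voxel along image columns / rows.  Must be > 0.
    slice_thickness : float, optional
        Through-plane thickness in mm.  Carried for provenance only; all
        processing is strictly per-slice.
    """

    spacing_x: float
    spacing_y: float
    slice_thickness: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValueError(
                f"spacing must be positive, got ({self.spacing_x}, {self.spacing_y})"
            )

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_x * self.spacing_y

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.hypot(self.spacing_x, self.spacing_y))

    def matches(self, other: "VolumeGeometry", *, rtol: float = 1e-6) -> bool:
        return bool(
            np.isclose(self.spacing_x, other.spacing_x, rtol=rtol)
            and np.isclose(self.spacing_y, other.spacing_y, rtol=rtol)
        )


def _require_same_geometry(*rasters: "_Raster") -> VolumeGeometry:
    geom = rasters[0].geometry
    for r in rasters[1:]:
        if not geom.matches(r.geometry):
            raise GeometryMismatchError(
                f"geometry mismatch: {geom} vs {r.geometry}"
            )
        if r.pixels.shape != rasters[0].pixels.shape:
            raise GeometryMismatchError(
                f"shape mismatch: {rasters[0].pixels.shape} vs {r.pixels.shape}"
            )
    return geom


@dataclass
class _Raster:
    pixels: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grid, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class IntensityImage(_Raster):
    """A FLAIR-like scalar image; arbitrary real range, finite values only."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.pixels = self.pixels.astype(np.float64, copy=False)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensity image contains non-finite values")


@dataclass
class ProbabilityMap(_Raster):
    """A tissue probability map with every pixel in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.pixels = self.pixels.astype(np.float64, copy=False)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("probability map contains non-finite values")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError(
                "probability map values outside [0, 1]; "
                "use io.read_raster which rescales 0-255 storage"
            )


@dataclass
class BinaryMask(_Raster):
    """A boolean mask (lesions, ventricles, binarized tissue)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.pixels = self.pixels.astype(bool, copy=False)

    def count(self) -> int:
        return int(self.pixels.sum())

    def area_mm2(self) -> float:
        return self.count() * self.geometry.pixel_area_mm2

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask":
        """A new mask sharing this mask's geometry."""
        return BinaryMask(pixels=pixels, geometry=self.geometry)
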