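"""Per-lesion geometry: components, contours, distances and areas.

A WMH mask is decomposed into 8-connected components.  For each
component the classifier needs three numbers, all in millimetres:

* the shortest Euclidean distance from the lesion's contour to the
  ventricular contours (minimum over all point pairs);
* the distance from the lesion's mass center to the nearest ventricular
  contour point;
* the shortest distance from the lesion's contour to the GM contours;

plus the lesion area in mm².  A contour is the set of mask pixels with
at least one background 4-neighbour (pixels on the image edge count as
boundary), with pixel centers converted to mm by the raster geometry.

Distances are computed between pixel centers with a KD-tree over the
reference contour points; no sub-pixel interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .rasters import BinaryMask, VolumeGeometry

__all__ = [
    "LesionComponent",
    "ContourSet",
    "NoReferenceError",
    "find_components",
    "extract_contours",
    "contour_pixels",
    "shortest_distance",
    "center_distance",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

CenterMode = Literal["pixels", "contour"]


class NoReferenceError(ValueError):
    """A distance was requested against an empty reference contour set."""


@dataclass
class ContourSet:
    """All boundary points of a mask (possibly many contours), in mm."""

    points_mm: np.ndarray  # (n, 2) array of (y_mm, x_mm)

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=np.float64).reshape(-1, 2)
        self._tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.points_mm)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            if len(self) == 0:
                raise NoReferenceError("empty contour set has no KD-tree")
            self._tree = cKDTree(self.points_mm)
        return self._tree


@dataclass
class LesionComponent:
    """One 8-connected WMH object with its classifier-relevant geometry."""

    id: int
    pixel_indices: np.ndarray  # (k, 2) array of (row, col)
    contour_points_mm: np.ndarray  # (m, 2) array of (y_mm, x_mm)
    mass_center_mm: tuple[float, float]
    area_mm2: float

    @property
    def contour(self) -> ContourSet:
        return ContourSet(self.contour_points_mm)


def contour_pixels(pixels: np.ndarray) -> np.ndarray:
    """Boolean grid of mask pixels with >= 1 false 4-neighbour or on the edge."""
    interior = ndimage.binary_erosion(pixels, structure=_FOUR, border_value=0)
    return pixels & ~interior


def _to_mm(rows_cols: np.ndarray, geom: VolumeGeometry) -> np.ndarray:
    out = np.empty((len(rows_cols), 2), dtype=np.float64)
    out[:, 0] = rows_cols[:, 0] * geom.spacing_y
    out[:, 1] = rows_cols[:, 1] * geom.spacing_x
    return out


def extract_contours(mask: BinaryMask) -> ContourSet:
    """Boundary pixel centers of every object in the mask, in mm."""
    boundary = contour_pixels(mask.pixels)
    rows, cols = np.nonzero(boundary)
    return ContourSet(_to_mm(np.column_stack([rows, cols]), mask.geometry))


def find_components(
    mask: BinaryMask, *, center_mode: CenterMode = "pixels"
) -> list[LesionComponent]:
    """Split a mask into 8-connected components in raster-scan order.

    ``center_mode`` selects the mass-center definition: the centroid of
    the component's pixel set (default) or of its contour points only.
    """
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT)
    geom = mask.geometry
    comps: list[LesionComponent] = []
    if n == 0:
        return comps
    # raster-scan order of each component's first pixel
    first_pixel = ndimage.minimum(
        np.arange(mask.pixels.size).reshape(mask.pixels.shape),
        labels,
        index=range(1, n + 1),
    )
    order = np.argsort(first_pixel, kind="stable") + 1

    for new_id, lab in enumerate(order, start=1):
        comp_pixels = labels == lab
        r, c = np.nonzero(comp_pixels)
        idx = np.column_stack([r, c])
        boundary = contour_pixels(comp_pixels)
        br, bc = np.nonzero(boundary)
        contour_mm = _to_mm(np.column_stack([br, bc]), geom)
        if center_mode == "contour":
            cy, cx = contour_mm[:, 0].mean(), contour_mm[:, 1].mean()
        else:
            cy = r.mean() * geom.spacing_y
            cx = c.mean() * geom.spacing_x
        comps.append(
            LesionComponent(
                id=new_id,
                pixel_indices=idx,
                contour_points_mm=contour_mm,
                mass_center_mm=(float(cy), float(cx)),
                area_mm2=len(r) * geom.pixel_area_mm2,
            )
        )
    return comps


def shortest_distance(a: ContourSet, b: ContourSet) -> float:
    """Minimum Euclidean distance (mm) over all pairs of contour points."""
    if len(a) == 0 or len(b) == 0:
        raise NoReferenceError("shortest_distance requires two non-empty contours")
    if len(a) <= len(b):
        small, big = a, b
    else:
        small, big = b, a
    d, _ = big.tree.query(small.points_mm, k=1)
    return float(np.min(d))


def center_distance(c: LesionComponent, b: ContourSet) -> float:
    """Distance (mm) from the lesion's mass center to the nearest point of b."""
    if len(b) == 0:
        raise NoReferenceError("center_distance requires a non-empty reference")
    d, _ = b.tree.query(np.asarray(c.mass_center_mm), k=1)
    return float(d)
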