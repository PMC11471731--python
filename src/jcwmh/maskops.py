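"""Threshold + morphology post-processing of tissue maps and lesion masks.

Turns raw GM/WM/CSF probability maps and raw WMH/ventricle masks into
the five cleaned binary masks the gray-matter refinement consumes:

* tissue maps are binarized (GM at a low threshold to keep as many GM
  voxels as possible, WM at a high threshold to keep only certain WM,
  CSF in between) and cleaned with a small opening + closing;
* the WMH mask is slightly inflated (one dilation with a 5x5 square
  element) to absorb uncertain lesion boundaries;
* the ventricle mask is closed with a large element to remove dispersed
  punctate noise, then dilated repeatedly (9x9 element, several
  iterations) until it has expanded by more than 10 mm in real-world
  terms, so that it covers periventricular regions falsely labelled as
  gray matter.

Border semantics are pinned so results are reproducible bit-exactly:
every operation treats pixels outside the image as background (zero
padding), and opening/closing are composed explicitly from erosion and
dilation under that convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rasters import BinaryMask, ProbabilityMap

__all__ = [
    "MorphologyConfig",
    "binarize",
    "dilate",
    "erode",
    "opening",
    "closing",
    "postprocess_tissue",
    "postprocess_wmh",
    "postprocess_ventricles",
]

log = logging.getLogger(__name__)


@dataclass
class MorphologyConfig:
    """Thresholds and structuring-element sizes for mask post-processing.

    The tissue thresholds are ordered ``gm_threshold < csf_threshold <
    wm_threshold``: the GM mask is deliberately permissive and the WM
    mask deliberately conservative.  Element sizes are edge lengths of
    square structuring elements, in voxels, and must be odd.
    """

    gm_threshold: float = 0.10
    wm_threshold: float = 0.90
    csf_threshold: float = 0.50
    wmh_dilate_size: int = 5
    vent_close_size: int = 9
    vent_dilate_size: int = 9
    vent_dilate_iters: int = 3
    cleanup_open_size: int = 3
    cleanup_close_size: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.gm_threshold < self.wm_threshold <= 1):
            raise ValueError(
                "thresholds must satisfy 0 < gm_threshold < wm_threshold <= 1"
            )
        if not (0 <= self.csf_threshold <= 1):
            raise ValueError("csf_threshold must lie in [0, 1]")
        for name in (
            "wmh_dilate_size",
            "vent_close_size",
            "vent_dilate_size",
            "cleanup_open_size",
            "cleanup_close_size",
        ):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.vent_dilate_iters < 1:
            raise ValueError("vent_dilate_iters must be >= 1")

    def vent_expansion_mm(self, spacing_min: float) -> float:
        """Guaranteed ventricle boundary expansion of the dilation stage.

        Each dilation with a (2r+1)-square element pushes the boundary
        outward by at least r voxels along the sparser axis.
        """
        r = self.vent_dilate_size // 2
        return self.vent_dilate_iters * r * spacing_min


def _square(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def binarize(pmap: ProbabilityMap, threshold: float) -> BinaryMask:
    """Threshold a probability map; a pixel is kept iff value >= threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return BinaryMask(pmap.pixels >= threshold, pmap.geometry)


def dilate(mask: BinaryMask, size: int, iterations: int = 1) -> BinaryMask:
    out = ndimage.binary_dilation(
        mask.pixels, structure=_square(size), iterations=iterations, border_value=0
    )
    return mask.with_pixels(out)


def erode(mask: BinaryMask, size: int) -> BinaryMask:
    out = ndimage.binary_erosion(
        mask.pixels, structure=_square(size), border_value=0
    )
    return mask.with_pixels(out)


def opening(mask: BinaryMask, size: int) -> BinaryMask:
    """Erosion then dilation, both with zero-padded borders."""
    return dilate(erode(mask, size), size)


def closing(mask: BinaryMask, size: int) -> BinaryMask:
    """Dilation then erosion, both with zero-padded borders."""
    return erode(dilate(mask, size), size)


def _cleanup(mask: BinaryMask, cfg: MorphologyConfig) -> BinaryMask:
    return closing(opening(mask, cfg.cleanup_open_size), cfg.cleanup_close_size)


def postprocess_tissue(
    pmap: ProbabilityMap, threshold: float, cfg: MorphologyConfig
) -> BinaryMask:
    """Binarize a tissue probability map and clean it (open, then close)."""
    out = _cleanup(binarize(pmap, threshold), cfg)
    if out.count() == 0:
        log.warning("tissue post-processing produced an empty mask")
    return out


def postprocess_wmh(mask: BinaryMask, cfg: MorphologyConfig) -> BinaryMask:
    """Slightly inflate the WMH mask: one dilation with a square element."""
    return dilate(mask, cfg.wmh_dilate_size)


def postprocess_ventricles(mask: BinaryMask, cfg: MorphologyConfig) -> BinaryMask:
    """Close the ventricle mask with a large element, then dilate it hard.

    The closing removes dispersed punctate noise; the repeated dilation
    expands the mask by more than 10 mm so it covers periventricular
    tissue that is prone to being mislabelled as GM.  Warns when the
    configured element/iterations cannot reach 10 mm at this spacing.
    """
    spacing_min = min(mask.geometry.spacing_x, mask.geometry.spacing_y)
    if cfg.vent_expansion_mm(spacing_min) <= 10.0:
        log.warning(
            "ventricle dilation config reaches only %.1f mm (<= 10 mm) at "
            "%.2f mm spacing",
            cfg.vent_expansion_mm(spacing_min),
            spacing_min,
        )
    if mask.count() == 0:
        log.warning("ventricle mask is empty; post-processing is a no-op")
        return mask.with_pixels(mask.pixels.copy())
    closed = closing(mask, cfg.vent_close_size)
    return dilate(closed, cfg.vent_dilate_size, iterations=cfg.vent_dilate_iters)
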