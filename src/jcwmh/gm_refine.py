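"""Specialized gray-matter mask construction.

The permissively-binarized GM mask still contains tissue that is useless
or harmful for juxtacortical lesion detection: certain WM, CSF, the
lesions themselves, and periventricular regions prone to GM mislabeling.
The union of the four post-processed non-GM masks is therefore removed
from the GM mask, and the remainder is cleaned with a small opening and
closing.  The result is a cortex proxy — not an anatomically faithful GM
segmentation — tailored so that "close to GM" means "close to cortex".
"""

from __future__ import annotations

import logging

import numpy as np

from .maskops import MorphologyConfig, _cleanup
from .rasters import BinaryMask, _require_same_geometry

__all__ = ["build_union", "refine_gm"]

log = logging.getLogger(__name__)


def build_union(
    wm: BinaryMask, csf: BinaryMask, wmh: BinaryMask, vent: BinaryMask
) -> BinaryMask:
    """Pixel-wise OR of the post-processed WM, CSF, WMH and ventricle masks."""
    _require_same_geometry(wm, csf, wmh, vent)
    union = wm.pixels | csf.pixels | wmh.pixels | vent.pixels
    return wm.with_pixels(union)


def refine_gm(
    gm: BinaryMask,
    union: BinaryMask,
    cfg: MorphologyConfig | None = None,
    *,
    cleanup: bool = True,
) -> BinaryMask:
    """Remove the union mask from the GM mask, then clean the remainder.

    Before cleanup the result is exactly ``gm AND NOT union`` (disjoint
    from the union and contained in the GM mask); the subsequent opening
    and closing remove subtraction debris.  Set ``cleanup=False`` to get
    the raw set difference.
    """
    _require_same_geometry(gm, union)
    diff = gm.with_pixels(gm.pixels & ~union.pixels)
    if not cleanup:
        return diff
    out = _cleanup(diff, cfg or MorphologyConfig())
    if out.count() == 0:
        log.warning("specialized GM mask is empty after refinement")
    return out
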