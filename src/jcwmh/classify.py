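"""Three-class WMH classification by distance and area rules.

Each white-matter-hyperintensity component is assigned exactly one of
three location-based classes, evaluated in this order:

1. periventricular (PE)  — shortest contour distance to the ventricles
   <= 5 mm, or mass-center distance to the ventricles <= 10 mm;
2. juxtacortical (JC)    — shortest contour distance to the GM mask
   < 5 mm AND area < 20 mm²;
3. paraventricular (PA)  — everything else (deep white matter).

Boundary semantics are deliberate and tested: the two ventricle rules
are inclusive (<=), the GM-distance and area rules strict (<).  A lesion
overlapping the ventricle mask has shortest distance 0 and is PE with no
special-casing.

When a reference mask is empty the corresponding rules are skipped with
a warning: no ventricles means a lesion cannot be PE; no GM means it
cannot be JC.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .lesions import (
    CenterMode,
    ContourSet,
    LesionComponent,
    center_distance,
    extract_contours,
    find_components,
    shortest_distance,
)
from .rasters import BinaryMask, VolumeGeometry, _require_same_geometry

__all__ = ["RuleSet", "WMHClass", "LesionRecord", "LabeledLesionMap",
           "classify_lesion", "classify_all"]

log = logging.getLogger(__name__)


class WMHClass(enum.IntEnum):
    """Lesion class and its integer label in rendered maps."""

    PE = 1  # periventricular
    PA = 2  # paraventricular (deep)
    JC = 3  # juxtacortical


#: RGB palette used for overlay rendering: PE red, PA green, JC yellow.
CLASS_COLORS: dict[WMHClass, tuple[int, int, int]] = {
    WMHClass.PE: (255, 0, 0),
    WMHClass.PA: (0, 255, 0),
    WMHClass.JC: (255, 255, 0),
}


@dataclass(frozen=True)
class RuleSet:
    """The four classification thresholds.

    pe_shortest_mm : ventricle contour distance for PE (inclusive <=)
    pe_center_mm   : ventricle mass-center distance for PE (inclusive <=)
    jc_gm_mm       : GM contour distance for JC (strict <)
    jc_max_area_mm2: lesion area bound for JC (strict <)
    """

    pe_shortest_mm: float = 5.0
    pe_center_mm: float = 10.0
    jc_gm_mm: float = 5.0
    jc_max_area_mm2: float = 20.0

    def __post_init__(self) -> None:
        for name in ("pe_shortest_mm", "pe_center_mm", "jc_gm_mm", "jc_max_area_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pe_shortest_mm > self.pe_center_mm:
            raise ValueError("pe_shortest_mm must not exceed pe_center_mm")


@dataclass
class LesionRecord:
    """One classified lesion with the distances that decided its class."""

    id: int
    wmh_class: WMHClass
    area_mm2: float
    d_vent_shortest_mm: float | None
    d_vent_center_mm: float | None
    d_gm_shortest_mm: float | None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "class": self.wmh_class.name,
            "area_mm2": self.area_mm2,
            "d_vent_shortest_mm": self.d_vent_shortest_mm,
            "d_vent_center_mm": self.d_vent_center_mm,
            "d_gm_shortest_mm": self.d_gm_shortest_mm,
        }


@dataclass
class LabeledLesionMap:
    """Per-lesion classes rendered back onto the raster grid.

    ``label_pixels`` is 0 on background and ``WMHClass`` values on
    lesions; ``per_lesion`` records each lesion's class and distances.
    """

    label_pixels: np.ndarray
    geometry: VolumeGeometry
    per_lesion: list[LesionRecord] = field(default_factory=list)

    def class_mask(self, cls: WMHClass) -> BinaryMask:
        return BinaryMask(self.label_pixels == int(cls), self.geometry)

    def counts(self) -> dict[str, int]:
        return {
            cls.name: sum(1 for r in self.per_lesion if r.wmh_class is cls)
            for cls in WMHClass
        }


def classify_lesion(
    c: LesionComponent,
    vent: ContourSet | None,
    gm: ContourSet | None,
    rules: RuleSet,
) -> tuple[WMHClass, LesionRecord]:
    """Apply the rule chain to one lesion; returns class and full record."""
    d_vs = d_vc = d_gm = None
    if vent is not None and len(vent) > 0:
        d_vs = shortest_distance(c.contour, vent)
        d_vc = center_distance(c, vent)
    else:
        log.warning("lesion %d: no ventricle contours; PE rules skipped", c.id)
    if gm is not None and len(gm) > 0:
        d_gm = shortest_distance(c.contour, gm)
    else:
        log.warning("lesion %d: no GM contours; JC rule skipped", c.id)

    if d_vs is not None and d_vs <= rules.pe_shortest_mm:
        cls = WMHClass.PE
    elif d_vc is not None and d_vc <= rules.pe_center_mm:
        cls = WMHClass.PE
    elif d_gm is not None and d_gm < rules.jc_gm_mm and c.area_mm2 < rules.jc_max_area_mm2:
        cls = WMHClass.JC
    else:
        cls = WMHClass.PA
    record = LesionRecord(c.id, cls, c.area_mm2, d_vs, d_vc, d_gm)
    return cls, record


def classify_all(
    wmh: BinaryMask,
    vent: BinaryMask,
    gm: BinaryMask,
    rules: RuleSet | None = None,
    *,
    center_mode: CenterMode = "pixels",
) -> LabeledLesionMap:
    """Classify every WMH component against ventricle and GM masks.

    ``gm`` is expected to be the specialized (refined) GM mask and
    ``vent`` the cleaned ventricle mask; ``wmh`` the original
    (pre-inflation) lesion mask, so lesion geometry is unaltered.
    """
    _require_same_geometry(wmh, vent, gm)
    rules = rules or RuleSet()
    vent_contours = extract_contours(vent)
    gm_contours = extract_contours(gm)
    labels = np.zeros(wmh.pixels.shape, dtype=np.int16)
    records: list[LesionRecord] = []
    for comp in find_components(wmh, center_mode=center_mode):
        cls, rec = classify_lesion(comp, vent_contours, gm_contours, rules)
        labels[comp.pixel_indices[:, 0], comp.pixel_indices[:, 1]] = int(cls)
        records.append(rec)
    return LabeledLesionMap(labels, wmh.geometry, records)
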