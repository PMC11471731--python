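"""Seeded synthetic FLAIR-like slices with known lesion classes.

Each phantom is a single axial-slice caricature of a lesion-bearing
brain: an elliptical head with an outer CSF rim, a cortical GM ribbon
just inside the rim, white matter filling the interior, and a pair of
mirrored central ventricles.  Hyperintense lesions are planted inside
the white matter at controlled distances from the ventricular and GM
contours and with controlled areas, so that the class of every lesion
(periventricular / paraventricular / juxtacortical) is known by
construction with a configurable safety margin beyond every decision
threshold.

The generator does its own distance bookkeeping with the same contour
and distance definitions as the classifier, and re-verifies every
placement before accepting it; the test-suite re-verifies placements
again through the public lesion-geometry API, so a bug would have to be
present identically in two code paths to go unnoticed.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .classify import LabeledLesionMap, LesionRecord, RuleSet, WMHClass
from .gm_refine import build_union, refine_gm
from .lesions import ContourSet, contour_pixels
from .maskops import (
    MorphologyConfig,
    binarize,
    postprocess_tissue,
    postprocess_ventricles,
    postprocess_wmh,
)
from .rasters import BinaryMask, IntensityImage, ProbabilityMap, VolumeGeometry

__all__ = ["PhantomSpec", "PhantomBundle", "generate", "generate_pairs",
           "inject_gm_leak", "PlacementError"]

log = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Raised when a lesion of a given class cannot be placed."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``n_lesions_per_class`` is (PE, PA, JC) counts; ``margin_mm`` is the
    safety slack kept between every planted lesion and every decision
    threshold, so pixelation can never flip a planted class.
    """

    image_size: int = 256
    spacing: float = 0.9
    n_lesions_per_class: tuple[int, int, int] = (2, 2, 2)
    lesion_radius_range_mm: tuple[float, float] = (1.2, 3.0)
    margin_mm: float = 1.5
    noise_sigma: float = 0.03
    seed: int = 0
    rules: RuleSet = field(default_factory=RuleSet)

    def __post_init__(self) -> None:
        if self.margin_mm <= 0:
            raise ValueError("margin_mm must be positive")
        if self.image_size < 48:
            raise ValueError("image_size must be >= 48 to fit the anatomy")
        if self.image_size * self.spacing < 100.0:
            raise ValueError(
                "field of view below 100 mm cannot hold the anatomy plus the "
                "distance rules; increase image_size or spacing"
            )

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.spacing, self.spacing, 6.0)


@dataclass
class PhantomBundle:
    """One phantom: image, probability maps, masks and truth labels."""

    flair: IntensityImage
    gm_prob: ProbabilityMap
    wm_prob: ProbabilityMap
    csf_prob: ProbabilityMap
    vent_mask: BinaryMask
    wmh_mask: BinaryMask
    truth_labels: LabeledLesionMap
    spec: PhantomSpec

    def gm_ribbon_mask(self) -> BinaryMask:
        """The anatomical cortical ribbon (GM probability majority)."""
        return binarize(self.gm_prob, 0.5)


# -- geometry helpers -------------------------------------------------------


def _mm_grids(size: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    coords = np.arange(size) * spacing
    return np.meshgrid(coords, coords, indexing="ij")  # (Y_mm, X_mm)


def _ellipse(
    Y: np.ndarray, X: np.ndarray, cy: float, cx: float,
    a_y: float, a_x: float, theta: float = 0.0,
) -> np.ndarray:
    """Filled rotated ellipse in mm coordinates (semi-axes a_y, a_x)."""
    dy, dx = Y - cy, X - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a_x) ** 2 + (v / a_y) ** 2 <= 1.0


def _contour_points_mm(pixels: np.ndarray, spacing: float) -> np.ndarray:
    r, c = np.nonzero(contour_pixels(pixels))
    return np.column_stack([r * spacing, c * spacing]).astype(np.float64)


def _edt_mm(pixels: np.ndarray, spacing: float) -> np.ndarray:
    """Distance (mm) from each pixel to the nearest true pixel of `pixels`."""
    if not pixels.any():
        return np.full(pixels.shape, np.inf)
    return ndimage.distance_transform_edt(~pixels, sampling=(spacing, spacing))


# -- anatomy ----------------------------------------------------------------


@dataclass
class _Anatomy:
    head: np.ndarray
    csf_rim: np.ndarray
    gm_ribbon: np.ndarray
    wm: np.ndarray
    vent: np.ndarray


def _build_anatomy(spec: PhantomSpec, rng: np.random.Generator) -> _Anatomy:
    size, sp = spec.image_size, spec.spacing
    Y, X = _mm_grids(size, sp)
    cy = cx = (size - 1) * sp / 2.0
    half = size * sp / 2.0

    # mild seeded jitter so phantoms differ across seeds
    ay = half * 0.90 * rng.uniform(0.96, 1.0)
    ax = half * 0.76 * rng.uniform(0.96, 1.0)
    head = _ellipse(Y, X, cy, cx, ay, ax)

    rim_mm = rng.uniform(2.5, 3.5)
    ribbon_mm = rng.uniform(4.0, 5.0)
    inner1 = _ellipse(Y, X, cy, cx, ay - rim_mm, ax - rim_mm)
    inner2 = _ellipse(Y, X, cy, cx, ay - rim_mm - ribbon_mm, ax - rim_mm - ribbon_mm)
    csf_rim = head & ~inner1
    gm_ribbon = inner1 & ~inner2

    # butterfly ventricles: two mirrored tilted ellipses near the center
    v_ay = half * rng.uniform(0.20, 0.24)
    v_ax = half * rng.uniform(0.075, 0.095)
    v_off = half * rng.uniform(0.13, 0.16)
    tilt = rng.uniform(0.12, 0.25)
    vent = _ellipse(Y, X, cy, cx - v_off, v_ay, v_ax, -tilt) | _ellipse(
        Y, X, cy, cx + v_off, v_ay, v_ax, tilt
    )
    vent &= inner2
    wm = inner2 & ~vent
    return _Anatomy(head, csf_rim, gm_ribbon, wm, vent)


# -- lesion planting --------------------------------------------------------


def _lesion_shape(
    rng: np.random.Generator, r_mm: float
) -> tuple[float, float, float]:
    """Semi-axes (a_y, a_x) with axis ratio <= 2 and a rotation angle."""
    ratio = rng.uniform(1.0, 2.0)
    a = r_mm * np.sqrt(ratio)
    b = r_mm / np.sqrt(ratio)
    return a, b, rng.uniform(0, np.pi)


def _min_dist(points: np.ndarray, ref: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(ref).query(points, k=1)
    return float(np.min(d))


def _verify_class(
    lesion_pixels: np.ndarray,
    planted: WMHClass,
    vent_pts: np.ndarray,
    gm_pts: np.ndarray,
    spec: PhantomSpec,
) -> LesionRecord | None:
    """Margin-checked distance bookkeeping; None if placement is unsafe."""
    sp, m, rules = spec.spacing, spec.margin_mm, spec.rules
    contour = _contour_points_mm(lesion_pixels, sp)
    r, c = np.nonzero(lesion_pixels)
    center = np.array([r.mean() * sp, c.mean() * sp])
    area = len(r) * sp * sp
    d_vs = _min_dist(contour, vent_pts)
    d_vc = _min_dist(center[None, :], vent_pts)
    d_gm = _min_dist(contour, gm_pts)

    ok = False
    if planted is WMHClass.PE:
        ok = d_vs <= rules.pe_shortest_mm - m
    elif planted is WMHClass.PA:
        ok = (
            d_vs >= rules.pe_shortest_mm + m
            and d_vc >= rules.pe_center_mm + m
            and d_gm >= rules.jc_gm_mm + m
        )
    elif planted is WMHClass.JC:
        ok = (
            d_vs >= rules.pe_shortest_mm + m
            and d_vc >= rules.pe_center_mm + m
            and d_gm <= rules.jc_gm_mm - m
            and area <= rules.jc_max_area_mm2 - 2.0
        )
    if not ok:
        return None
    return LesionRecord(0, planted, area, d_vs, d_vc, d_gm)


_MAX_TRIES = 400


def _plant_lesions(
    spec: PhantomSpec,
    anat: _Anatomy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[WMHClass, LesionRecord]]]:
    size, sp = spec.image_size, spec.spacing
    Y, X = _mm_grids(size, sp)
    vent_pts = _contour_points_mm(anat.vent, sp)
    gm_pts = _contour_points_mm(anat.gm_ribbon, sp)
    d_vent = _edt_mm(anat.vent, sp)
    d_gm = _edt_mm(anat.gm_ribbon, sp)
    rules, m = spec.rules, spec.margin_mm

    wmh = np.zeros((size, size), dtype=bool)
    labels = np.zeros((size, size), dtype=np.int16)
    # lesions live strictly inside WM; a 2-px moat between lesions keeps
    # 8-connected components from merging
    lesion_moat = np.zeros((size, size), dtype=bool)
    records: list[tuple[WMHClass, LesionRecord]] = []

    r_lo, r_hi = spec.lesion_radius_range_mm
    jc_r_hi = min(r_hi, 0.92 * np.sqrt((rules.jc_max_area_mm2 - 2.0) / np.pi))

    def candidate_centers(planted: WMHClass, a_max: float) -> np.ndarray:
        if planted is WMHClass.PA:
            sel = (
                anat.wm
                & (d_vent >= max(rules.pe_shortest_mm + m + a_max + sp,
                                 rules.pe_center_mm + m + sp))
                & (d_gm >= rules.jc_gm_mm + m + a_max + sp)
            )
        elif planted is WMHClass.JC:
            sel = (
                anat.wm
                & (d_gm >= 2.0 + a_max)
                & (d_gm <= 3.2 + a_max)
                & (d_vent >= rules.pe_center_mm + m + sp)
            )
        else:  # PE: ring just outside the ventricles
            sel = (
                anat.wm
                & (d_vent >= 0.7 + a_max)
                & (d_vent <= (rules.pe_shortest_mm - m) + a_max - 0.3)
            )
        r, c = np.nonzero(sel)
        return np.column_stack([r, c])

    plan = (
        [(WMHClass.PE, spec.n_lesions_per_class[0])]
        + [(WMHClass.PA, spec.n_lesions_per_class[1])]
        + [(WMHClass.JC, spec.n_lesions_per_class[2])]
    )
    for planted, count in plan:
        for _ in range(count):
            placed = False
            for _try in range(_MAX_TRIES):
                if planted is WMHClass.JC:
                    r_mm = rng.uniform(min(r_lo, jc_r_hi), jc_r_hi)
                else:
                    r_mm = rng.uniform(r_lo, r_hi)
                a, b, theta = _lesion_shape(rng, r_mm)
                cand = candidate_centers(planted, max(a, b))
                if len(cand) == 0:
                    continue
                row, col = cand[rng.integers(len(cand))]
                les = _ellipse(Y, X, row * sp, col * sp, a, b, theta)
                if not les.any():
                    continue
                if (les & ~anat.wm).any():
                    continue
                grown = ndimage.binary_dilation(les, iterations=2)
                if (grown & lesion_moat).any():
                    continue
                rec = _verify_class(les, planted, vent_pts, gm_pts, spec)
                if rec is None:
                    continue
                wmh |= les
                labels[les] = int(planted)
                lesion_moat |= grown
                records.append((planted, rec))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {planted.name} lesion after "
                    f"{_MAX_TRIES} tries (image too small or margins too large)"
                )
    return wmh, labels, records


# -- assembly ---------------------------------------------------------------

_INTENSITY = {"bg": 0.0, "csf": 0.10, "wm": 0.45, "gm": 0.62, "wmh": 0.92}


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Generate one phantom bundle, bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    for attempt in range(20):
        anat = _build_anatomy(spec, rng)
        try:
            wmh, label_grid, planted = _plant_lesions(spec, anat, rng)
        except PlacementError:
            if attempt == 19:
                raise
            continue
        break

    size = spec.image_size
    gm_p = np.zeros((size, size))
    wm_p = np.zeros((size, size))
    csf_p = np.zeros((size, size))
    csf_like = anat.csf_rim | anat.vent
    gm_p[anat.gm_ribbon] = 0.90
    wm_p[anat.gm_ribbon] = 0.05
    csf_p[anat.gm_ribbon] = 0.05
    wm_p[anat.wm] = 0.95
    gm_p[anat.wm] = 0.03
    csf_p[anat.wm] = 0.02
    csf_p[csf_like] = 0.95
    gm_p[csf_like] = 0.03
    wm_p[csf_like] = 0.02

    flair = np.full((size, size), _INTENSITY["bg"])
    flair[anat.wm] = _INTENSITY["wm"]
    flair[anat.gm_ribbon] = _INTENSITY["gm"]
    flair[csf_like] = _INTENSITY["csf"]
    flair[wmh] = _INTENSITY["wmh"]
    flair = flair + rng.normal(0.0, spec.noise_sigma, flair.shape)

    records = []
    for i, (planted_cls, rec) in enumerate(planted, start=1):
        records.append(replace(rec, id=i))
    truth = LabeledLesionMap(label_grid, geom, records)

    return PhantomBundle(
        flair=IntensityImage(flair, geom),
        gm_prob=ProbabilityMap(gm_p, geom),
        wm_prob=ProbabilityMap(wm_p, geom),
        csf_prob=ProbabilityMap(csf_p, geom),
        vent_mask=BinaryMask(anat.vent, geom),
        wmh_mask=BinaryMask(wmh, geom),
        truth_labels=truth,
        spec=spec,
    )


def pipeline_gm_target(
    bundle: PhantomBundle, cfg: MorphologyConfig | None = None
) -> BinaryMask:
    """Specialized GM mask from the real pipeline applied to a bundle."""
    cfg = cfg or MorphologyConfig()
    gm_bin = binarize(bundle.gm_prob, cfg.gm_threshold)
    wm = postprocess_tissue(bundle.wm_prob, cfg.wm_threshold, cfg)
    csf = postprocess_tissue(bundle.csf_prob, cfg.csf_threshold, cfg)
    wmh_inf = postprocess_wmh(bundle.wmh_mask, cfg)
    vent_inf = postprocess_ventricles(bundle.vent_mask, cfg)
    union = build_union(wm, csf, wmh_inf, vent_inf)
    return refine_gm(gm_bin, union, cfg)


def generate_pairs(
    spec: PhantomSpec, n: int, cfg: MorphologyConfig | None = None
) -> list[tuple[IntensityImage, BinaryMask]]:
    """(FLAIR, specialized-GM) training pairs for the surrogate model.

    The target mask of each pair is produced by running the *actual*
    mask-processing + GM-refinement pipeline on the phantom's
    probability maps and masks, so a model trained on these pairs learns
    the pipeline itself, not the anatomical ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = []
    for i in range(n):
        bundle = generate(replace(spec, seed=spec.seed + i))
        pairs.append((bundle.flair, pipeline_gm_target(bundle, cfg)))
    return pairs


def inject_gm_leak(
    bundle: PhantomBundle, rng: np.random.Generator | None = None
) -> PhantomBundle:
    """Adversarial variant: a GM-probability leak next to a deep lesion.

    Emulates the common failure mode of tissue segmentation near the
    ventricles: a periventricular patch is falsely given high GM
    probability.  A small paraventricular lesion is planted just beyond
    the 10 mm center-distance limit, and the leak is placed between it
    and the ventricle — close enough to the lesion (< 5 mm) that a
    classifier trusting the raw GM map will call the lesion
    juxtacortical, while the refinement pipeline removes the leak (it
    lies inside the inflated ventricle mask) and classifies it
    correctly.
    """
    rng = rng or np.random.default_rng(bundle.spec.seed + 10_007)
    spec = bundle.spec
    sp, size = spec.spacing, spec.image_size
    Y, X = _mm_grids(size, sp)
    vent = bundle.vent_mask.pixels
    gm_ribbon = bundle.gm_ribbon_mask().pixels
    wm = ~(vent | gm_ribbon | (bundle.csf_prob.pixels > 0.5)) & (
        bundle.wm_prob.pixels > 0.5
    )
    vent_pts = _contour_points_mm(vent, sp)
    gm_pts = _contour_points_mm(gm_ribbon, sp)
    d_vent = _edt_mm(vent, sp)

    occupied = ndimage.binary_dilation(bundle.wmh_mask.pixels, iterations=3)
    r_les = 1.8
    for _ in range(_MAX_TRIES):
        # lesion center ~12 mm from the ventricle contour, in clean WM
        sel = wm & (d_vent >= 11.8) & (d_vent <= 13.0) & ~occupied
        rr, cc = np.nonzero(sel)
        if len(rr) == 0:
            raise PlacementError("no room for the adversarial lesion")
        k = rng.integers(len(rr))
        row, col = rr[k], cc[k]
        les = _ellipse(Y, X, row * sp, col * sp, r_les, r_les)
        if (ndimage.binary_dilation(les, iterations=2) & occupied).any():
            continue
        if not (les & wm).sum() == les.sum():
            continue
        rec = _verify_class(les, WMHClass.PA, vent_pts, gm_pts, bundle.spec)
        if rec is None:
            continue
        # leak: a GM-probability blob between lesion and ventricle, fully
        # inside the >10 mm inflation reach of the ventricle mask
        center = np.array([row * sp, col * sp])
        from scipy.spatial import cKDTree

        _, j = cKDTree(vent_pts).query(center, k=1)
        toward = vent_pts[j] - center
        toward = toward / np.linalg.norm(toward)
        leak_c = center + toward * (r_les + 1.5 + 1.4)  # ~1.5 mm gap
        leak = _ellipse(Y, X, leak_c[0], leak_c[1], 1.4, 1.4)
        leak &= wm & ~les
        if not leak.any():
            continue
        if float(d_vent[leak].max()) > 10.0:
            continue  # leak must be covered by the inflated ventricles
        gap = _min_dist(_contour_points_mm(les, sp), _contour_points_mm(leak, sp))
        if not (0.8 <= gap <= bundle.spec.rules.jc_gm_mm - bundle.spec.margin_mm):
            continue

        wmh = bundle.wmh_mask.pixels | les
        label_grid = bundle.truth_labels.label_pixels.copy()
        label_grid[les] = int(WMHClass.PA)
        gm_p = bundle.gm_prob.pixels.copy()
        wm_p = bundle.wm_prob.pixels.copy()
        csf_p = bundle.csf_prob.pixels.copy()
        gm_p[leak] = 0.85
        wm_p[leak] = 0.10
        csf_p[leak] = 0.05
        flair = bundle.flair.pixels.copy()
        flair[les] = _INTENSITY["wmh"]

        records = list(bundle.truth_labels.per_lesion)
        records.append(replace(rec, id=len(records) + 1))
        geom = bundle.flair.geometry
        return PhantomBundle(
            flair=IntensityImage(flair, geom),
            gm_prob=ProbabilityMap(gm_p, geom),
            wm_prob=ProbabilityMap(wm_p, geom),
            csf_prob=ProbabilityMap(csf_p, geom),
            vent_mask=BinaryMask(vent, geom),
            wmh_mask=BinaryMask(wmh, geom),
            truth_labels=LabeledLesionMap(label_grid, geom, records),
            spec=spec,
        )
    raise PlacementError("could not construct the adversarial phantom")
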