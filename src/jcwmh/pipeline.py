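"""End-to-end flows: mask preparation -> GM refinement -> classification.

``run_pipeline`` is the reference flow: the five input rasters are
post-processed, the union of the four non-GM masks is removed from the
permissive GM mask, and every WMH component is classified against the
ventricular and specialized-GM contours.  ``run_baseline_t1`` is the
comparison arm: it classifies against the raw binarized GM probability
map with no refinement at all, the behaviour of a system that trusts
the registered-T1 GM segmentation as-is.  The difference between the two
arms is the point of the method: the baseline can call a deep lesion
juxtacortical because of GM mislabelled near the ventricles; the
pipeline removes such pixels by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .classify import LabeledLesionMap, RuleSet, classify_all
from .gm_refine import build_union, refine_gm
from .lesions import CenterMode
from .maskops import (
    MorphologyConfig,
    binarize,
    closing,
    postprocess_tissue,
    postprocess_ventricles,
    postprocess_wmh,
)
from .rasters import BinaryMask, ProbabilityMap

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_baseline_t1",
           "StageError"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything that parameterises one reproducible run."""

    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    rules: RuleSet = field(default_factory=RuleSet)
    spacing: tuple[float, float] | None = None  # geometry override for PNGs
    center_mode: CenterMode = "pixels"
    use_inflated_wmh: bool = False  # classify on dilated lesion geometry
    use_inflated_ventricles: bool = False  # measure distances to inflated mask
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["spacing"] is not None:
            d["spacing"] = list(d["spacing"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "morphology" in d:
            d["morphology"] = MorphologyConfig(**d["morphology"])
        if "rules" in d:
            d["rules"] = RuleSet(**d["rules"])
        if d.get("spacing") is not None:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Outputs and intermediates of one pipeline run."""

    specialized_gm: BinaryMask
    union: BinaryMask
    labels: LabeledLesionMap
    gm_binarized: BinaryMask
    wm: BinaryMask
    csf: BinaryMask
    wmh_inflated: BinaryMask
    vent_inflated: BinaryMask
    vent_reference: BinaryMask
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def classification_ventricles(vent: BinaryMask, cfg: RunConfig) -> BinaryMask:
    """The ventricle mask against which classification distances are taken.

    By default the denoised (closed) mask *before* the >10 mm inflation:
    the inflation exists to build the union mask, and measuring the 5 mm
    / 10 mm rules against an inflated contour would make them vacuous.
    ``use_inflated_ventricles`` switches to the fully inflated mask.
    """
    if cfg.use_inflated_ventricles:
        return postprocess_ventricles(vent, cfg.morphology)
    if vent.count() == 0:
        return vent
    return closing(vent, cfg.morphology.vent_close_size)


def run_pipeline(
    gm_prob: ProbabilityMap,
    wm_prob: ProbabilityMap,
    csf_prob: ProbabilityMap,
    wmh: BinaryMask,
    vent: BinaryMask,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """The full specialized-GM + classification flow."""
    cfg = cfg or RunConfig()
    m = cfg.morphology

    prep = _stage("maskops")(
        lambda: (
            binarize(gm_prob, m.gm_threshold),
            postprocess_tissue(wm_prob, m.wm_threshold, m),
            postprocess_tissue(csf_prob, m.csf_threshold, m),
            postprocess_wmh(wmh, m),
            postprocess_ventricles(vent, m),
        )
    )
    gm_bin, wm_mask, csf_mask, wmh_inf, vent_inf = prep()

    refine = _stage("gm_refine")(
        lambda: (
            build_union(wm_mask, csf_mask, wmh_inf, vent_inf),
        )
    )
    (union,) = refine()
    specialized = _stage("gm_refine")(lambda: refine_gm(gm_bin, union, m))()

    vent_ref = classification_ventricles(vent, cfg)
    wmh_for_classify = wmh_inf if cfg.use_inflated_wmh else wmh
    labels = _stage("classify")(
        lambda: classify_all(
            wmh_for_classify,
            vent_ref,
            specialized,
            cfg.rules,
            center_mode=cfg.center_mode,
        )
    )()

    counts = {
        "gm_binarized": gm_bin.count(),
        "wm": wm_mask.count(),
        "csf": csf_mask.count(),
        "wmh_inflated": wmh_inf.count(),
        "vent_inflated": vent_inf.count(),
        "union": union.count(),
        "specialized_gm": specialized.count(),
        "lesions": len(labels.per_lesion),
    }
    for name, n in counts.items():
        log.info("stage %-16s %8d px", name, n)
        if n == 0 and name not in ("lesions",):
            log.warning("stage %s produced an empty mask", name)

    manifest = {
        "tool": "jcwmh",
        "version": __version__,
        "config": cfg.to_dict(),
        "pixel_counts": counts,
        "classes": labels.counts(),
    }
    return PipelineResult(
        specialized_gm=specialized,
        union=union,
        labels=labels,
        gm_binarized=gm_bin,
        wm=wm_mask,
        csf=csf_mask,
        wmh_inflated=wmh_inf,
        vent_inflated=vent_inf,
        vent_reference=vent_ref,
        manifest=manifest,
    )


def run_baseline_t1(
    gm_prob: ProbabilityMap,
    wmh: BinaryMask,
    vent: BinaryMask,
    cfg: RunConfig | None = None,
) -> LabeledLesionMap:
    """Comparison arm: classify against the raw binarized GM map.

    No union filtering, no morphology on the GM map — the GM reference
    is exactly ``binarize(gm_prob, gm_threshold)``.  Ventricle handling
    is identical to the pipeline arm so the two arms differ only in the
    GM reference.
    """
    cfg = cfg or RunConfig()
    gm_raw = binarize(gm_prob, cfg.morphology.gm_threshold)
    vent_ref = classification_ventricles(vent, cfg)
    return classify_all(
        wmh, vent_ref, gm_raw, cfg.rules, center_mode=cfg.center_mode
    )


def save_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
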