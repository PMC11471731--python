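# jcwmh

Location-based classification of white matter hyperintensities (WMH) on
FLAIR MRI slices, built around a *specialized gray-matter mask* that makes
juxtacortical lesions detectable by a simple distance rule.

WMH — the bright lesions seen on T2-FLAIR in multiple sclerosis and
small-vessel disease — are conventionally subdivided by location:
**periventricular (PE)** lesions hug the ventricles, **juxtacortical
(JC)** lesions touch the cortex, and **paraventricular (PA,** deep
white-matter**)** lesions sit in between. The location class carries
diagnostic weight (the McDonald criteria count periventricular and
juxtacortical lesions separately), but automating it is blocked by one
practical problem: raw gray-matter segmentations of lesion-bearing FLAIR
images are unreliable near the ventricles, where tissue is routinely
mislabeled as GM. A classifier that measures "distance to cortex" on such
a map will call deep lesions juxtacortical.

`jcwmh` implements the two-part remedy:

1. **Specialized GM segmentation.** The GM probability map is binarized
   permissively (threshold 0.10) and then *filtered*: the union of the
   post-processed WM mask (threshold 0.90), CSF mask (0.50), the
   5×5-dilated WMH mask, and the ventricle mask closed and dilated by
   more than 10 mm is subtracted from it. What survives is a cortex
   proxy with no periventricular debris.

2. **Rule-chain classification.** Each 8-connected lesion component
   with contour *C*, centroid *m* and area *A* is assigned, in order:

   | rule | condition | class |
   |------|-----------|-------|
   | 1 | d(C, ventricle contour) ≤ 5 mm | PE |
   | 2 | d(m, ventricle contour) ≤ 10 mm | PE |
   | 3 | d(C, GM contour) < 5 mm **and** A < 20 mm² | JC |
   | 4 | otherwise | PA |

   where d(·,·) is the minimum Euclidean distance in millimetres.
   Boundary semantics are exact: the ventricle rules are inclusive, the
   GM and area rules strict.

The package also provides pixel-level evaluation metrics (Dice,
IoU, precision, sensitivity, specificity, accuracy, with per-class /
macro / support-weighted report tables), a seeded **phantom generator**
that plants lesions at controlled distances so every rule is testable
without patient data, and a small **pix2pix-style surrogate** (U-Net
generator + patch discriminator, written in numpy) that learns the
FLAIR → specialized-GM mapping so the whole mask pipeline can be
replaced by one forward pass.

## Worked example

```python
from jcwmh.phantom import PhantomSpec, generate
from jcwmh.pipeline import run_pipeline
from jcwmh.metrics import class_report

b = generate(PhantomSpec(seed=11))          # 256 px, 0.9 mm, 2+2+2 lesions
res = run_pipeline(b.gm_prob, b.wm_prob, b.csf_prob, b.wmh_mask, b.vent_mask)
print(res.manifest["classes"])
for r in res.labels.per_lesion[:2]:
    print(r.to_dict())
print(class_report(res.labels, b.truth_labels).summary())
```

prints

```
{'PE': 2, 'PA': 2, 'JC': 2}
{'id': 1, 'class': 'JC', 'area_mm2': 13.77, 'd_vent_shortest_mm': 60.3,
 'd_vent_center_mm': 62.11, 'd_gm_shortest_mm': 2.7}
{'id': 2, 'class': 'PE', 'area_mm2': 23.49, 'd_vent_shortest_mm': 1.27,
 'd_vent_center_mm': 4.5, 'd_gm_shortest_mm': 58.83}
                DSC  Precision  Sensitivity  Specificity  Accuracy  Support
PE           1.0000     1.0000       1.0000       1.0000    1.0000       52
PA           1.0000     1.0000       1.0000       1.0000    1.0000       46
JC           1.0000     1.0000       1.0000       1.0000    1.0000       30
macro avg    1.0000     1.0000       1.0000       1.0000    1.0000      128
weighted avg 1.0000     1.0000       1.0000       1.0000    1.0000      128
```

Lesion 1 sits 2.7 mm from the specialized GM contour with area
13.8 mm² (< 20), so rule 3 fires: juxtacortical. Lesion 2 is 1.3 mm
from a ventricle: periventricular by rule 1. On this clean phantom the
pipeline recovers every planted class, so every per-class Dice is 1.

The same flows are available from the shell:

```sh
jcwmh phantom --n 1 --size 256 --seed 11 --out ph/
jcwmh run --gm ph/phantom000_gm_prob.nii.gz --wm ph/phantom000_wm_prob.nii.gz \
      --csf ph/phantom000_csf_prob.nii.gz --wmh ph/phantom000_wmh.nii.gz \
      --vent ph/phantom000_vent.nii.gz --truth ph/phantom000_labels.nii.gz --out out/
```

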