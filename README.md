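# zmo — zygomatico-orbital reconstruction-accuracy morphometry

`zmo` measures how accurately a zygomatico-orbital (ZMO) fracture has been
reduced relative to the mirrored presurgical plan. In navigation-guided
craniofacial surgery the unaffected half of the face is segmented, mirrored
across the midsagittal plane and used as the ideal target for the fractured
side; `zmo` quantifies the residual discrepancy between the actual anatomy
(pre- or postoperative CT segmentations) and that plan object. It is aimed at
craniofacial surgeons and imaging researchers who have label volumes and
anatomical landmarks and want reproducible, scriptable outcome metrics
instead of manual planning-station measurements.

## The metrics

All geometry lives in an anatomical head frame: the **Frankfort horizontal
(FH) plane** is the least-squares plane through bilateral porion and
orbitale, and the **vertical midline** (midsagittal plane) is perpendicular
to it through the nasion and the porion midpoint.

**Zygoma.** Displacement is scored at the five key sutures — zygomatico-
maxillary (ZM), zygomaticofrontal (ZF), inferior orbital rim (IO),
zygomaticosphenoidal (ZS), zygomaticotemporal (ZT) — as the distance from
each suture landmark to its mirrored-plan counterpart, and summed. On an
axial slice parallel to FH through the zygomatic prominence, point *O* is the
intersection of the midline with the line through the bilateral zygomatic-
arch bases. Five rays from *O*, evenly spaced in angle between the
infraorbital foramen and the arch base, cut the actual contour at Z1–Z5 and
the plan contour at P1–P5. The **deviation index** is

    DI = Σ_{k=1..5} |Z_k P_k|   (mm)

and the conformance sums Σ|Z_kO|, Σ|P_kO| compare result against plan.

**Orbit.** Cavity volume is voxel count × voxel volume per side, with the
bilateral difference |V_affected − V_unaffected|. The orbital floor is traced
in the sagittal plane through the cavity centroid; coronal planes at arc
fractions 1/6, 1/2 and 5/6 sample the anterior, middle and posterior thirds,
and in each coronal section the interior angle of the medial transition-zone
buttress (floor / medial-wall junction) is estimated from line fits on both
limbs of the detected corner.

**Statistics.** Pre- vs postoperative metrics are compared with an exact
two-sided Wilcoxon signed-rank test (full null distribution by dynamic
programming, equivalent to enumerating all 2^n sign patterns) — appropriate
for the small paired samples these studies produce.

Because no imaging data accompany such studies, the package ships a
**synthetic cranial phantom**: analytic zygoma shells, orbital cavities and
the full landmark set, with a known rigid fragment displacement and a known
orbital-volume increment, so every metric can be validated against ground
truth.

## Worked example

```python
import numpy as np
from zmo import *

spec = PhantomSpec(
    side_affected="left",
    zygoma_translation_mm=(-3.0, 1.0, 0.0),   # 3 mm lateral + 1 mm anterior
    zygoma_rotation_deg=4.0,                  # about the prominence
    orbital_volume_increment_mm3=3930.0,      # blow-out expansion
    voxel_spacing_mm=(0.5, 0.5, 0.5),
)
img, landmarks, truth = build_phantom(spec)
frame = compute_head_frame(landmarks)

plan = mirrored_plan_sutures(landmarks, frame, "left")
disp = measure_suture_displacements(landmarks, plan, "left")
print("suture gaps (mm):", {k: round(v, 2) for k, v in disp.gaps_mm.items()})
print("suture sum (mm): ", round(disp.sum_mm, 2))

actual, affine = label_mask(img, "zygoma_L")
unaffected, _ = label_mask(img, "zygoma_R")
plan_mask = mirror_mask(unaffected, affine, frame)
sl = select_axial_slice(actual, affine, frame,
                        landmarks["zygoma_prominence_L"], landmarks, "left",
                        plan_mask=plan_mask)
di = deviation_index_result(sl)
print("deviation index:", round(di.DI, 2), "mm")

orb_a, _ = label_mask(img, "orbit_L")
orb_u, _ = label_mask(img, "orbit_R")
om = bilateral_orbit_metrics(orb_a, orb_u, affine, frame, "left", unit="cm3")
print("orbital volumes:", round(om.volume_affected, 2), "vs",
      round(om.volume_unaffected, 2), "cm3  (diff", round(om.volume_diff, 2), ")")
print("TZ angle diffs :", np.round(om.angle_diff_deg, 2))
```

Output:

```
suture gaps (mm): {'ZM': 3.74, 'ZF': 3.41, 'IO': 4.05, 'ZS': 2.91, 'ZT': 0.61}
suture sum (mm):  14.71
deviation index: 12.26 mm
orbital volumes: 17.31 vs 13.4 cm3  (diff 3.91 )
TZ angle diffs : [0.01 0.01 1.22]
```

The suture gaps are the per-suture distances from the displaced fragment to
the mirrored ideal (their sum is the 2D displacement score); the deviation
index aggregates the five ray-wise contour discrepancies on the prominence
slice; the bilateral volume difference recovers the 3.93 cm³ increment that
was injected (3.91 cm³ measured from the voxelised masks); and the
transition-zone angle differences are near zero because both cavities carry
the same 135° buttress dihedral.

## Command line

```bash
zmo simulate --out phantom/ --seed 7          # labels.nii.gz + landmarks + truth
zmo align    --landmarks phantom/landmarks.json --out frame.json
zmo zygoma   --mask-actual a.nii.gz --mask-plan p.nii.gz \
             --landmarks lm.json --frame frame.json --side left --out z.json
zmo orbit    --labels labels.nii.gz --label-affected 3 --label-unaffected 4 \
             --affected left --frame frame.json --out orbit.json
zmo stats    --pairs pairs.csv --out stats.json
zmo run      --config study.yaml --out report/   # full pipeline + CSV tables
```

The pipeline YAML schema is documented in `zmo/pipeline.py`; reports are
emitted as JSON plus CSV tables shaped like the clinical outcome tables
(per-suture columns ZM/ZF/IO/ZS/ZT/Sum and Z1P1…Z5P5/DI; orbit volume and
per-third angle columns).

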