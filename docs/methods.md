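# Methods

This note records the models, conventions and numerical choices behind the
package, including the points where the underlying clinical workflow leaves
the definition open and a convention had to be fixed.

## Coordinate conventions

World coordinates are RAS millimetres derived from the NIfTI affine; voxel
indices are 0-based. The head frame has x pointing right (midsagittal
normal), y anterior, z superior (FH normal). One fixed convention removes
silent left/right flips; functions that need an orientation decision fail
loudly (`OrientationError`) rather than guessing when landmark labels
contradict it.

## Head frame

The FH plane is the total-least-squares plane (SVD) through bilateral porion
and orbitale; the fit residual is reported on the frame (`fh_residual_mm`).
The superior sign is chosen so the upper-incisor tip lies below the plane.
The right axis is the porion L→R vector projected into the plane; anterior
completes the right-handed triple and is checked against the nasion.
Planning software aligns the "vertical midline" manually and does not state
which landmarks define it; here the midsagittal plane has the right axis as
normal and is anchored at the mean offset of the nasion and the porion
midpoint, which makes it deterministic, testable and exact for symmetric
inputs. Frame construction is rigid-equivariant to ~1e-6, which is what
makes the downstream metrics rigid-invariant.

Mirroring is reflection across the midsagittal plane: an exact isometric
involution on points; label masks are resampled back onto the source grid
with nearest-neighbour interpolation, so mirrored masks stay integral.
Landmark-based rigid alignment is orthogonal Procrustes (Kabsch) with the
proper-rotation determinant correction, returning the transform and RMSD;
registration verification applies the clinical rule distance < 1 mm
(configurable tolerance, strict inequality).

## Zygoma metrics

*Suture displacement* is defined as the distance between each actual
fragment-side suture landmark (ZM, ZF, IO, ZS, ZT) and its mirrored-plan
counterpart — not the fracture-gap width or step-off, which the workflow
does not define operationally. This choice makes pre- and postoperative
values directly comparable and sends a perfect reduction to exactly zero.

*Deviation index.* The measurement slice is parallel to the FH plane through
the zygomatic prominence (caller-supplied landmark; fallback: centroid of
the mask's widest axial cross-section — the slice is chosen visually in the
manual workflow). Contours are extracted by trilinear sampling of the mask
on a 0.25 mm in-plane grid, marching squares at the 0.5 level, and
resampling to ≤ 0.25 mm arc spacing. Point O is the intersection of the
arch-base line with the midline trace (x = 0 in frame coordinates). The
angle vertex for "evenly distributed by angle" is O itself; the five rays
sit at interior fractions k/6, k = 1..5, of the angular span from the
infraorbital foramen to the affected arch base, so the bounding landmarks
are not among Z1–Z5. Ray/contour intersection is exact segment intersection
with linear interpolation; Zk takes the outermost hit (the facial surface of
a shell contour), Pk the hit nearest Zk. DI is the plain sum of the five
Zk–Pk distances — the column arithmetic of the outcome tables resolves the
otherwise ambiguous phrase "discrepancy of the summation" in favour of a
sum, not a difference or ratio. Values are rounded to two decimals only at
the report layer.

## Orbit metrics

*Volume* is voxel count × voxel volume (optionally after a Euclidean-ball
binary closing emulating manual border fine-adjustment, default off).
Volumes are computed in mm³; the report layer converts to cm³, the scale at
which clinical orbital volumes (~25 cm³) and bilateral differences (~4 cm³)
are actually quoted, whatever unit label the table carries.

*Floor thirds.* The floor curve is the inferior boundary of the cavity in
the sagittal plane through the cavity centroid (the exact sagittal cut is
not specified in the manual workflow), traced per anterior-posterior column
with sub-voxel interpolation of the 0.5 crossing. Three points must both
"divide the floor in thirds" and label three regions, so the coronal planes
are placed at the centres of the thirds — arc fractions 1/6, 1/2, 5/6 from
the anterior end. Floors shorter than 3 voxels raise an error.

*Transition-zone angle.* In the coronal cross-section the boundary is
extracted at 0.25 mm, resampled, and smoothed with a ~2 mm circular moving
average to damp voxelisation staircase wiggles. Candidate corners are
boundary points in the inferomedial quadrant whose chord-probe interior
angle (2.5 mm arms) falls below 168°; among them the inferior-most is taken
(the point where the wall limb rejoins the smooth boundary can be equally
sharp) and refined to the local curvature maximum. A line is fitted (PCA) to
each limb over the 2–6 mm arc window on either side of the corner, and the
interior angle between the fitted directions is returned in (0, 180]. With
no candidate the boundary is declared flat: 180° with a warning. Known
limitation: a smooth arc of small radius (≲ 10 mm) in the inferomedial
quadrant is locally indistinguishable from an obtuse corner at the probe
scale, so genuinely tubular cavities may report an angle below 180 rather
than flat; the window and thresholds are configurable.

## Statistics

The Wilcoxon signed-rank test drops zero differences (classic behaviour;
the Pratt variant is switchable), mid-ranks ties, and computes the exact
two-sided p for effective n ≤ 25 by dynamic programming over the doubled
(hence integral) ranks — identical to enumerating all 2^n sign patterns.
Two-sided p doubles the smaller tail and caps at 1. Above n = 25 the normal
approximation is used with the tie-correct null variance Σr²/4 and no
continuity correction. Summaries are mean with min–max range; percentages
round to one decimal at the report layer.

## Synthetic phantom

The phantom generates the geometry the metrics consume, not CT intensities:

* **Zygoma shells**: thin spherical-shell patches (radius 56–59 mm) centred
  on the arch-base/midline intersection, azimuth sector 0–63°, |z| ≤ 12 mm.
  Centring the sphere on that intersection makes the axial contour a
  circular arc about point O, giving the ray construction a closed-form
  oracle.
* **Orbital cavities**: half-ellipsoids (semi-axes 17 × 24 × 24 mm, open
  anteriorly at a rim plane through the centre) cut by a floor plane and a
  medial-wall half-space whose cross-sections are self-similar, so every
  coronal section shows the same transition-zone corner with a prescribed
  dihedral angle (default 135°, per-third overrides per side). A fixed
  (non-self-similar) corner would fall outside the shrinking posterior
  sections and lose the angle there.
* **Landmarks**: porion, orbitale, nasion, incisor tip, infraorbital
  foramina, arch bases, prominences and the five sutures per side, placed
  analytically on the structures.

The unaffected side is the exact mirror of the affected side's
pre-displacement geometry, so identity displacement plus zero increment
yields a bilaterally symmetric phantom (measured mirror Dice = 1.0 on the
default grid). The affected fragment (shell, sutures, prominence) moves by a
rigid transform — rotation about a chosen axis through the prominence plus a
translation; the arch base and infraorbital foramen stay fixed, as they sit
on temporal/maxillary bone in this fracture model, which also keeps the
point-O construction stable. Ground-truth suture gaps are the analytic
displacements of the noiseless landmarks (captured before optional Gaussian
jitter), exact to 1e-9.

The volume increment scales the affected cavity about its centre by
s = ((V₀+ΔV)/V₀)^{1/3}, where the base volume V₀ is measured once on a fine
half-step-offset grid (≤ 0.5 mm); scaling makes the true increment exact, so
the only error in recovery is output-grid voxelisation. Default spacing is
1.0 mm isotropic (matching 1 mm CT slices); 0.5 mm is used where volume
accuracy within 2% is needed. Flat faces of the analytic shapes are kept off
the voxel-centre layers of the standard grids so they are not
half-counted — voxel-centre counting of a face lying exactly on a sample
layer is a degenerate alignment, not the generic case the accuracy claims
are about.

What the phantom does *not* emulate: CT intensities and segmentation noise,
comminution (the fragment is a single rigid piece), soft tissue, implant
hardware, and real orbital wall topography. Passing tests therefore validate
the measurement pipeline's geometry and statistics, not robustness to
segmentation quality. Structures are checked against the grid and against
each other at build time; simultaneous extremes (e.g. an ~11 cm³ increment
combined with a large medial fragment displacement) can make structures
collide, which raises a sizing error naming the structure rather than
silently merging labels.

## Pipeline and problem sizes

The pipeline derives one sub-seed per case/timepoint from the config seed
(kept below 2^31), collects per-case failures instead of aborting the run,
and records config hash, seed and package version in the report. Reports are
deterministic given config + seed (no timestamps), so reruns are
byte-identical. The test suite and the acceptance script run phantoms at
1 mm spacing (0.5 mm where volume or angle accuracy is the point) and an
eight-case pre/post cohort for the paired statistics — sizes chosen so the
whole validation runs in seconds while every tolerance is still meaningfully
exercised.
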