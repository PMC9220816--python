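# Methods

This note records the models, conventions and numerical choices behind
`epedetect`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic tests do and do not
demonstrate about real data.

## Geometry and conventions

All volumes share one axis convention: arrays are indexed `(x, y, z)`
with *x* the left–right axis, *y* posterior–anterior and *z* the slice
index. NIfTI files are reoriented to the closest RAS+ orientation on
load, and spacing is always taken from the header; voxel indices are
0-based and every physical length is computed in mm through the spacing.
Volumes carry a `kind` tag (`probability`, `intensity`, `mask`,
`labelmap`) whose invariants are enforced at construction, so invalid
inputs (a "probability" of 1.2, a non-binary mask, NaN voxels) fail
loudly at the boundary rather than corrupting downstream logic.
Alignment of co-registered volumes means identical shape and spacing
within 1e-6 mm; the package performs no resampling or registration.

## Intensity preprocessing

Histogram-landmark standardization follows the Nyul–Udupa scheme: for
each training image, intensities at a fixed set of percentiles are
computed (inside the prostate mask when provided, since the target of
normalization is the gland); the per-percentile means over the cohort
are the landmarks, and new images are mapped by the monotone
piecewise-linear function sending their own percentile values onto the
landmarks, with linear extrapolation beyond the outer knots. The
percentile set defaults to {1, 10, 20, ..., 90, 99} — deciles with
robust 1/99 endpoints, the method's common configuration; it is a
configuration parameter, not an inferred constant. Z-score
normalization uses the mean and *population* standard deviation of the
voxels inside the prostate mask and is applied to the whole grid;
population (rather than sample) std makes the operation exactly
idempotent and the unit tests exact. Constant images and empty or
zero-variance regions are rejected rather than silently propagated.

## The decision pipeline

* **Dilation** is 2D per axial slice with a symmetric square element of
  half-width `r` (full width `2r + 1`). The clinically motivated kernel
  is ~1.86 cm wide; an even-width square has no symmetric center, so the
  nearest symmetric element (65 px at 0.29 mm/px, `r = 32`) is the
  default and `r` is a parameter. A square element makes the dilation a
  separable maximum filter, which is applied exactly (verified against a
  brute-force Minkowski-sum oracle).
* **Thresholding** keeps voxels with `p > α` (strictly), so `α = 0`
  retains exactly the strictly positive support and `α = 1` clears the
  volume.
* **Connected components** use 26-connectivity on the voxel grid,
  deliberately ignoring spacing anisotropy (the standard choice for
  lesion-candidate extraction). Labeling is done with
  `scipy.ndimage.label` and a full 3×3×3 structuring element and is
  cross-checked against a breadth-first flood-fill oracle. Candidate
  ordering is size-descending with ties broken by smallest linear voxel
  index, so outputs are deterministic.
* **Rule II comparison** defaults to `TCL ≥ threshold`, with a strict
  variant available (`tcl_strict`); the inclusive form is the
  documented default.

### Contact-length measurement

The TCL of a candidate is measured per axial slice on the sub-pixel 0.5
iso-contour of the prostate mask: contour points whose distance to the
nearest candidate voxel center (bilinear sampling of a Euclidean
distance transform) is within 0.75 px are marked "in contact"; the slice
TCL is the arc length of the longest contiguous run of marked points,
and the candidate TCL is the maximum over slices. Three numerical
choices deserve explanation:

* **Per-slice maximum, not a 3D sum.** TCL is clinically an in-plane
  measurement, and the slice distance (3–5 mm) is an order of magnitude
  coarser than the pixel size, so summing across slices would produce a
  quantity dominated by slice count rather than capsule geometry.
* **Contact tolerance 0.75 px.** Marching-squares contour points sit on
  cell edges, exactly 0.5 px from the nearest voxel center across a
  binary boundary; 0.75 px covers this offset (and bilinear-sampling
  slack) without extending contact runs materially past the lesion. A
  larger tolerance of one pixel diagonal (√2 px) was evaluated and
  systematically overestimated arcs by ~2–3.5 px on phantoms with known
  geometry, so the tighter value is used.
* **Chord resampling of the run polyline.** The iso-contour of a binary
  mask is a staircase whose raw polyline length overestimates the smooth
  boundary length by ~5% (4.8% measured on a 50 px circle). Run length
  is therefore measured on the polyline resampled every 3 contour
  points, which recovers smooth arc length to ~0.4% while leaving
  genuinely straight runs exact.

With these choices the pipeline agrees with the phantom's analytic arc
oracle to within ±0.9 px across the tested geometries, comfortably
inside the 2 px discretization budget used by the end-to-end tests, and
a 35-pixel straight-edge contact is measured exactly (34 × 0.29 mm).
Mask slices with fewer than 3 boundary points contribute no contact; a
single contact point is a degenerate run of length 0.

### Monotonicity properties

Raising α shrinks the thresholded support, which can only shrink or
split components, never extend a contact run or create a capsule
crossing; hence patient-level predicted-positive sets are nested along
the α grid, and raising `TCL_th` never adds accepted candidates. Both
properties are asserted on phantom cohorts.

## Sextants

The grid — not just the gland — is partitioned into six regions, so that
extraprostatic prediction voxels (which lie outside the mask by
definition) remain attributable to a sextant. Zones depend only on the
slice index: with `n` prostate-bearing slices and `k = n // 3`, apex
takes the first `k`, mid `k` (plus one when `n mod 3 = 2`), base the
remainder; slices before/after the prostate span inherit apex/base. The
left/right boundary is the sagittal plane through the prostate centroid
x (robust to off-center glands; the image midline is available as an
option). The published sextant conventions do not pin down these
tie-breaks; the implemented rules are explicit, deterministic stand-ins
and are configurable.

## Evaluation

Patient-level: positive iff `Q ≠ 0` anywhere (ground truth: any EPE
label voxel). Sextant-level: positive iff `Q` (or the EPE labelmap) is
nonzero inside the region; cohort metrics pool sextant units across
patients (six per patient) before computing rates. Sensitivity or
specificity with a zero denominator is reported as absent (`None`),
never as 0 — small cohorts hit these edges routinely. ROC curves sweep
α over {0.00, 0.05, ..., 1.00}; AUC is the trapezoidal area over the
operating points augmented with (0,0) and (1,1) and sorted by FPR, which
is order-invariant and standard for threshold sweeps. The TCL grid
search runs one ROC sweep per threshold in
{2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0} mm (per fold when folds
are given) and tabulates mean AUC at both levels.

## Phantom generator

The phantom replaces the upstream neural network: the prostate is an
axis-aligned ellipsoid (voxel centers strictly inside), and each lesion
is a ball of radius `R` carrying the cosine-taper kernel
`peak · (1 + cos(πr/R)) / 2`. The taper was chosen because its
super-level set at any threshold α is again a ball with the closed-form
radius `r_α = (R/π)·arccos(2α/peak − 1)` — so the support the pipeline
sees after thresholding is analytically known, and the geometric
contact-arc oracle can be evaluated at any α (α = 0 gives the full
support). Per slice the capsule cross-section is an ellipse and a ball
cuts a single contiguous arc out of it; the oracle samples the ellipse
at 4096 points and takes the maximum arc over slices, mirroring the
pipeline's in-plane convention. Straddling lesions are placed by
bisecting the outward offset of the ball center along the capsule
normal until the oracle arc at the requested reference α matches the
target (the arc is maximal with the center on the capsule and decreases
monotonically outward). Noise is uniform on [0, amplitude], added and
clipped to [0, 1]; the default amplitude 0.05 exercises thresholding
without ever crossing the α = 0.30 operating point by itself. Ground
truth: cancer is the union of lesion supports; EPE is the extracapsular
part of straddling/exterior lesions, so `gt_epe ⊆ gt_cancer` and
`gt_epe ∩ L_pr = ∅` by construction.

Cohorts draw per-case geometry from a generator seeded by
`(cohort_seed, case_index)`, making each case reproducible independently
of cohort size. A case is EPE-positive with the requested prevalence;
positive cases carry 1–2 straddling lesions whose contact arcs are
prescribed at α = 0.25 — inside the recommended operating band — so
that detectability degrades gradually across the threshold sweep, as it
does for real lesions; negative cases carry 0–2 interior lesions.
Lesion size is drawn from the target arc and capped by the
periprostatic room on the grid, and lesion centers are snapped to the
nearest slice plane so the widest cut of the support is actually
sampled.

**What the phantoms do not emulate:** real MRI texture and
detector-specific failure modes (periprostatic structures that mimic
tumor, apex/base label truncation), non-spherical lesions that spread
along the capsule (real high-TCL tumors are sheet-like, phantom arcs
are bounded by ~2R), inter-scanner intensity variation, and microscopic
EPE below voxel resolution. Passing phantom tests therefore validates
the decision logic and its geometry — not the clinical accuracy of any
upstream detector.

## Problem sizes

Default parameters reproduce the study grid (224×224 in-plane at
0.29 mm, 3 mm slices; dilation half-width 32 px; α = 0.30;
`TCL_th` = 10 mm). The test suite and the acceptance script run the
same code on 128×128×10 grids at 0.5 mm in-plane with the dilation
radius scaled to the same physical margin (19 px ≈ 9.5 mm), 20-case
cohorts for sweep properties, and 160×160×16 grids for the largest
phantom lesions; these sizes were chosen so the full suite completes in
well under a minute while every geometric tolerance is still expressed
in physical units.

## Known limitations

* TCL is measured per slice; a lesion contacting the capsule obliquely
  across slices has no 3D surface-path length defined here.
* Whether dilation should act in 3D for thick-slice data is an open
  question; the 2D per-slice form matches the in-plane kernel
  definition.
* The sextant slice-allocation and side-split tie-breaks are this
  package's conventions; other implementations may bin boundary slices
  differently.
* Exterior lesions are rejected by Rule I even when they are true EPE
  disconnected from the intraprostatic tumor at the detector's
  threshold — an inherent property of the rule set, reproduced
  faithfully.
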