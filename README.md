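# epedetect

Rule-based detection and localization of **extraprostatic extension
(EPE)** — prostate cancer spreading beyond the capsular boundary — from
voxelwise cancer-probability maps on multiparametric MRI.

Deep-learning prostate-cancer detectors output a probability volume
`p_Ca(x, y, z)` over the whole image, but say nothing about whether a
lesion breaches the capsule. `epedetect` is the decision stage that turns
such a map, together with a binary prostate segmentation `L_pr`, into
localized EPE predictions using clinically motivated rules built around
the **tumor–capsule contact line length (TCL)**, an established
independent predictor of EPE. The package is model-agnostic: any
detector's probability map (or the bundled synthetic phantom generator)
can drive it.

## The pipeline

Given co-registered `p_Ca` and `L_pr` on one grid:

1. **Dilated search region** — `M_pr = dilate(L_pr)` per slice with a
   square structuring element (default half-width 32 px ≈ 9.3 mm at
   0.29 mm/px), because detector output far from the gland is unreliable;
2. **Masking** — `p = p_Ca ⊙ M_pr`;
3. **Binary threshold** — keep voxels with `p > α` (default α = 0.30,
   recommended range 0.30–0.35);
4. **Lesion candidates** — 3D 26-connected components `C(i)` of the
   thresholded volume `P_α`;
5. **Rule I** — a candidate must have voxels both inside and outside the
   prostate (`C(i) ∩ L_pr ≠ ∅` and `C(i) \ L_pr ≠ ∅`);
6. **Rule II** — its contact length `l_TCL(i)` along the capsule must
   reach the threshold `TCL_th` (default 10 mm).

Accepted candidates carry their thresholded probabilities into the final
EPE map `Q = Σ_i C(i) ⊙ P_α`. A patient is called EPE-positive iff `Q`
is nonzero anywhere; for spatial evaluation the prostate is divided into
six sextants ({apex, mid, base} × {left, right}, as in systematic 12-core
biopsy) and each sextant is scored by whether `Q` is nonzero inside it.
ROC curves are built by sweeping α over [0, 1] in steps of 0.05 at both
levels, and a grid-search harness tabulates AUC over
`TCL_th ∈ {2.5, 5.0, ..., 20.0} mm`.

The package also implements the upstream MRI intensity steps (Nyul-style
histogram-landmark standardization and prostate-region Z-scoring) and a
**phantom generator**: ellipsoidal prostates with ball-shaped lesions
carrying cosine-taper probability kernels, placed interior to, straddling,
or exterior to the capsule with an analytically controlled contact arc —
so every stage can be validated against closed-form geometry without
patient data or network weights.

## Worked example

```python
from epedetect import *
from epedetect.sextants import SEXTANT_NAMES

spec = PhantomSpec(
    shape=(128, 128, 10), spacing=(0.5, 0.5, 3.0),
    semi_axes_mm=(16.0, 13.0, 12.0),
    lesions=[LesionSpec(radius_mm=9.5, peak=0.9, placement="straddling",
                        target_contact_mm=11.0, contact_alpha=0.30,
                        direction_deg=0.0)],
    noise_amplitude=0.0, seed=1)
case = make_case(spec)

params = PipelineParams(alpha=0.30, tcl_threshold=10.0, dilation_radius=19)
q, candidates = detect_epe(case.p_ca, case.prostate, params)
for c in candidates:
    print(c.summary())
print("patient EPE call:", patient_call(q))
flags = region_flags(q, partition(case.prostate))
print("positive sextants:", [SEXTANT_NAMES[k] for k, v in flags.items() if v])
```

prints

```
{'voxel_count': 1116, 'inside_count': 396, 'outside_count': 720,
 'crosses_capsule': True, 'contact_length_mm': 11.208, 'accepted': True}
patient EPE call: True
positive sextants: [('mid', 'right'), ('base', 'right')]
```

The phantom lesion was constructed with an 11 mm contact arc at the
α = 0.30 operating point; the pipeline measures 11.2 mm on the voxelized
case (sub-pixel agreement), accepts the candidate under the 10 mm rule,
calls the patient EPE-positive, and localizes the extension to the two
right-sided sextants the lesion actually spans.

The same pipeline is available from the shell:

```sh
epedetect phantom --n 20 --prevalence 0.5 --seed 7 --out-dir cohort/
epedetect run --prob prob.nii.gz --prostate mask.nii.gz \
              --alpha 0.30 --tcl-th 10 --out epe.nii.gz --report lesions.json
epedetect roc --cohort cohort/manifest.csv --out roc.csv
```

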