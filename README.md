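# caliper

Automated measurement of the **callosal angle (CA)** from 3D T1-weighted MRI.

The callosal angle — the opening between the medial walls of the lateral
ventricles, measured on a coronal plane perpendicular to the AC–PC line at the
level of the posterior commissure (PC) — is a key imaging biomarker for normal
pressure hydrocephalus (NPH): angles below 90° suggest the disproportionate
ventricular enlargement typical of NPH. Manual measurement requires reslicing
the volume along the AC–PC axis and drawing the ventricle walls by hand, which
is slow and observer-dependent. `caliper` implements the geometric measurement
pipeline end-to-end, for neuroimaging researchers and method developers who
need reproducible CA values, its evaluation statistics, and a fully synthetic
phantom for validation without any patient data.

## The measurement

Given a volume and the anterior/posterior commissure landmarks (AC, PC):

1. **Preprocess** — reorient to RAS, resample into an isotropic 128³ cube
   preserving the aspect ratio (`scale_factor` mm per cube voxel), standardize
   intensities to zero mean / unit variance.
2. **Plane** — build the oblique coronal plane through PC with normal
   **n** = (AC − PC)/‖AC − PC‖, in-plane axes anchored to the subject
   left–right axis (columns) and the superior direction (rows increase
   inferiorly); extract a 224×224 slice.
3. **Ventricle geometry** — from a multiclass mask (background / left / right
   lateral ventricle; produced by any segmenter behind a simple contract),
   trace subpixel 0.5 iso-level contours of the two ventricles.
4. **Angle** — find the maximum-margin line separating the two contours (the
   perpendicular bisector of the shortest segment between their convex hulls,
   identical to the hard-margin SVM solution); cast perpendicular rays from it
   and record the first collision on each side (the medial walls); anchor a
   **base point** at each ventricle's most superior near-contact point; for
   each side find the direction through the base point that crosses the most
   wall points within a 1.5 px band (ties broken by minimal inlier RMS); the
   CA is the angle between the two inferior-oriented wall directions,

   θ = arccos(**d**_L · **d**_R),  classified *narrow* iff θ < 90°.

Landmark-localization metrics (Euclidean error, PCK@10, pitch angle),
segmentation metrics (Dice, Hausdorff), method-agreement statistics (MAE ± SD,
Bland–Altman bias and 95% limits of agreement, Pearson r), and the
plane-perturbation sensitivity experiment (PC shifts ±10 voxels, sagittal and
axial rotations ±10°, paired t-tests vs baseline) are included.

Trained landmark-detection and segmentation networks are *not* part of this
package; both enter through provider contracts (`LandmarkProvider`,
segmenter callables), with file-based providers and exact phantom providers
shipped.

## Worked example

Generate a synthetic wedge phantom with a known 112° angle, then measure it:

```bash
$ caliper phantom --apex 112 --seed 7 -o demo.nii.gz \
      --truth truth.json --mask-out demo_mask.png
$ caliper measure demo.nii.gz --landmarks demo.nii.gz.landmarks.json \
      --mask demo_mask.png -o result.json --plot overlay.png
[caliper] CA = 112.77 deg (wide)
```

`result.json` holds the angle (112.7675°, within 1° of the 112° ground
truth), the *wide* classification (≥ 90°), the resampling scale factor
(1.0 mm per cube voxel here), every geometric intermediate (separating line,
medial-wall points, base points, wall lines) and the effective configuration;
`overlay.png` renders them on the slice. The same objects are available from
Python:

```python
from caliper import PhantomSpec, make_wedge_slice, measure_ca

_, mask, _ = make_wedge_slice(PhantomSpec(apex_angle_deg=112, seed=7))
result = measure_ca(None, mask)
result.angle_deg        # 112.7675...
result.classification   # "wide"
```

Other subcommands: `caliper preprocess`, `caliper perturb` (sensitivity
experiment over a phantom cohort), `caliper evaluate` (agreement statistics
between two angle CSVs, with Bland–Altman and correlation plots), and
`caliper landmarks-eval`.

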