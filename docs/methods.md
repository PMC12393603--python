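# Methods

This note documents the measurement model, its numerical choices, the
synthetic phantom, and what validation on phantoms does and does not show.

## Coordinate conventions

World coordinates are millimetres RAS+ (x right, y anterior, z superior).
Voxel indices are 0-based and refer to voxel centers. After preprocessing, one
cube voxel equals `scale_factor` mm along every axis, and the padding offsets
make the cube ↔ source mapping exactly invertible. On the 2D slice, columns
run subject-left → subject-right and rows increase inferiorly; 2D points are
(x, y) with y growing downward, so "inferior-oriented" directions have
positive y components.

## Preprocessing

Volumes are reoriented to RAS by axis permutation/flip (an affine whose voxel
axes lie more than 45° from every canonical axis is refused rather than
silently resampled). The volume is then resampled trilinearly into an
isotropic cube, default edge 128: the largest physical extent maps to 128
voxels and the other axes are scaled by the same mm-per-voxel factor and
padded symmetrically with the volume minimum, preserving aspect ratio.
Intensity standardization (zero mean, unit variance) is computed over the
non-padded content box only, per volume, so background padding does not bias
the moments; the same affine map is applied everywhere, making the output a
monotone affine function of the input.

## Plane construction and slicing

The measurement plane passes through PC with unit normal pointing from PC to
AC. The in-plane column axis is the projection of the subject left–right axis
onto the plane (this fixes the roll, which the angle definition needs:
"vertical" in the slice is the superior direction); the row axis completes the
frame and is sign-fixed to point superior. The plane fails loudly when the
AC–PC line lies within 5° of the left–right axis, where roll is undefined.
Slices default to 224×224 pixels at 1 cube-voxel spacing, sampled trilinearly
for intensities and by nearest neighbour for labels; the slice center pixel is
`(size // 2, size // 2)`, which places pixel centers exactly on voxel centers
for axis-aligned planes.

Perturbations translate the origin along the baseline normal (positive =
anterior) and rotate the frame about the in-plane left–right axis (sagittal)
then about the rotated superior axis (axial), re-orthonormalizing afterwards.
At ≤10° the non-commutativity of the two rotations is below 0.02°, but the
order is fixed for reproducibility.

## Contours

Per class, the largest 8-connected component is kept (components under 5 px
are refused with a warning). The component indicator is smoothed with a
0.5 px Gaussian and the closed 0.5 iso-level contour is traced by marching
squares. The smoothing is deliberate anti-aliasing: for a straight edge the
0.5 level of the smoothed indicator sits exactly on the subpixel edge
position, so the staircase of the rasterized mask does not bias the wall-line
fit (without it we observed 1–3° bias at steep wall angles). 0.5 px is small
enough that corner rounding stays below ~1 px.

## The angle measurement

**Separating line.** The maximum-margin separator of two disjoint point sets
is the perpendicular bisector of the shortest segment between their convex
hulls; we compute it exactly that way (Shapely hulls + nearest points). This
is mathematically identical to the hard-margin linear SVM solution but
deterministic, free of solver tolerance, and exactly symmetric under
mirroring. When the contours touch or overlap slightly, a soft-margin linear
SVM fallback is used and flagged in the diagnostics; overlap beyond 20% of the
smaller hull area is an error.

**Medial walls.** Rays leave the separating line perpendicular to it, toward
each side, spaced `ray_step` (default 1 px) and centered on the midpoint of
the contours' projected extent (this centering makes the ray set exactly
mirror-symmetric for mirror-symmetric inputs). Per ray the first contour
intersection is kept. Two robustness rules: the local contour tangent is
estimated from a ±2-vertex chord (single marching-squares segments wiggle with
the pixel grid), and a first collision at grazing incidence (< 6° between ray
and tangent) invalidates the whole ray — tangential collisions are numerically
unstable and sample corner arcs rather than the wall. Fewer than 3 stable hits
on a side is an error.

**Base points.** Candidates are contour points within
`max(base_threshold, d_min + 1 px)` of the other contour (`d_min` = minimal
inter-contour distance; the guard guarantees candidates). The most superior
candidate is the base point, with two stabilizations: the contour polyline is
densified by per-segment subdivision (≈0.2 px, mirror-exact) so the selection
is not quantized to marching-squares vertices, and superiority is resolved
with a 2 px tolerance inside which the candidate *closest to the other
contour* wins. The base point is anatomically a point of near-contact of the
two ventricles below the corpus callosum; on discretized contours the literal
y-minimum rides rasterization artifacts along the ventricle roof, while the
closest-point rule locks onto the contact corner.

**Wall lines.** For each side, directions through the base point are scored
by the number of wall points within `wall_tol` (default 1.5 px) of the line.
The search combines a coarse sweep (`angular_step`, default 0.25°) with the
exact critical angles at which each wall point enters or leaves the tolerance
band, so the maximal count is exact (equal to an arbitrarily fine sweep). Ties
are broken by minimal RMS distance of the inliers — each winning inlier set is
also refined by the constrained least-squares direction through the base
(principal eigenvector of Σ rᵢrᵢᵀ) — then by the smaller angle from vertical.
Directions are oriented inferiorly. The callosal angle is
arccos(**d**_L·**d**_R) in degrees; exactly 90° classifies as *wide* (narrow
is strict <, consistent with the strict-inequality reading used for PCK@10).

## Evaluation statistics

Landmark error is the per-landmark 3D Euclidean distance (mm in the world
frame when available). PCK@10 counts a landmark correct iff its error is
strictly below 10% of the ground-truth AC–PC distance (scale-invariant by
construction). The pitch angle between two AC–PC lines is undirected, in
[0°, 90°]. Dice is 2|A∩B|/(|A|+|B|) per class, with empty-vs-empty defined as
1.0 and empty-vs-nonempty as 0.0; Hausdorff is the symmetric
max-of-directed-sup-inf distance on boundary point sets, multiplied by pixel
spacing when known. Agreement statistics use differences predicted − manual:
MAE with the SD (ddof = 1) of absolute errors, Bland–Altman bias ± 1.96·SD
limits of agreement (the standard normal multiplier, not a t quantile), and
Pearson r with its t-transform p-value. The paired t-test for the
perturbation experiment is the classic paired t on differences (scipy's
implementation; degenerate zero-variance differences raise).

## The synthetic phantom

The phantom emulates only the geometry the measurement depends on, not MR
contrast. Each "ventricle" is a wedge whose medial wall descends from a blunt
superomedial corner at half the apex angle from vertical; the two corners sit
`gap` apart (default 6 px) and the ground-truth CA at the PC plane equals the
apex angle exactly, with analytic wall lines returned alongside. Shape
details follow coronal ventricle anatomy closely enough to avoid rasterization
degeneracies: the roof slopes down laterally at 15° (so the superomedial
corner is the unique most superior point, as under the corpus callosum), the
floor rises laterally at 15° from the wall's bottom corner (trigone-like; no
near-horizontal surface can be poked by rays), and the corner carries a 3 px
flat cap (infinitely sharp tips rasterize unstably). The apex sits ~45 voxels
above the PC plane, as ventricle bodies sit well superior to the AC–PC line.

In 3D the wedge is extruded along the anterior–posterior axis with two
anatomical-variation terms: the apex angle drifts linearly with the anterior
offset (`angle_slope_deg_per_voxel`, default 2.0, cohort draws 1.5–2.5) and
the walls acquire an antisymmetric twist (`wall_twist_deg_per_voxel`, default
0.7, draws 0.5–0.9). A uniform extrusion would be blind to PC shifts and, by
left–right symmetry, to axial rotations; the chosen rates reproduce the
plane-misplacement sensitivities reported for clinical material (roughly
10°/20° of CA error at 5/10 voxels of PC shift, 4–9° at 5–10° sagittal
rotation, 3–6° at 5–10° axial rotation). Wall half-angles saturate at
[12°, 78°] so geometry stays valid over the ±30-voxel extrusion. AC sits
26 voxels anterior of PC (a typical commissural distance, making PCK@10
thresholds realistic). Optional global tilt rotates volume and landmarks
jointly; labels are rasterized analytically on the rotated grid, so tilting
adds no resampling artifacts. Intensity is the smoothed shape indicator plus
Gaussian noise; all randomness sits behind one seed.

The phantom segmenter evaluates the analytic membership on any requested
plane (exact masks); a label-volume reslicing segmenter and file-based
segmenters are also provided.

**What phantom validation shows and does not show.** Passing phantom suites
demonstrates the geometric pipeline is correct, stable under mirroring, rigid
rotation, and discretization refinement, and recovers known angles within
~1.5° at 224² resolution. It does not exercise MR contrast, segmentation
errors, anatomical wall curvature, asymmetric or disconnected ventricles, or
landmark-detection error — on real data those enter through the providers and
dominate the error budget.

## Problem sizes

Validation suites use 224² slices and 128³ volumes: 135 end-to-end runs for
the robustness grid (5 apex angles × 3 tilts × 3 noise levels × 3 geometry
draws), 20-phantom cohorts with 61 measurements each for the sensitivity
experiment, and 25-instance oracle batteries for the separator and wall-fit
primitives. These sizes keep full validation in minutes on one CPU while
leaving the statistical checks well-powered.

## Known limitations

- Ventricle masks must have exactly one dominant component per side; severely
  disconnected segmentations are refused rather than guessed at.
- The base-point rule assumes the ventricles approach each other below the
  corpus callosum; pathologies that fuse or widely separate the ventricles
  (> `base_threshold`, guarded by d_min + 1) shift the anchor.
- The soft-margin fallback for touching ventricles is approximate; its margin
  is reported as the worst-case correctly-classified distance and flagged.
- Angles are reported in the resampled cube frame; anisotropy of the original
  acquisition is handled by the isotropic resampling, not modelled in-plane.
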