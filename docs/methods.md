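# Methods

## Coordinate conventions

All computation happens in LPS physical coordinates (+x patient Left,
+y Posterior, +z Superior), in millimetres. Voxel indices are 0-based
and voxel **centers** map to physical points through

    physical(i, j, k) = origin + direction · (spacing ⊙ (i, j, k)),

the single geometric contract every module shares. Volumes read from
disk in other orientations (e.g. RAS) are reoriented on load by pure
index permutation/flips — never interpolation — and oblique volumes
(direction more than a configurable tolerance off axis-aligned,
default 1°) are rejected with advice to resample first. Angle
conventions: yaw is a right-handed rotation about +z (axial plane),
pitch about +x (sagittal), roll about +y (coronal); a composite
R = R_roll·R_pitch·R_yaw means yaw is applied first.

## The alignment model

The method assumes three point landmarks, pairwise > 1 mm apart and
non-collinear (nasal bridge > 1 mm off the inter-cochlear line), with
the left cochlea at larger x than the right and the nasal bridge
anterior to the inter-cochlear midpoint. These are validated on every
`LandmarkSet` construction, so degenerate anatomy fails loudly at the
boundary rather than producing a silent 180° flip. Rotation center is
the inter-cochlear midpoint — the sources describing this procedure
leave the center unspecified, and the midpoint keeps the structure of
interest fixed and makes yaw/roll symmetric about it. No translation
is applied.

**Sequential mode** (the default, mirroring the three-panel clinical
description): yaw solved on the input landmarks, pitch on the
yaw-rotated set, roll on the pitch-rotated set; each solver picks the
|angle| ≤ 90° branch, which preserves anatomical orientation. The
composite is applied to the image in one resampling pass. Two exact
residual laws characterize what this leaves behind:

* final cochlear y deviation = |Δz after yaw| · |sin(pitch)| — pitch
  re-tilts the yaw-aligned cochlear axis;
* final nasal-bridge z deviation — roll, applied last about y, moves
  the right cochlea (which sits off the roll axis) more than the nasal
  bridge (which sits near it).

Both are sub-voxel at clinical tilts (≲ 10–15° per plane) and grow
with the applied misalignment; the test suite asserts the y law to
1e-9 mm and uses the sum of the two corresponding small angles as the
exact bound on the geodesic distance between sequential and exact
rotations.

**Exact mode**: build e1 = unit(l − r), e2 = unit component of
(n − r) ⊥ e1, e3 = e1 × e2, and return the proper rotation taking
(e1, e2, e3) to ((1,0,0), (0,−1,0), (0,0,−1)). This satisfies all
three alignment constraints to machine precision, is equivariant under
rigid motions (so recovery of a known misalignment is exact), and
serves as the oracle for sequential mode. It is exposed as an optional
"perfect" variant.

**Resampling.** Exactly one interpolation per aligned volume: linear
for images, nearest-neighbour for label maps (label values stay in
{0,1} through every stage). With `expand_z` the output grid grows
craniocaudally, in whole voxels, until every rotated corner of the
input extent is covered; the x–y extent is left untouched and new
voxels are filled with air (−1024 HU). Out-of-extent fill defaults:
−1024 for images, 0 for labels.

**Decomposition.** Residual rotations are split back into
(yaw, pitch, roll) by closed-form extraction from R = R_y R_x R_z
(sin pitch = −R[1,2], etc.), rejecting gimbal-adjacent cases
(|pitch| → 90°), which lie far outside the supported ±45° envelope.
An optional constant sagittal offset (bounded to ±15°) lets users tilt
the final result toward the true AC-PC plane, which the
cochlea/nasal-bridge plane approaches but does not equal (≈ 5° off on
average in clinical data); it is a pass-through convenience, not a
validated correction.

## Landmark extraction

A landmark point is the unweighted mean physical position of the
foreground voxels of the **largest 26-connected component** of its
binary label. Largest-component selection guards against speckle in
predicted labels; the mean commutes with the affine index→physical map,
so COM is computed in index space and mapped once. Empty labels raise
`LandmarkNotFoundError` — the machine analogue of absent or destroyed
anatomy (the known clinical failure modes: infant skulls, extensive
fractures, labyrinthectomy). Training-style labels are spheres of
**10 mm diameter** ("1 cm sphere" is read as naming the diameter);
a voxel is foreground iff its center lies within the radius.

The phantom oracle detector thresholds midway between skull and
landmark-sphere intensity, requires exactly three components, and
assigns anatomy geometrically: the closest pair are the cochleas
(~60 mm apart, versus ~85 mm from either cochlea to the nasal bridge),
right/left by x order — an assignment stable under the full ±45°
misalignment envelope of the phantom geometry.

A segmentation-network path (per-landmark 3D U-Net: 5 levels,
16→256 channels, stride-2 downsampling, 2 residual units, Dice loss,
Adam at 1e-4, early stop after 50 stagnant epochs, 90/10 train/val
split, one ±45°-rotated augmentation copy per case, inputs at 1.5 mm
isotropic normalized to [0,1]) is the intended route for real CT data
but is **not shipped**: no deep-learning runtime is among this
package's dependencies, and every geometric claim the package makes is
network-independent by design — the oracle detector exercises the same
COM-based interface. Reproducing clinical segmentation accuracy is
out of scope.

## The synthetic phantom

The phantom is schematic on purpose: an ellipsoidal soft-tissue head
(semi-axes 70 × 88 × 60 mm) with a bony shell, a small bony ridge at
the nasal bridge, and three high-density spheres (radius 5 mm,
2000 HU — above bone, so thresholding is trivial) at the landmark
points. Only geometry matters to the algorithm under test; realistic
CT texture, noise, beam hardening and pediatric anatomy are
deliberately absent, so passing tests demonstrate geometric
correctness of the alignment machinery, not detection robustness on
real tissue contrast.

Defaults: 128³ voxels at 1.5 mm isotropic (the working resolution of
the downsampled prediction grid; the grid is sized so landmark spheres
survive worst-case 45°/45°/45° rotations without clipping), cochlear
separation 60 mm, nasal bridge 80 mm anterior **on** the cochlear
axial plane — the canonical pose already satisfies the alignment
target, so recovery of an applied misalignment Q is exactly Qᵀ, and
intensities air/tissue/bone = −1024/40/700 HU. A seed-driven jitter
(default ±2 mm, uniform) shifts the cochlear pair jointly (their
separation stays exact by construction) and the nasal bridge
independently, giving per-subject variety. Landmark points are
propagated **analytically** through every transform; image-derived
COMs are used only when detection itself is under test, separating
algorithm error from discretization error. Applied misalignments are
drawn uniformly per plane on [−45°, +45°], the envelope the method is
specified to handle.

## Evaluation and statistics

Skull-base quality is the pair |y_l − y_r|, |z_l − z_r| of the
transformed cochlear points (perfect alignment = 0,0). Whole-head
quality on phantoms is the residual rotation (recovered ∘ applied)
decomposed per plane; reporting preserves the clinical convention —
clockwise positive, rounded to whole degrees half away from zero — so
phantom numbers are unit-compatible with manual review.

Cohort comparisons use the two-sided Wilcoxon signed-rank test on
**absolute** deviations (signed clockwise/counter-clockwise errors
cancel in means), dropping zero differences per the classical
convention; identical paired samples are treated as a degenerate-test
error rather than p = 1. A Shapiro–Wilk gate (α = 0.05) documents the
non-normality that motivates the nonparametric choice. ICC(1,k) —
one-way random effects, average of k raters, absolute agreement — is
implemented directly from the ANOVA mean squares,
ICC = (MS_B − MS_W)/MS_B, with the standard F-based 95% CI
(lower 1 − 1/(F/F₁₋α/₂), upper 1 − 1/(F·F'₁₋α/₂)); the test suite
checks it against brute-force ANOVA to 1e-10 and against an
independent reference implementation to 1e-6. Summary tables report
mean / median / sample SD (n−1) / range of absolute deviations per
condition plus the paired p-value.

## Problem sizes and numerical tolerances

Analytic contracts (solver post-conditions, residual laws, rigidity,
decomposition round-trips) are asserted at 1e-9 mm/deg; rotation
matrices at 1e-12; voxel-level contracts at half a coarse-voxel
diagonal (0.75 mm at 1.5 mm spacing) or one voxel diagonal where two
resampling passes are involved. Cohort sizes in the test suite —
100 phantoms for the perfect-alignment property, 50 for rotation
recovery, 20 for the single-interpolation comparison, 1000 analytic
geometries for the residual law — were chosen as the smallest cohorts
that exercise the full misalignment envelope with stable statistics.

## Known limitations

* The sequential (default) mode's residuals grow with tilt; heads
  rotated tens of degrees are better served by `mode="exact"`.
* No translation or scaling: the output shares the input's origin and
  physical dimensions by design; template registration is out of scope
  (an externally produced transform can be compared via the same
  deviation metrics).
* The oracle detector only applies to phantoms; real CTs need labels
  from a human or a trained network.
* DICOM support is read-only, single series, uniform spacing.
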