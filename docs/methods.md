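# Methods

This note documents the models, parameter choices and numerical conventions
behind `navphantom`, and what the synthetic phantom does and does not
emulate.

## Coordinate frames

Four tagged frames are modelled. The reference image coordinate system
(RICS) is right-handed RAS in millimetres; the analysis frame (ACS) is
identified with it. The virtual platform's frame (VCS) is left-handed and
in centimetres; an intermediate right-handed frame (IVCS) precedes the
handedness flip. The forward engineering matrix is FEM = U·R_pos with
U = diag(0.1) (mm→cm) and R_pos a rotation about the superior axis — 0°
supine, 180° prone, ±90° lateral. The scale is folded into one matrix
rather than kept as a separate unit step, and the reverse engineering
matrix is the exact matrix inverse of the FEM rather than a re-derivation,
so REM∘FEM is the identity to machine precision by construction.

Two conventions were genuinely open and are exposed as configuration rather
than hard-coded: which lateral side maps to +90° (default: left-lateral
= +90°, switchable via `lateral_sign=-1`), and the exact axis
correspondence of the virtual frame (the handedness flip is applied to the
third axis, the conventional choice for left-handed graphics frames).
Transforms refuse point sets whose frame or unit tags do not match; there
is no silent unit coercion anywhere.

## Rigid registration

The optimal rigid map from the ground-truth set C to the perceived physical
set P minimizes Σ‖R·C_i + t − P_i‖² over proper rotations and translations.
It is solved in closed form: demean both sets, take the SVD of the
cross-covariance H = Ĉᵀ P̂, and correct the sign of the smallest singular
direction so det(R) = +1 — rigid-body mode, no scaling, no reflection.
Correspondence is strictly by marker label order; there is no point
matching or ICP. At least three markers are required and collinear
configurations are rejected (the rotation about the common axis would be
unidentifiable); study-style cases have 6–7 markers. Tests cross-check the
closed form against an independent numerical least-squares optimizer over
an axis-angle + translation parameterization and against
`scipy`'s `Rotation.align_vectors`.

## Landmark metrics

FLE, TRE and FRE are per-marker displacement *vectors* with their Euclidean
norms; case summaries report mean ± sample SD (ddof = 1) of the norms, kept
at full precision internally and rounded to 0.1 mm only for display. FN is
the Frobenius norm of (T\* − I) over all 16 entries of the homogeneous
matrix, exactly as defined — it deliberately mixes dimensionless rotation
residuals with millimetre translation entries. Because that mixing hampers
interpretation, `decompose_fn` optionally splits it into the
rotation-block and translation-column norms (FN² is exactly their sum of
squares); the decomposition is an interpretive extra and is off by default.
The pipeline records that the virtual set V is probed before the physical
set P (`acquisition_order`), since FLE's role as a quality-control baseline
depends on that ordering.

## Lesion metrics

The transformed model TM is obtained by applying T\* to the ground-truth
mask and resampling back onto its own voxel grid by inverse mapping with
nearest-neighbour interpolation — binary masks must stay binary. This
accepts a discretization error of up to one voxel; HD95 values near the
grid spacing (1 mm by default) should be read with that quantization in
mind.

DSC is computed on voxel sets of a shared grid. HD95 is *directed* by
default: for every ground-truth surface point, the distance to the nearest
TM surface point, reduced to the maximum of the smallest 95 % of the
distance multiset. With n distances this is the ⌈0.95 n⌉-th order
statistic, not an interpolated percentile: "the maximum of the first 95 %"
is an element of the multiset, and the constructed example (95 distances of
1 mm, 5 of 10 mm) must yield exactly 1 mm, which interpolation between
order statistics would not. Many segmentation-comparison tools report a
symmetric variant; `symmetric=True` takes the maximum of both directions.
Surfaces are the centers of boundary voxels — foreground voxels with at
least one background 6-neighbour — in physical millimetres.

Lesion depth is the minimum radius of a sphere centered at the lesion
centroid and tangential to the skin mesh, computed as the exact
point-to-triangle distance over all faces (vertex-only distances would
overestimate on coarse meshes). The L2 norm is the centroid's distance to
the image origin. Both are reported in centimetres, volume in cm³ —
matching the units such studies tabulate.

## Synthetic phantom generator

The generator defines the study conditions under which everything is
tested; it emulates the *statistical structure* of a 19-case phantom
cohort, not its anatomy.

* **Head**: a triangulated ellipsoid with semi-axes 80 × 95 × 85 mm — the
  scale of an adult head. A user-supplied STL mesh can be substituted. The
  head center sits at (10, 25, 70) mm, deliberately offset ~75 mm from the
  image origin: in real reference scans the head is far from the RAS
  origin (tabulated lesion L2 norms run around 8 cm), and the offset is
  what couples the misregistration rotation into the translation column of
  the fitted transform, as happens in practice.
* **Fiducials**: 6–7 markers placed exactly on the analytic ellipsoid, on
  its anterior/superior aspect (where adhesive markers go), with ≥ 25 mm
  pairwise separation.
* **Lesions**: axis-aligned ellipsoids (mild random anisotropy) voxelized
  on a 1 mm isotropic grid with a 12 mm background margin, volumes drawn
  uniformly from 8–38 cm³ by default, placed strictly inside the head.
  Two of the 19 cohort cases carry two lesions, giving 21 lesions in 19
  cases.
* **Noise model**: V = C + ε, P = T_err(C) + ε′ with ε, ε′ isotropic
  Gaussian per coordinate (σ_probe), and T_err a small rotation about a
  uniformly random axis through the head center (angle ~ N(0, rot_sigma))
  composed with a per-axis Gaussian translation (trans_sigma).

The defaults σ_probe = 1.2 mm, rot_sigma = 1.5°, trans_sigma = 1.0 mm are
calibrations, not claims about any platform's physical error mechanism:
σ_probe is set from the closed-form Maxwell mean of a 3-D Gaussian norm,
2σ√(2/π) ≈ 1.91 mm, to land FLE near the ~1.9 mm scale such studies
report, and the misregistration sigmas follow from a small-angle lever-arm
estimate that puts TRE near ~3 mm. Determinism is bit-for-bit: one master
seed fixes a cohort, with per-case seeds derived by fixed arithmetic.

What the generator does *not* emulate: real scalp geometry and curvature
(so position-dependent registration difficulty — e.g. flatter occipital
surfaces in prone cases — does not arise; simulated position groups differ
only by sampling noise), heavy-tailed or anisotropic probe errors, marker
or skin shift, and the long-tailed lesion-volume distribution of a clinical
cohort. A consequence worth knowing: in the uncontrolled synthetic cohort
the DSC spread is dominated by the per-case misregistration draw, so the
DSC–volume correlation is weak there; the positive association appears
cleanly in the controlled simulation that holds the misregistration
magnitude fixed across a 21-lesion volume ladder
(`dsc_volume_simulation`), which is the designed test of that mechanism.
Passing tests therefore demonstrate the correctness of the metric and
statistics chain under a known noise family — not the field accuracy of
any navigation device.

## Statistics

Non-parametric throughout, mirroring small-cohort practice: Kruskal–Wallis
omnibus across position groups (supine/prone/lateral, the two lateral
sides pooled), all-pairs Mann–Whitney U post hocs at the
Bonferroni-adjusted alpha 0.05/k (k = 3 pairs → 0.017), two-sided
everywhere. Mann–Whitney p-values use the exact null distribution when the
combined sample is ≤ 20 and tie-free (the study-scale group sizes), and
the tie-corrected normal approximation otherwise. Spearman correlations
use tie-corrected ranks. Median splits assign ties to the ≤ median group.
Sample SDs use n − 1. Degenerate inputs raise informative errors at the
function level (constant vectors, undersized groups); the cohort report
catches these and records the corresponding cells as NaN so that, e.g., a
zero-noise validation run (all DSC = 1) still completes.

## Problem sizes and numerics

Default analyses are sized for interactive use: a 19-case cohort generates
and evaluates in a few seconds; the acceptance sweep uses 200 zero-noise
replicates for misregistration recovery (every matrix entry reproduced to
1e-9) and 10,000 draws for the Maxwell check (sample mean within 5 %).
Frame round-trips are exact to 1e-9 mm; rigid-fit orthogonality is enforced
to 1e-9; voxel-level lesion operations are exact set arithmetic. Transform
files are plain-text 4 × 4 matrices with JSON sidecars; every pipeline run
writes its fully resolved configuration and a hash of the scientific
parameters (paths excluded) next to its outputs, and rerunning the same
configuration reproduces the deterministic outputs byte for byte.

## Known limitations

* HD95 inherits a one-voxel quantization from nearest-neighbour mask
  resampling.
* The ellipsoidal head makes lesion depth slightly larger on average than
  clinical tables suggest (lesions are placed uniformly in the interior,
  not preferentially cortical).
* FN's mm/radian mixing means its absolute scale depends on where the
  rotation center sits relative to the image origin; compare FN values
  only within a fixed frame convention.
* The FCSV reader supports the markups-fiducial dialect's coordinate
  conventions (RAS/LPS) but not its full schema (orientation quaternions
  are ignored).
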