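# navphantom

Registration-accuracy evaluation for mixed-reality (holographic)
neuronavigation, driven entirely by synthetic head phantoms.

## The problem

Head-mounted-display navigation systems overlay holographic anatomy on the
physical patient. Validating such a system on 3D-printed head phantoms
produces, per case, three ordered scalp-fiducial point sets in the reference
image coordinate system (RAS, mm):

* **C** — ground-truth marker centroids segmented from the reference scan,
* **V** — the perceived *virtual* marker centers, probed on the hologram,
* **P** — the perceived *physical* marker centers, probed on the phantom,

plus a lesion segmentation and a skin surface mesh. `navphantom` implements
the full evaluation chain for this kind of study — and, because such
phantom measurements are rarely shared, ships a synthetic-phantom generator
so the entire analysis runs with no external data. It is a library for
people who build or assess image-guided-surgery systems: everything is
importable from Python, `examples/` holds one narrative script per
capability, and a thin `navphantom` CLI wraps the common pipeline stages.

## What it computes

**Frames.** Holographic platforms work in a centimetre, left-handed virtual
frame, re-oriented per surgical position (supine 0°, prone 180°, lateral
±90° about the superior axis). The forward engineering matrix
FEM = U·R_pos (U = uniform 0.1 scale), the handedness conversion matrix
HCM = diag(1, 1, −1, 1) and the reverse engineering matrix REM = FEM⁻¹ link
the image frame to the virtual frame and back; every transform carries
frame/unit tags that are checked at application.

**Landmark metrics** (mm, in the analysis frame):

* FLE_i = V_i − C_i — fiducial localization error (probe/perception noise),
* TRE_i = P_i − C_i — target registration error (alignment accuracy),
* T\* = argmin_{R,t} Σ‖R·C_i + t − P_i‖² — the optimal rigid transform,
  solved in closed form (Kabsch/Umeyama: demeaning, cross-covariance SVD,
  determinant sign correction; no scaling, no reflection),
* FRE_i = R\*·C_i + t\* − P_i — fiducial registration error,
* FN = ‖T\* − I‖_F — Frobenius-norm size of the fitted misregistration.

**Lesion metrics.** T\* applied to the ground-truth mask GT gives the
transformed model TM (nearest-neighbour resampling on GT's grid). Then
DSC = 2|GT∩TM| / (|GT|+|TM|) and the directed 95th-percentile Hausdorff
distance HD95 = max of the smallest 95 % of GT-surface-to-nearest-TM-surface
distances (surface = boundary voxels under 6-connectivity, distances in
physical mm; a `symmetric=True` variant takes the max of both directions).
Per lesion, the characteristics volume (cm³), depth (minimum
centroid-to-skin-mesh distance, cm) and L2 norm (centroid to image origin,
cm) are reported.

**Cohort statistics.** Kruskal–Wallis across surgical positions,
Mann–Whitney U post hocs at the Bonferroni-adjusted alpha (0.05/3 = 0.017),
tie-corrected Spearman correlations of DSC/HD95 with the lesion
characteristics, and median-split subgroup comparisons.

## Worked example

```sh
python examples/02_landmark_registration.py
```

```text
case case_01: 7 markers, position supine
FLE  1.6 ± 0.7 mm   (probe/perception error)
TRE  3.3 ± 0.9 mm   (alignment error at markers)
FRE  1.3 ± 0.4 mm   (residual after rigid re-fit)
FN   3.9          (||T* - I||_F, mixes mm and rad)
```

The case was generated with the calibrated noise model (probe noise
σ = 1.2 mm per coordinate; misregistration rotation σ = 1.5°, translation
σ = 1 mm per axis): FLE sits near the Maxwell mean 2σ√(2/π) ≈ 1.9 mm, TRE
adds the rigid misregistration on top, and FRE is smaller than TRE because
the optimal re-fit removes the rigid part and leaves only probe noise.
`examples/04_cohort_report.py` runs the full 19-case cohort (8 supine /
6 prone / 5 lateral, 21 lesions) and prints the grouped summary tables with
their Kruskal–Wallis p-values, e.g.

```text
  group  n  fle_mean  fle_sd  tre_mean  tre_sd  fre_mean  fre_sd  fn_mean  fn_sd
overall 19      1.85    0.26      2.74    0.69      1.41    0.30     2.45   0.99
```

and the controlled equal-misregistration simulation behind the volume–DSC
association: `Spearman rho(DSC, volume) = 0.842 (p = 1.7e-06)` — at a fixed
boundary displacement, larger lesions keep a larger fraction of their
overlap.

The same pipeline is scriptable from a shell:

```sh
navphantom report --seed 1 --n 19 --mix 8,6,5 --out run/
navphantom simulate --n 1 --mix 1,0,0 --seed 2 --out cases/
navphantom evaluate landmarks --case cases/case_01
```

## Layout

```
src/navphantom/   frames, registration, landmarks, lesions, phantom,
                  tables, stats, io, pipeline, plots, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, calibrations, numerical choices, limitations
```
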