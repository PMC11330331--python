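# Methods

This note documents the models, conventions and numerical choices behind
`prepscore`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Meshes and units

STL files carry no units; the package assumes millimetres throughout,
because every clinical threshold it applies (0.25 mm error unit, 1.50 mm
ideal depth, 1.25 mm ideal width) is metric and dental CAD/CAM scanners
export metric geometry. On load, duplicated facet corners are welded
(tolerance 1e-6 mm) so that faces index a shared vertex list — vertex masks
and the deviation map require shared indices.

Closest-point queries are point-to-*surface*: the exact global minimum
point-to-triangle distance. A KD-tree over triangle centroids yields an
upper bound (the exact distance to the nearest centroid's triangle); every
triangle that could contain a closer point must have its centroid within
`bound + max circumradius` of the query, so a ball query gives a provably
sufficient candidate set and the accelerated result equals the exhaustive
minimum — this equality is asserted against a brute-force oracle in the
test suite. Vertex-only distances were rejected because they overestimate
deviations on coarse meshes.

## Rigid alignment

Point-to-point ICP with the SVD (Kabsch) closed-form update; the
reflection case is corrected by flipping the smallest singular vector, so
the rotation is always proper. Correspondences run from the included
prepared vertices into the reference surface only: the cavity is a hole in
the prepared tooth, so reference→prepared correspondences across the
cavity would be meaningless. The occlusal exclusion region is
user-configured (axis-aligned box or vertical cylinder in reference
coordinates) rather than auto-detected; automatic cavity detection before
alignment is a chicken-and-egg problem the package deliberately avoids.

Parameters and defaults:

| parameter | default | rationale |
|---|---|---|
| `max_iterations` | 100 | linear convergence; 100 steps reduce the pose error well below scan resolution on the standard fixtures |
| `mse_rel_tolerance` | 1e-6 | stop when the MSE plateaus (noisy scans) |
| `mse_abs_tolerance` | 1e-10 mm² | stop at sub-micrometre RMS; with identical noise-free surfaces the MSE decays geometrically toward zero and a relative test alone never fires |
| `trim_fraction` | 0 (off) | exact correspondences need no trimming; ~0.1 recommended for noisy scans |
| `pre_align` | none | scanner pose is trusted; `centroid` / `principal_axes` available for coarsely posed inputs |

The per-iteration mean squared closest-surface distance is non-increasing
for untrimmed point-to-point ICP (each correspondence update and each
Kabsch step can only lower it); with trimming the same argument applies to
the trimmed set, and both monotonicities are asserted in the tests. The
documented capture range on the standard fixture is roughly 10° / 1 mm;
larger perturbations may converge to a wrong pose but still return a
finite, monotone result.

## Deviation map and the seven readings

Signed deviation = closest-surface distance, with the sign taken from the
nearest reference face normal: positive below the surface (material
removed), negative above. Reference meshes are expected to have outward
(occlusally upward) normals, which the STL winding convention provides.

All probe geometry lives in an explicit `LandmarkConfig` in the reference
frame — the package never guesses where mesial/middle/distal are, because
reproducibility and auditability beat heuristics for an assessment tool.
Lateral distances for depth probes and ridge segments are measured
perpendicular to the configured occlusal axis (default +z), so a probe's
height never affects which vertices it captures; this is what makes the
same landmark set valid for under- and over-deep preps.

* **Depth** = median deviation within the probe radius (default 0.25 mm).
  The median resists mesh noise; a single nearest vertex does not.
* **Cavity footprint threshold** 0.5 mm (configurable): separates
  intentional preparation from scan noise when delimiting the cavity set.
* **Isthmus width** = spread of the cavity-set vertices' projections on the
  plane's width axis, within a slab of half-width 0.2 mm (enough vertices
  at ≥ 4 vertices/mm resolution).
* **Ridge remaining** = distance along the segment (projected to the
  occlusal plane) from the proximal endpoint to the nearest cavity vertex;
  the full segment length if the cavity never reaches it. The mesiodistal
  "extension" criterion is realized through these two readings, keeping
  the reading count at seven.

Whether depth should be measured along the scanner z-axis or normal to the
surface is genuinely open; the closest-surface distance (approximately
surface-normal) was chosen for consistency with the alignment metric. On
the synthetic fixtures the difference is < 0.02 mm because the channel
floor region is nearly flat.

## Scoring and grading

`units = floor(|measured − ideal| / 0.25 + 1e-9)` per reading, summed over
the seven readings. The floor rule is the only quantization consistent
with both canonical examples (exactly 0.25 mm short → 1 error; a 2.00 mm
isthmus vs 1.25 mm ideal → 3 errors); the 1e-9 guard keeps
floating-point representations of exact multiples on the intended side.
Deviations are scored symmetrically (over- and under-preparation both
count), unweighted and uncapped.

The error-total → 0–100 mapping is a convention of this package:
`score = max(0, 100 − 2 × errors)` with the penalty configurable. No
published rule ties error counts to points, so reproduction of any
particular study's grade distribution is explicitly not claimed. Letter
bands are closed at their lower bound; a score equal to the pass/fail
cutoff passes. The default cutoff 44 is the borderline-group value
(`borderline_cutoff` computes the mean of a borderline group's scores);
"F" is accepted as an input alias for the lowest band E.

## Agreement battery

Conventions, where the literature offers choices:

* **Positive class / truth**: "pass" is positive; the panel is ground
  truth and the software the rated method (the natural direction for
  validating an automated grader against experts).
* **Kendall**: τ-b (tie-corrected) — letter-ish integer scores are heavily
  tied.
* **ICC**: ICC(3,k) = two-way mixed effects, consistency, average of k = 2
  measurements, `(MS_subjects − MS_error)/MS_subjects`; 95% CI from
  F-distribution bounds on `MS_subjects/MS_error` with
  (n−1, (n−1)(k−1)) degrees of freedom. A constant offset between raters
  lands in the rater term, not the error term, so a shifted duplicate
  scores exactly 1 — asserted as a closed-form test.
* **ROC AUC** by the trapezoid rule over the threshold sweep, which equals
  the Mann–Whitney concordance probability with ties counted ½ (asserted
  against an exhaustive pair-counting oracle). **PR area** uses the
  step-wise (average-precision) estimator; linear interpolation between PR
  points is optimistic. The F1-maximizing software threshold is reported
  as the suggested operating cutoff.
* **Weighted kappa** uses the full ordered category space A–E with weights
  |i−j|/(k−1) (linear) or ((i−j)/(k−1))² (quadratic), so an absent middle
  grade keeps its spacing. In the 2-category case both reduce exactly to
  unweighted kappa.
* **Quartiles** by linear interpolation between order statistics
  (numpy's default); IQR-style summaries depend on this choice, so it is
  fixed and documented. Mode takes the smallest value on ties.
* **Tail agreement** uses panel-defined tails as the denominator, with
  ties broken by subject id.
* **p-values**: large-sample approximations from scipy; for n ≤ 10 they
  are replaced by seeded Monte-Carlo permutation p-values (4999
  resamples), where the asymptotics are unreliable.
* Undefined quantities (empty class, zero variance, expected agreement 1
  with imperfect observed agreement) are reported as NaN, never raised, so
  a report is always produced.

Curve construction and kappa/rank statistics go through scikit-learn and
scipy where those provide the standard computation; every metric is also
checked against an independent brute-force implementation (O(n²) loops,
direct formula transcription) on 100 seeded small instances, and ICC
against an independent reference implementation.

## Synthetic fixtures

The generator emulates the study conditions, not real anatomy:

* **Tooth**: a heightfield occlusal surface — four Gaussian cusps
  (height 1.2 mm, σ 1.3 mm) mirrored about a flat-bottomed central groove
  (depth 0.4 mm, quartic-exponential profile) on an 11 × 10 mm footprint at
  8 vertices/mm. Heightfields have no undercuts, which keeps every
  ground-truth reading analytic; all seven readings are occlusal/proximal,
  so nothing relevant is lost. Cusp offsets were chosen so the channel
  floor region is nearly flat (slope < ~7°), making vertical carve depth
  and closest-surface depth agree to < 0.02 mm.
* **Cavity**: vertices inside the mesiodistal channel footprint are
  lowered by the carve depth (default 1.50 mm deep, 1.25 mm wide, stopping
  2.0 mm short of each proximal surface — the ideal prep). Optional wall
  draft and floor roughness are available; defaults are vertical walls and
  a flat floor. Note the default grid (0.125 mm) represents the default
  widths exactly; at coarser resolutions a width that is not a multiple of
  the grid spacing cannot be carved exactly.
* **Perturbation**: rotation about the centroid plus translation, then
  isotropic Gaussian vertex noise (the simplest scanner-noise proxy); the
  exact transform is returned for recovery tests.
* **Paired scores**: Gaussian copula with latent correlation
  r = 2·sin(πρ_s/6), which makes the population Spearman correlation equal
  the target; normal margins (panel mean 60.91, SD 18.24; software mean
  +3.2, SD ×0.88 — a realistic exam-score regime with the automated grader
  slightly more lenient) clipped to [0, 100].

What passing tests on these fixtures do **not** show: robustness to real
scanner artefacts (holes, topological noise, partial scans), to anatomical
variation between typodont teeth, or to preparations that violate the
channel topology (e.g. multiple disconnected pits). The fixtures establish
correctness of the geometry and statistics, not clinical validity.

## Problem sizes in the standard runs

Registration tests run at 4 vertices/mm (≈ 1.8 k vertices) and measurement
tests at the full 8 vertices/mm (≈ 7.2 k vertices); the acceptance script
uses 8 vertices/mm end to end, a 3 × 3 depth × width fixture grid,
n = 10 000 for simulation-recovery checks and n = 70 for the study-sized
agreement battery. These sizes were chosen as the smallest at which the
discretization error (≈ grid spacing effects) is negligible against the
0.05 mm recovery tolerances.

## Known limitations

* No mesh repair, hole filling or decimation; inputs are assumed clean.
* No non-rigid or scale registration (scanner output is metric).
* Cavity wall convergence/divergence and outline form are not assessed —
  the seven-reading scheme does not capture them.
* ICP has a limited capture basin (~10°/1 mm without pre-alignment);
  grossly misposed scans need the principal-axes pre-alignment flag, which
  itself can be fooled by near-symmetric shapes.
* The error-count → score mapping and the probe geometry are conventions
  that must be configured consistently across a cohort for scores to be
  comparable.
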