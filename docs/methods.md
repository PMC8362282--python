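# Methods

## The problem

Lumbar finite-element (FE) models need two geometric inputs that imaging
papers rarely standardise: where the nucleus pulposus sits inside the
annulus fibrosus, and how much of the disc cross-section it occupies.
Published models place the nucleus "slightly posterior", or a fixed
3.5 mm back, or give it anywhere from 30% to 50% of the disc area.
Because the nucleus is much softer than the annulus, these choices change
the bending stiffness of the motion segment and therefore its computed
range of motion (RoM).

`disccalib` implements the measurement-and-calibration workflow that
replaces those ad-hoc choices with two dimensionless indicators:

* **P1** = mean(D1) / mean(D2), where D1 and D2 are the anterior and
  posterior annulus widths along the mid-sagittal line (mm). P1 > 1 means
  the nucleus sits posterior of the disc centre.
* **P2** = mean nucleus area / mean disc area, a fraction of the
  transverse cross-section.

Both are ratios of cohort means, not means of per-subject ratios; the
pooled estimate P1 = 1.22 arises from mean widths 8.87 mm / 7.29 mm, and
P2 = 38% from mean areas 671.4 / 1761.0 mm².

## Coordinate and measurement conventions

Transverse plane, x-axis anteroposterior increasing posteriorly, y-axis
left–right, origin free (the disc centroid in generated data). The
mid-sagittal line is the horizontal through the **disc** centroid.
D1 is the gap from the anterior disc boundary to the anterior nucleus
boundary along that line; D2 the posterior analogue. They are *line*
measurements, matching how distances are read on a sagittal MR slice, not
minimum clearances. Areas use the shoelace formula (via shapely) and are
orientation-invariant.

## Nucleus placement (the inverse problem)

Given a disc contour and target ratios, the nucleus contour is the disc
contour similarity-scaled about the disc centroid by √P2 — making the area
fraction exactly P2 — then translated along x by the offset δ that makes
the measured D1/D2 equal P1. When the mid-sagittal intersection of each
contour is a single interval [a, b], δ has the closed form

    δ = (P1·(b_disc − b_nucleus) + a_disc − a_nucleus) / (1 + P1),

which the implementation verifies and, for contours whose midline crosses
a concavity, replaces with a bracketed root solve. Placement is validated
by strict polygon containment.

A consequence worth recording: for any *convex* disc the midline
feasibility bound coincides with the full 2-D containment bound (Minkowski
argument for similar scaled copies), so a ratio-driven placement can never
push the nucleus outside a convex disc — unlike a fixed millimetre offset,
which fails on small discs. Infeasible placements only arise for concave
outlines whose dent the shifted nucleus cannot nest into; the test suite
constructs such a disc explicitly.

## Reliability statistics

Measurements come from human observers, so the pipeline qualifies them
before pooling:

* **Cohen's kappa** (unweighted, nominal categories) for every observer
  pair on the Pfirrmann grades, computed on the *pre-exclusion* ratings.
  Undefined when chance agreement is 1; raised as an error rather than
  returned as NaN.
* **Cronbach's alpha** per indicator (D1, D2, disc area, nucleus area)
  with observers as items and n−1 sample variances throughout. Undefined
  at zero total-score variance.

Both are short closed-form computations implemented directly so the
degenerate cases raise typed errors; the tests cross-check them against
`sklearn.metrics.cohen_kappa_score` and `pingouin.cronbach_alpha`.

## Synthetic cohort

The generator emulates the study population (43 young adults, three
observers) rather than any individual image:

* Disc = ellipse with sampled semi-axes, AP 21.066 ± 1.70 mm and lateral
  26.609 ± 2.10 mm. These means jointly reproduce the published mean
  annulus widths (D1 + D2 = 16.16 mm at P2 = 0.38) *and* the mean disc
  area (1761 mm²); the ~8% axis spread reproduces the published disc-area
  SD (~206 mm²).
* Per-subject ratios jittered around the true values: P1 1.22 ± 0.08,
  P2 0.38 ± 0.02. The published D1/D2 SDs (~1.4–1.5 mm) are larger than
  the generator's (~0.9 mm); matching them would require axis spreads that
  overshoot the published area SD, and means, not spreads, drive every
  downstream estimate.
* Observer noise: multiplicative lognormal, `value · exp(0.02·z)`. A 2%
  perturbation keeps all four alphas above 0.95 at n = 43.
* Grades: true Pfirrmann frequencies (0.30, 0.28, 0.22, 0.12, 0.08) for
  the *reviewed* clinical pool; observers confuse a grade with an adjacent
  one 15% of the time (85% diagonal confusion). With a 0.85 diagonal,
  expected unweighted kappa is bounded by ~0.67 regardless of marginals;
  the chosen frequencies put it near that bound (~0.66), inside the
  0.6–0.85 qualitative band. At n = 43 the per-pair sampling SE is ~0.09,
  so individual seeds scatter visibly around that expectation.
* Inclusion mirrors the study: a subject enters the measurement pool only
  when all three observers grade the disc I–II; kappa still uses everyone.

What the generator does **not** emulate: MRI signal formation, segmentation
error structure, correlated per-observer bias, non-elliptical disc
outlines, and 3-D volume effects. Passing tests therefore demonstrate that
the *pipeline* recovers what it is fed under realistic noise — not that
elliptical cross-sections describe real discs.

## Motion-segment surrogate

The full study used commercial FEA with unpublished material tables; this
package instead ships a reduced-order composite-section model whose only
job is to be a live, monotone, mechanically grounded evaluator of
P1 ↦ (flexion RoM, extension RoM).

The disc cross-section is sliced into ≥100 equal-width strips along the AP
axis (default 2000; 10³ vs 10⁴ strips changes RoM by <0.1%). The annulus
is bilinear — modulus `E_at` in tension, `E_ac` in compression — and the
nucleus takes `E_n ≤ min(E_at, E_ac)` (equality is the degenerate
homogeneous limit in which position and size stop mattering). Under a pure
moment the neutral axis x₀ is the root of the net axial force
Σ E(x, strain sign)·(x − x₀)·A, found by bisection to 1e-9 mm (the
residual is strictly decreasing); curvature is κ = |M| / Σ E·(x − x₀)²·A
and RoM = degrees(κ·h) with disc height h. Axial loading uses the
uniform-strain composite rod: DC = F·h / Σ E·A, with the nucleus stress
E_n·DC/h serving as a pressure *proxy* (it is not calibrated to
physiological intradiscal pressure).

During calibration the nucleus is **suppressed**: the geometry stays but
its modulus is zero. This keeps the evaluator sensitive to (P1, P2) —
the stiffness change comes from how the void redistributes annulus
material between the tension and compression zones — which is the only
reading under which a nucleus-suppressed yet P1-sensitive calibration is
coherent.

Default materials: `E_at = 1.0 MPa`, `E_ac = 8.0 MPa`, `E_n = 0.5 MPa`,
`h = 10 mm`. The tension/compression asymmetry produces the directional
signature of the published sweep — flexion RoM strictly increasing, and
extension magnitude strictly decreasing, over P1 ∈ [1.1, 1.7] with a void
nucleus — and places both RoMs at 10 Nm in the cadaveric 15–18° band on
the cohort mean disc. A milder asymmetry (e.g. 2:1) loses the extension
monotonicity beyond P1 ≈ 1.5. No claim is made that the surrogate
reproduces the FE model's absolute trajectory; the published sweep itself
is embedded as a table fixture for exact-number work.

The 100 N preload of the RoM load case is superposed uniform compression
and does not alter bending stiffness (linear model) — a documented
simplification. Facet contact force is not modelled at all: the surrogate
has no posterior elements, so FCF enters validation only as externally
supplied numbers. Lateral bending and axial rotation are outside the
sagittal-plane model for the same reason.

## Calibration statistic and loop

Accuracy of a computed value c against a target t ≠ 0 is

    ACC = (1 − |c − t| / |t|) · 100   [%, clipped below at 0].

This reconstruction reproduces the published six-step sweep's accuracy
cells from the printed (RoM, target) pairs at two-decimal precision —
eleven cells exactly; the twelfth (flexion at P1 = 1.12) computes 92.70
against a printed 92.69, one unit in the last printed digit, consistent
with the source table carrying unrounded RoM upstream.

`calibrate_p1` evaluates an increasing P1 grid (input order irrelevant),
scores both directions at each step, and returns the smallest P1 whose
flexion **and** extension accuracies reach the threshold (default 99%, the
published stopping rule; the published grid is measured P1 − 0.10 stepping
+0.10). If no grid point qualifies, the result is flagged non-converged
and carries the argmax of min(flexion, extension) accuracy. Only P1 is
calibrated: growing P2 softens the disc in every direction simultaneously
and cannot move flexion and extension accuracies in opposite directions,
whereas shifting the nucleus stiffens one side of the section while
softening the other.

## Validation

Each computed indicator (RoM, DC, IDP proxy; FCF externally supplied) is
scored with the same accuracy statistic against a reference mean, plus a
strict within-one-SD flag when the reference carries an SD. An entry is
acceptable at accuracy ≥ floor (default 90%) *or* within one SD — the
latter encodes accepting a sub-floor indicator whose value sits inside the
experimental scatter. The shipped reference table is a labelled synthetic
placeholder (schema example); only the two cadaveric RoM targets, 16.71°
flexion and −16.24° extension at 10 Nm, are study constants.

## Problem sizes and determinism

Defaults throughout are the study's own sizes: 43 subjects, 3 observers,
6-point calibration grid, 2000 strips, 192–256-vertex contours. A full
pipeline run takes well under a second in table mode and a few seconds in
surrogate mode. All randomness flows through one integer seed per run;
identical configs produce byte-identical report bundles (no timestamps in
any artifact).

## Known limitations

* 2-D cross-section ratios only; no 3-D volume ratio, no lordotic-angle
  effects.
* The surrogate omits ligaments, facets, contact, and fibre-reinforced
  hyperelasticity; its IDP proxy is a stiffness-weighted stress, not a
  pressure measurement.
* Reliability statistics are point estimates, without confidence
  intervals.
* The elliptical generator cannot produce the concave posterior margin of
  real L4–L5 discs (the placement code handles concave contours; the
  generator just does not emit them).
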