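# Methods

## Geometry and conventions

Axes are fixed to the registration convention: x = left–right, y =
inferior–superior (increasing cranially), z = anterior–posterior
(increasing anteriorly). Structures are stacks of simple planar polygons on
axial (x–z) slices; one polygon per slice (multi-island slices are
rejected). Lengths are mm, areas cm², volumes cc, doses Gy; conversions are
centralized in `cordshift.units`.

The cord partition uses half-open intervals [y_min, y_max); a contour
exactly on a boundary belongs to the interval that starts there. The
vertebral-level boundaries are configuration, not anatomy the code derives:
defaults place C6–C7 at [0, 60) mm, C4–C5 at [60, 100) and C1–C3 at
[100, 160).

**Shift sign convention.** A setup error is the anatomy position at
treatment minus the planned position, in plan coordinates; the rapid
estimator adds this vector to the planned cord contour. (The convention is
a declaration — measured registration output must be mapped onto it.)

**Rasterization** is voxel-centre membership (even–odd rule) against the
slice polygon nearest in y, within half a slice spacing; no partial-volume
weighting. The error is bounded by the voxel size and the cylinder test
shows the expected convergence with refinement.

**Contour clipping.** Shrinkage by fraction f scales each slice polygon
radially about its own centroid by √(1−f), so the slice area scales by
exactly (1−f) and the measured contour change of the result equals f to
machine precision. Isotropic area-matched scaling is a declared stand-in
for the (undefined) clinical clipping geometry; posterior-weighted clipping
would concentrate the same area loss on the cord side and would increase
the cord-dose sensitivity per unit area change, so slopes fitted on this
phantom are not transferable to patients.

## Dose metrics

D(v) is defined discretely: sort in-mask voxel doses descending, accumulate
voxel volumes, return the dose of the voxel at which the cumulative volume
first reaches v (v = 0 gives the voxel maximum). No sub-voxel DVH
interpolation; whether a commercial TPS interpolates is unknown, so the
discrete convention is declared rather than claimed equivalent. It is
verified against a brute-force definitional oracle (largest dose d with
volume{dose ≥ d} ≥ v) and is monotone non-increasing in v. Per-fraction
metrics are scaled linearly by the fraction count (default 33) before
percent differences against the planned value, which are always taken
against the same region's own planned D(0.1cc).

## The rapid estimator

`dmax_displaced` rasterizes the planned-position cord once, translates the
in-mask voxel centres by the measured shift, and samples the planned dose
grid by trilinear interpolation at those points. Sampling moved points
(rather than re-rasterizing the moved polygon) makes the estimate
continuous in the shift — no grid locking at sub-voxel errors — and makes
the zero-shift case literally the same code path as the planned value, so
the identity is exact. Points leaving the grid raise a hard error rather
than clamping, to avoid silently underestimating dose. Shifts are applied
per region independently (each region is registered separately); no
blending at region boundaries. The pooled fit of Dmax_displaced on the
engine-recalculated setup dose is the estimator's validation; a per-region
fit mode exists but pooled is the default.

## The synthetic phantom and toy dose engine

The phantom stands in for a planning CT course; it emulates the statistical
structure of a real cohort, not its anatomy or physics.

**Body.** Elliptical cross-sections with a fixed anterior–posterior
semi-axis (57 mm) and a left–right width carrying the cranio-caudal area
profile. The profile interpolates linearly between region-midpoint nodes
and the nodes are calibrated by fixed-point iteration so the *median* slice
area per region equals the configured planning SSAs (192.7 / 133.0 /
171.4 cm² for C1–C3 / C4–C5 / C6–C7) — the mid-neck narrowing makes the
within-region median differ from the midpoint value, so this calibration is
not redundant. The cord is a straight posterior cylinder (radius 5 mm,
axis at z = −38 mm), 2.5 mm slices.

**Engine.** Dose at an interior point p = (x, y, z):

    D(p) = A · g(y) · [1 − β(y) · exp(−r²(x,z) / 2σ²)] · Σ_b w_b · exp(−μ · depth_b(p))

* Σ_b: N = 36 equally spaced coplanar parallel beams; depth_b is the
  distance from p to the body surface along beam b's source direction
  (closed-form for convex slices); μ = 0.005 mm⁻¹ (≈ 6 MV in water).
* w_b = 1 + a·cos φ_b with a = 0.5 skews fluence toward anterior entry.
* The bracket is a room-fixed Gaussian dose *valley* (σ = 8 mm) carved
  around the planned cord axis — the minimal stand-in for a plan that
  spares the cord inside a high-dose neighbourhood. Its depth β(y) is 0.25
  at the C1–C3 midpoint, 0.12 at C4–C5 and 0.05 at C6–C7: steep valley
  walls near the cranial target, flat caudally. This single feature gives
  both of the study-design behaviours: any rigid displacement climbs the
  valley wall (setup errors *increase* the cord Dmax on average), and the
  sensitivity is largest in the upper neck.
* g(y) is the plan fluence profile, piecewise-linear through region
  midpoints, calibrated (fixed-point, on cord voxels only) so the planned
  per-region cord D(0.1cc) at course scale equals 37.4 / 36.2 / 33.2 Gy.
* A normalizes the unmodulated field so a reference target point (anterior,
  upper neck) receives the per-fraction prescription (70 Gy / 33).

β, g and the body width are all *continuous* in y. Early piecewise-constant
versions put large dose discontinuities at region boundaries, which the
grid recomputation snaps across while the estimator interpolates — an
artifact of the toy model, not of the estimator — so continuity is a design
requirement here.

Shrinking the body strictly shortens every beam path, so dose at a fixed
interior point strictly increases — the qualitative contour-change effect —
and the response is locally linear in the area change (first-order
μ·Δdepth, property-tested against the Taylor prediction).

**Grids.** Slices every 2.5 mm; in-plane sampling 1.25 mm over ±20 mm
around the cord axis. The finer in-plane pitch is needed because D(0.1cc)
of a 5 mm-radius cord at 2.5 mm pitch rides on ~6 voxels and becomes
unstable under sub-voxel displacements; 1.25 mm is standard practice for
small serial organs. Course variants are evaluated only at cord-mask
voxels, which keeps a 10-patient course (1080 engine evaluations) near
10 s.

**Uncertainty model.** Setup errors are per-region, per-axis Gaussians with
an early phase (fractions < 23) and an inflated late phase for C4–C5 and
C6–C7, clipped at ±8 mm. The per-axis spreads are assumptions chosen from
the Maxwell-mean relation E‖N₃(0, σ²I)‖ ≈ 1.596 σ to reproduce the
per-phase 3D-error means (head ≈ 2.0 mm, C1–C3 2.1→2.7, C4–C5 2.5→4.0,
C6–C7 2.8→4.2 mm); the anterior–posterior means are small and negative
(−0.3 to −1.2 mm), encoding the posterior drift of the neck. Shrinkage is
linear in fraction index from zero to a per-patient course-end fraction
drawn around 6.7 / 12.9 / 17.9 % (SDs 7.3 / 12.1 / 15.6 %, clipped to
[−0.10, 0.32] so the cord stays inside the body); recorded SSAs add 1 cm²
of measurement noise. Six imaging timepoints per course (fractions 1, 10,
17, 23, 28, 33). All draws flow from one `numpy` Generator seeded by the
caller.

**What the generator does not emulate:** real beam physics (scatter,
heterogeneity, arc delivery), CBCT imaging or its artefacts, deformable
anatomy (shrinkage here is area-preserving scaling, not posterior tissue
loss), rotational setup errors, intra-fraction motion, or inter-patient
anatomical variation (all patients share one phantom). Passing tests
therefore demonstrate the *pipeline's* correctness and the estimator's
internal consistency under the declared model — not clinical accuracy of
any fitted slope.

## Longitudinal statistics

* Grand means are means of per-timepoint means (equal to the pooled mean
  for equal group sizes, which the generator guarantees); grand SDs pool
  all observations.
* The average contour change is, by default, the mean over timepoints of
  the cohort-mean SSA's change against the cohort planning SSA
  ("cohort" mode); a "per_patient" mode averages each patient's own
  fraction-wise changes first. The two coincide for a single patient or a
  common planning SSA and differ in the second decimal otherwise; both are
  provided because published summaries do not always state which was used.
* Head-vs-region comparisons use the two-sided Wilcoxon signed-rank test on
  paired per-direction errors: zeros dropped (Wilcoxon's rule), exact null
  for small tie-free samples, tie-corrected normal approximation otherwise
  (scipy). All-zero differences return p = 1 — no evidence of a difference —
  rather than an error. No multiple-testing correction is applied.
* Regressions are ordinary least squares (scipy `linregress`) reporting
  slope, intercept, R², residual mean/SD and n; a constant regressor raises
  a degenerate-input error, and a constant *response* with zero residuals
  reports R² = 1 by convention. The contour-dose fit uses one point per
  imaging timepoint (cohort means), which is why its R² is high by
  construction on the noise-controlled phantom.
* Slope-recovery validation uses a declared linear-response generator
  (y = βx + noise) rather than the full engine, so the truth is exact; the
  engine's own shrink response is only first-order linear.

## Numerical choices and edge cases

* D(v) ties: stable descending sort; the returned dose is unaffected.
* The engine requires convex body slices (closed-form ray exit); non-convex
  slices raise a geometry error.
* Zero shrink and zero shift are short-circuited so a null perturbation
  reproduces the plan bit-exactly.
* Fixture I/O is lossless round-trip JSON + npz with a checked schema tag
  (`cordshift-fixture-v1`); DICOM RTDOSE/RTSTRUCT reading converts the
  patient LPS axes by (x, y, z)ᵢₙₜ = (x, z, −y)_DICOM and logs the mapping;
  frame-of-reference mismatches warn but load.

## Known limitations

* One polygon per slice; no multi-island bodies or cords.
* Translational setup errors only.
* The clipping geometry is isotropic per slice, not posterior-weighted.
* The re-planning trigger is a pure threshold screen on estimated regional
  D(0.1cc); it encodes no clinical judgement.
* Acceptance-scale cohorts (10 patients, 6 timepoints) are study-sized by
  design; the statistical checks use tolerances appropriate to that n.
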