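# Methods

`bwdose` predicts bladder-wall dose-volume endpoints for pelvic
radiotherapy plans from the spatial relationship between the planning
target volume (PTV) and the bladder, and judges finished plans against
the 95% confidence interval of the predicted mean. This note records the
models, conventions and numerical choices the package commits to, and
what its synthetic phantoms do and do not emulate.

## Voxel geometry

All structures live on a shared regular grid, index order (z, y, x),
with physical voxel spacing in mm (anisotropic allowed; pelvic CT is
typically 5 mm slices with finer in-plane pixels). Margin expansion and
contraction use the Euclidean distance transform with the physical
spacing, so margins are isotropic in physical space regardless of grid
anisotropy.

Distances follow the **voxel-center convention**: a voxel joins an
expansion when its center lies within the margin (inclusive) of some
structure-voxel center, and survives a contraction when its center is
strictly farther than the margin from every complement-voxel center.
This convention is exactly testable against a brute-force all-pairs
distance computation, which the test suite does. Its known bias is about
half a voxel at structure boundaries: contracting by a distance below
the smallest voxel edge removes nothing, and derived shell volumes run
thin by roughly half a voxel per surface. Consequences:

- Volumes are voxel counts times voxel volume; no sub-voxel
  (partial-volume or marching-cubes) correction is applied.
- The bladder wall thickness t = exp(3.6105 − 0.52 ln V) (t in mm, V
  the bladder volume in ml, with 1 cm³ ≡ 1 ml) is typically 1.5–2.5 mm
  for realistic bladders — smaller than a 5 mm CT slice. The wall mask
  (bladder minus its contraction by t) then degenerates toward a
  one-voxel shell; the package warns, and falls back to the 6-connected
  one-voxel boundary shell if the contraction removes nothing, so the
  wall is never empty. Thin-shell volume accuracy should only be
  expected when the wall thickness spans several voxels (the suite
  verifies ~10% agreement with the analytic shell at 0.5 mm spacing and
  radius ≥ 20 voxels).
- Expansions are clipped at the grid edge; feature extraction warns when
  the largest PTV expansion touches the edge, since overlaps may then be
  truncated by the field of view.

The overlap features are, for each margin x in {0, 0.5, …, 3} cm,
the percentage of bladder-wall (Pbw_x) and whole-bladder (Pb_x) volume
inside the PTV expanded by x cm. Expansions are nested, so each feature
curve is non-decreasing in x — asserted as a property test. The PTV
volume feature counts PTV voxels on the slice range (inclusive, along
z) occupied by the bladder.

## Dose endpoints

Plans are renormalized by a single global factor so that D95 of the PTV
equals the prescription (50 Gy default). D95 uses the no-interpolation
order statistic: the largest dose d such that at least 95% of PTV voxels
receive ≥ d. Endpoints are then read directly from voxel dose values —
no DVH binning: VxGy (x = 10…45 in 5 Gy steps) is the absolute cm³ of
wall voxels with dose ≥ x (inclusive threshold, the standard cumulative
convention), and Dmean is the plain mean over wall voxels (uniform
voxels make this the volume-weighted mean). Dose and structure grids
must be identical; resampling is deliberately out of scope (an error,
never silent interpolation). Dose-volume criteria (e.g. bowel V45 < 190
cm³, femoral-head V40 < 35%) are strict inequalities; equality fails.

## Regression protocol

For each endpoint, candidate multiple-linear-regression models are built
by three selection methods (forward, backward, stepwise) over three
predictor pools — all 17 candidates {VPTV, Vbw, Vbladder, Pbw_x, Pb_x},
the 10 wall-overlap candidates, and the 10 bladder-overlap candidates —
giving nine candidates with (method, pool) provenance, duplicates kept
and flagged. Selection is driven by coefficient p-values with
α_enter = 0.05 and α_remove = 0.10 (the common defaults of commercial
statistics packages; configurable). Candidates are scanned in a fixed
column order and p-value ties go to the earlier column, so the protocol
is fully deterministic.

Each candidate is screened: overall F-test p < 0.05; every slope
p < 0.05; max VIF < 5 (VIF computed by definition, 1/(1 − R²) of each
predictor on the others); Shapiro–Wilk residual normality p ≥ 0.05;
Breusch–Pagan homoscedasticity p ≥ 0.05. The residual tests are the
standard named tests for properties the protocol requires but does not
name a test for; both thresholds are configurable. Numerically zero
residuals (exact fits) make the residual tests meaningless; they are
skipped and the report flagged degenerate-pass. R² is defined as 0 for a
zero-variance response (degenerate flag). The best model is the
screened-passing candidate with maximal adjusted
R² = 1 − (n−1)/(n−p)(1−R²) (p counts the intercept); ties break toward
fewer predictors, then pool order full → wall-only → bladder-only.
Reported statistics are rounded to 3 decimals in outputs; full precision
is kept internally.

## Prediction and plan verdicts

A fitted model keeps its sufficient statistics — (XᵀX)⁻¹ of the
intercept-augmented design and the residual mean square s² — so that at
a new predictor row x_h (intercept-augmented):

- mean-response CI: ŷ_h ± t(1−α/2, n−p) · √(s² · x_hᵀ(XᵀX)⁻¹x_h)
- individual CI:    ŷ_h ± t(1−α/2, n−p) · √(s² + s² · x_hᵀ(XᵀX)⁻¹x_h)

The individual interval strictly contains the mean interval whenever
s² > 0. A plan endpoint is *acceptable* when the actually computed value
is at or below the upper limit of the 95% mean-prediction CI; above it,
the plan is flagged for re-optimization. Equality resolves to
acceptable. α defaults to 0.05.

The shipped registry of 27 published models (9 endpoints × combined /
rectal / gynecologic cohorts) carries coefficients and R² only; the
sufficient statistics are not recoverable from coefficients, so
published models give point predictions but refuse to fabricate
intervals. Disease-specific models are preferred over the combined model
when the cohort is known. Two registry caveats are shipped as-is: the
gynecologic V35Gy row fails the mean-consistency identity by ~0.85 cm³
(all sibling rows pass within rounding, suggesting a transcription
issue at the source), and models whose predictors only have published
medians (not means) cannot be mean-consistency-checked at all; both are
excluded from the reproduction suite but remain usable.

Accuracy metrics follow the printed definitions: RMSE, and a **signed**
mean percentage error MPE = 100/n Σ (A_i − P_i)/A_i. Despite the name's
similarity to MAPE, errors of opposite sign cancel; this is intentional
and prominently documented.

## Synthetic phantoms and cohorts

`make_phantom` builds an ellipsoidal bladder and a PTV primitive (box,
ellipsoid or capped z-cylinder) on a default 48×96×128-voxel grid at
5×2×2 mm (240×192×256 mm — large enough to hold a realistic bladder
plus a PTV with 3 cm of clearance so the largest expansion is never
clipped; primitives violating that clearance raise). Dose falls off
sigmoidally with signed distance d to the PTV surface (negative
inside): dose = prescription · σ(−d/λ), λ = 8 mm default, plus optional
Gaussian noise clipped at 0. The sigmoid is a deliberately simple dose
model that preserves the monotone dose–distance structure the overlap
features exploit; it does not emulate beam geometry, scatter, or
heterogeneity, so absolute endpoint magnitudes from voxel phantoms are
not clinically calibrated.

`make_cohort` has two modes. *Voxel* mode pushes n randomized phantoms
(bladder volume log-normal, PTV proximity uniform) through the full
geometry + dosimetry pipeline. *Fast* mode samples feature vectors
directly from distributions calibrated to the published cohort
summaries: normal for variables with published mean/SD, log-normal
matched to median/IQR for the skewed volumes, and a Gaussian copula for
the overlap percentages whose correlation decays with margin distance
(AR(1) in margin rank, lag-1 correlation 0.95 by default). Adjacent
margins differ by small geometric increments, so their correlation must
exceed that of distant margins; the decaying structure also keeps
per-plan monotonicity violations rare, and the residual violations are
repaired by isotonic projection, which preserves the calibrated means
(verified to 3 standard errors at n = 500). Endpoints follow a
configurable linear generative rule with Gaussian noise; by default the
registry equations of the calibrated cohort with residual SD set to
endpoint_SD · √(1 − R²), so synthetic cohorts jointly reproduce the
published predictor and endpoint structure. The generative coefficients
are returned as ground truth for recovery and coverage tests.

What fast-mode passing tests show: the selection/screening/interval
machinery behaves correctly on cohorts with the published first and
second moments and a linear truth. What they do not show: performance
on real contours, where feature distributions are not Gaussian, the
feature→dose relation is only approximately linear, and inter-feature
correlation comes from anatomy rather than a copula.

## Problem sizes in the test suite

The suite favors sizes that exercise every code path at full fidelity:
brute-force geometry oracles on ~10³-voxel grids, full phantoms at the
default grid, 50-seed selection-recovery and 1000-replicate interval-
coverage experiments on fast-mode cohorts of n = 49–50 (the published
cohort sizes), and 100-seed power checks for the heteroscedasticity
screen at n = 300.

## Known limitations

- No DICOM-RT adapter: NIfTI volumes and CSV tables are the interfaces.
- No dose resampling between mismatched grids (by design).
- Wall extraction at 5 mm slices is a coarse one-voxel shell; volumes
  derived from it inherit that granularity.
- Published-model prediction intervals are impossible without the
  original design matrices; only package-fitted models provide them.
- The re-optimization verdict is a statistical screen, not a clinical
  judgment; it assumes the fitted cohort represents the plan under test.
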