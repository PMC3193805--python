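# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `brixflow`, and what the synthetic test bed does and does
not establish about real data.

## Pharmacokinetic model and normalization

Enhancement is modeled in relative-signal space: no T1 mapping, flip-angle
correction or signal-to-concentration conversion is attempted, and no
arterial input function is estimated. The Brix two-compartment model
describes the voxel enhancement as

RSI(t) = A·k_ep/(k_el − k_ep)·(e^(−k_ep t) − e^(−k_el t)),

with amplitude A (dimensionless, related to EES size), exchange rate k_ep
(min⁻¹) and plasma elimination rate k_el (min⁻¹), t in minutes post-bolus.
Near the k_ep = k_el diagonal the closed form cancels catastrophically in
floating point; the implementation switches (at |k_el − k_ep|·t < 1e-4) to
the factorization A·k_ep·t·e^(−k_ep t)·φ(x), φ(x) = (1 − e^(−x))/x
evaluated by a four-term Taylor series, which keeps the curve continuous
across the diagonal to ~1e-12 relative. The curve's analytic peak time is
t* = ln(k_ep/k_el)/(k_ep − k_el).

The baseline SI(0) is the mean over all pre-contrast frames (noise
reduction; the protocol acquires five). A voxel with non-positive baseline
is flagged non-evaluable rather than raising, since this is a data-quality
property of single voxels.

**Time-axis alignment.** Tumors differ in their actual injection duration;
post-contrast frame times are shifted by (actual − nominal)/2 seconds so
that all curves are referenced to a common bolus midpoint. Baseline frames
are untouched and the corrected series carries actual = nominal, making
the correction idempotent. The synthetic generator applies the inverse
convention when simulating, so correction aligns simulated tumors exactly.

## Voxel fitting

Bounded nonlinear least squares per voxel with A ∈ [0, 50],
k_ep ∈ [0, 30] min⁻¹, k_el ∈ [0, 5] min⁻¹, solved by scipy's Trust Region
Reflective method with an analytic Jacobian (tolerances 1e-8 on objective,
gradient and step; 500 evaluations max). TRF was chosen over classical
Levenberg–Marquardt because the problem is bounded; on interior solutions
the two coincide in the optimum. Starts: (A, k_ep, k_el) = (1, 1, 0.1),
with fallbacks (0.5, 5, 0.05) and (3, 0.5, 0.5) tried when the first start
fails or fits poorly (r² < 0.5).

Two structural hazards are handled explicitly:

- **Exchange symmetry.** (A, k_ep, k_el) and (A·k_ep/k_el, k_el, k_ep)
  generate identical curves. Fits are canonicalized to k_ep ≥ k_el (fast
  exchange, slow elimination — the physiological regime here). Because the
  rate bounds are asymmetric, a solver can strand on the mirror branch
  with a rate clipped at its bound; when a fitted rate saturates, the
  solver is restarted once from the mirrored parameter point and the
  better optimum kept.
- **No enhancement.** An identically-zero curve returns A = 0 with
  undefined r² (NaN) and is excluded downstream.

Voxel exclusion reasons: non-positive baseline, fit failure, r² < 0.5
(configurable), or saturation of A or k_el at the upper bound. A saturated
k_ep does **not** exclude the voxel; it feeds the ROI-level k_ep QC below.
The r² threshold and the exclusion taxonomy are package decisions — the
operational counterpart of qualitative technical-failure exclusions in
animal studies.

**k_ep reliability.** With 12 s frames, a steep in-wash (high permeability/
perfusion) leaves the upslope essentially unsampled and k_ep poorly
determined. A usable voxel counts against k_ep when its fitted k_ep sits
at the upper bound or fewer than 3 post-contrast frames precede the fitted
peak time t*. If more than 25 % (configurable) of usable voxels are
flagged, ROI summaries omit k_ep and report A and k_el only.

**Grid-search oracle.** `grid_search_fit` is an independent global check:
an exhaustive 40³ lattice over the bounds (geometric spacing, since all
three are positive scale parameters) followed by Nelder–Mead refinement
from the best lattice point of each symmetry branch. It shares no code
path with the production fitter beyond the model itself and is used in
tests to certify global optimality.

## Growth endpoints

Volumes use V = (π/6)·length²·width with the longer caliper diameter
squared, implemented exactly as stated in the protocol this package
operationalizes; a `width_squared` switch provides the more common
ellipsoid convention. Relative volume is V(t)/V(0). The 3-fold crossing
time is found by linear interpolation on the volume scale between the
bracketing measurements (the simplest monotone-consistent rule); a tumor
that never crosses is censored at its last observation day. Group TGD is
the difference of group *mean* crossing times, and any censored treated
tumor makes the group value a lower bound, never a point estimate. No
survival-analysis treatment of censoring is attempted.

**Trend comparisons.** Growth curves are compared through orthonormal
linear and quadratic polynomial contrasts of the measurement days applied
to each tumor's log relative-volume series, giving one linear and one
quadratic trend score per animal; arms are compared by two-sample pooled
t-tests on the scores (the quadratic test is the primary comparison). This
is the classical per-animal version of a group×trend interaction
regression: fitting a pooled multiple regression over all time points
would understate the standard errors (within-tumor residuals are
correlated) and fail calibration, whereas per-animal scores make the null
distribution exact. Log transformation stabilizes the multiplicative
measurement variance.

## Group statistics

Relative change is 100·(post − pre)/pre. Within-arm day-0 vs day-8
comparisons are paired on tumor identity (the same tumors are imaged
twice); between-arm comparisons are unpaired pooled-variance t-tests. The
arm-level relative change is primarily the mean of per-tumor relative
changes; the relative change of arm means is exported alongside. Pearson
correlations are computed across arm means for five pairings: hypoxic
fraction vs ΔA, Δk_el, ΔV; and ΔV vs ΔA, Δk_el. A pairing is computed
over complete pairs and skipped only when fewer than 3 remain. No
multiple-testing correction is applied by default (flat 5 % level); Holm
adjustment is available but off.

## Synthetic cohort generator

The generator emulates a five-arm xenograft radiochemotherapy study; its
defaults are the study conditions every test runs under.

- **Acquisition**: 5 baseline frames, 12 s interval, 3 s injection at the
  end of the baseline block, 20 min post-contrast (100 frames). Per-tumor
  actual injection durations can be jittered (default U(2, 6) s) to
  exercise the time-axis correction.
- **Parameter fields**: log-normal, spatially smoothed (Gaussian kernel,
  σ = 2 voxels) over an elliptical single-slice ROI (~400 voxels at the
  default 32×32 grid). Pre-treatment means A = 1.2, k_ep = 3 min⁻¹,
  k_el = 0.25 min⁻¹; voxel CVs (0.15, 0.20, 0.15); tumor-level CVs
  (0.12, 0.15, 0.12). The high k_ep mean relative to the 12 s frame
  interval deliberately reproduces the regime where the in-wash is steep
  and k_ep estimation is fragile, exercising the QC path. Log-normal
  marginals guarantee positivity.
- **Treatment effects**: post-treatment maps are the pre maps scaled
  voxel-wise by per-arm multipliers — A: (0.82, 0.74, 1.04, 1.20, 1.29)
  and k_el: (1.45, 1.85, 1.47, 0.73, 0.73) for (control, PL-DXR,
  PL-DXR+hypoxic RT, hypoxic RT, RT) — so the in-ROI mean post/pre ratio
  equals the multiplier exactly. These mirror the reference group-mean
  percentage changes the package is calibrated to emulate; they are
  emulation targets, not reproductions of any measurement.
- **Noise**: additive Gaussian on signal intensity, SD = 5 % of baseline
  by default. Rician noise is deliberately omitted: at this SNR the
  Gaussian approximation is accurate and keeps the fitting oracle simple.
- **Growth**: V(t) = V0·exp(g·t·(1 − t/(2·t_sat))) with t_sat = 30 d,
  base rate 0.132 d⁻¹ (the untreated arm crosses 3-fold near day 10,
  consistent with a >19 d lower-bound delay for a fully censored arm at a
  29-day window), arm modifiers (1.0, 0.75, 0.40, 0.55, 0.25), per-tumor
  rate CV 0.10, caliper noise SD 0.2 mm, initial diameter U(6, 9) mm,
  width/length ratio U(0.65, 0.95), measurements every 4 days from day 0
  to day 28. Day-9 volume changes are taken at the day-8 measurement, the
  nearest point on the 4-day grid.
- **Hypoxia**: per-tumor hypoxic fraction = 0.17 − 0.21·(relative A
  change) + N(0, 0.02), clipped to [0, 1]. Hypoxic fractions enter as
  scalars; no synthetic stain images are produced.
- **Determinism**: every draw derives from the design seed and
  (stage, group, tumor) indices via `SeedSequence` spawn keys, so arms are
  coupled at a fixed seed and any stage can be reproduced in isolation.

**What the test bed does not show.** The generator works directly in
enhancement space with Gaussian noise, multiplicative treatment effects
that are exact at the map level, a single slice, and growth laws chosen
for qualitative shape. Passing tests therefore certify the correctness and
calibration of the *analysis machinery* — normalization, fitting,
exclusion logic, endpoints, inference — under known ground truth; they do
not certify accuracy on real scanner data, where coil inhomogeneity,
motion, Rician noise at low SNR, partial-volume effects and model
misspecification all enter.

## Problem sizes in the validation suite

The acceptance checks use sizes chosen to make the whole suite run in a
few minutes on one core while keeping every estimate meaningfully
powered: parameter recovery on the full default ~400-voxel ROI; oracle
equivalence on 50 random noiseless curves at a 40³ lattice; calibration at
1000 null replicates (binomial ±3σ band); effect-direction agreement over
50 simulated cohorts with 3 tumors/arm and ~80-voxel ROIs (the sign of an
arm-mean change is insensitive to ROI size once fit noise averages over
tens of voxels).

## Known limitations

- k_ep is reported only when its reliability QC passes; with the default
  steep-in-wash regime it is often excluded, by design.
- Censored growth delays are lower bounds; no event-time modeling.
- The pooled t-tests assume equal variances across arms; Welch variants
  are not exposed.
- The printed-volume formula squares the *longer* diameter, which
  overstates absolute volumes relative to the conventional ellipsoid
  formula; relative endpoints are unaffected.
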