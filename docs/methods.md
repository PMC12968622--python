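# Methods

`empabridge` implements a model-based bridging workflow for empagliflozin in
paediatric heart failure: an adult population-PK model is scaled to children
by allometry, virtual paediatric cohorts are simulated, a fixed-tablet dose
rationale is derived by exposure matching, and sparse PK sampling designs for
a 12-patient phase-2a study are optimised (Fisher information) and stress-
tested (simulation-re-estimation).  This note records the model, the
numerical choices, and what the synthetic populations do and do not
represent.

## Structural PK model

Empagliflozin disposition follows a two-compartment model with sequential
zero-/first-order absorption, lag time and first-order elimination.  The
dose (mg, converted to nmol with the molar mass 450.91 g/mol) is released at
a constant rate over `D1` hours into an absorption depot starting `ALAG1`
hours after administration; the depot empties into the central compartment
at rate `ka`.  All disposition parameters are apparent (CL/F, Vc/F, Vp/F,
Q/F): bioavailability is folded in and never appears separately.

The zero-order phase feeds the depot rather than the central compartment.
This choice keeps random effects on both `D1` and `ka` meaningful (both
shape the absorption profile) and is the conventional realisation of
"sequential zero- then first-order absorption" in NONMEM-style models.

The central concentration is evaluated in closed form.  A unit bolus into
the depot yields a tri-exponential central response with rates
(alpha, beta, ka); zero-order release is its exact convolution with a
rectangular input, and repeated dosing is handled by superposition.  For
uninterrupted once-daily dosing the completed doses collapse into a
geometric partial sum, so cost is independent of treatment duration; the
infinite-sum version gives the exact steady state.  Numerical safeguards:
`expm1` for short-release terms, the product identity for the slow root
beta (avoids cancellation), and a relative nudge of `ka` when it collides
with a disposition rate (coincident-eigenvalue singularity, measure zero in
practice).  A stiff-ODE integration (LSODA, rtol 1e-10) serves as an
independent oracle in the test suite; agreement is at the 1e-10 level.  A
numba-compiled version of the once-daily kernel accelerates the estimation
hot loop; it is bit-compatible with the numpy path at the 1e-12 level and
falls back to numpy when numba is absent.

Terminal half-life is `ln 2 / lambda_z` where `lambda_z` is the slowest
disposition exponent *with non-negligible amplitude*: in the one-compartment
limit `Q -> 0` the beta exponent tends to zero but its coefficient vanishes,
and the observable terminal slope is the alpha phase.  The amplitude
threshold is a 1e-8 fraction of the IV-bolus response.

Secondary metrics over one steady-state interval use a fixed 0.05 h grid:
AUC(0-24) by trapezoid, Cmax/Tmax as the grid maximum with earliest-time
tie-break (grid error is far below the reported precision), Css = AUC/24.
Steady state is either the analytic superposition or an explicit 28-dose
simulation with a 1e-6 relative trough-convergence check; the two agree to
1e-5 and the analytic route is the default.

## Reference fixture (calibrated stand-in)

The published adult model is available only through summary anchors; its
numeric typical values are not reprinted.  The package therefore ships a
*calibrated stand-in*, not the published estimates:

- CL/F = (25 mg in nmol)/5,499 nmol·h/L = 10.08 L/h at 70 kg — exact from
  the linear-model identity AUC = dose/CL.
- Vc/F 22 L, Vp/F 100 L, Q/F 55 L/h, ka 2.0 1/h, D1 1.0 h, ALAG1 0.25 h —
  frozen from a grid search over plausible ranges that reproduces, at
  70 kg / 25 mg once daily: Cmax 766.5 nmol/L (anchor interval
  641–898), tmax 1.4 h (anchor 1.2–1.8), terminal half-life 9.4 h (anchor
  7–12).
- omega^2(CL) = 0.052 (23% CV), matched in closed form to the printed AUC
  interquartile interval (4,696–6,398 nmol·h/L around 5,499): for a
  lognormal AUC the relative IQR width w satisfies
  `exp(z75*s) - exp(-z75*s) = w`.
- omega^2 = 0.09 (30% CV) for Vp/F, Q/F, D1, ka, ALAG1 — placeholders at a
  conventional magnitude; these spreads are not anchored by printed values.
- Proportional residual SD 0.15.

Vc/F carries no random effect (absent from the adult model's random-effects
list).  Calibration is deterministic and idempotent; every value can be
overridden to plug in published estimates, and `make_reference_parameters`
re-verifies all anchors and refuses infeasible combinations.

## Allometry and virtual cohorts

Clearances scale with (W/70)^0.75 and volumes with (W/70)^1.0; absorption
parameters are weight-independent.  The exponents are configurable: the
printed exposure table is internally most consistent with an effective flow
exponent near 0.79, and with the theory-based default 0.75 the typical
50 kg / 25 mg AUC lands 1.2% below the printed value — within the tolerance
of every downstream result.  No maturation function is applied (renal
function and UGT activity are mature in the ≥2-year age range of interest).

The trial cohort draws body weight from a truncated normal, 38.1 ± 16.8 kg
on [15, 90] kg; the dose-rationale grid spans 10–90 kg.  A quantile-matched
lognormal reproduces the 5-patient clinic survey (median 42, IQR 27–44 kg)
for resampling, since only summary statistics are available.  IIV is
diagonal lognormal; no parameter correlations are reported, so none are
imposed.

What the generator does *not* emulate: real demographic covariance
(weight-age-creatinine structure), disease effects on disposition, dropout,
adherence, or assay error beyond the proportional model.  Passing tests
shows internal consistency of the pipeline under the stated assumptions,
not predictive accuracy for real paediatric heart-failure patients.

## Exposure matching

For each (weight, dose) cell, child and adult virtual subjects are simulated
*independently* (no common random numbers: the ratio spread should reflect
variability in both populations) and per-pair ratios of steady-state AUC,
Cmax and Css summarised by quantiles.  The decision rule:

- efficacy: median AUC ratio vs the 70 kg adult at 10 mg >= 0.70;
- safety: median AUC *and* Cmax ratios vs the 50 kg adult at 25 mg <= 1.30.

The 50 kg adult at the maximum recommended dose is the conservative safety
comparator; the 95th percentile of that reference's exposure is also
emitted for plotting, but the 1.3 x median cap drives the decision.  The
minimum admissible weight is the smallest grid weight passing both rules;
with the default fixture and 10 mg tablets this is 15 kg, stable across
seeds at n = 10,000 pairs per cell.

## Design evaluation: Fisher information

The expected FIM uses the first-order (FO) approximation: a subject's
observations are normal with mean `f(theta, t)` at eta = 0 and covariance
`G Omega G' + sigma^2 diag(f^2)`, with `G = df/deta` at eta = 0 from
central finite differences (relative step 1e-4).  Fixed effects enter on
the log scale, so predicted SEs are relative SEs directly and the
D-criterion is invariant to unit rescaling.  Fixed-effect and variance
blocks are block-diagonal, the standard population-design treatment; the
criterion includes all identifiable blocks by default and can be restricted
to match a given estimation model.  Information is additive over subjects,
so grouped designs are group-wise sums; optimisation represents every
subject by the typical 38.1 kg individual (weight is the only covariate).

Schedule optimisation is multistart coordinate descent on the rounded time
grid (default 15 min within the visit windows: [0, 8] h with at most 6
samples at Visit 1, 165–171 h at Visit 2, 501–507 h at Visit 3 for the
designated half of the groups).  Because times live on a finite grid,
coordinate sweeps are exact and reproducible; the empirical 7-sample
schedule is included as a warm start, which guarantees the optimised
criterion never falls below it.

## Simulation-re-estimation

Each replicate simulates a trial (weights, IIV, proportional error,
truncated at zero) and re-fits the model by approximate maximum likelihood.
The marginal likelihood integrates the six subject-level random effects by
a Laplace approximation at the empirical-Bayes mode; the inner optimiser is
a batched damped Newton iteration across subjects (Gauss-Newton-type
curvature clipped from below, backtracking line search, affine-invariant
decrement stop at 1e-3).  The Laplace Hessian keeps the first-order
curvature terms and drops second derivatives of the prediction — the
FOCE-like convention; on one-compartment reductions the resulting OFV
agrees with adaptive Gauss-Hermite quadrature to well under 0.5 units.
The outer maximisation runs Powell's method on log-transformed parameters
(positivity without constraints), started at the extrapolated adult values.

Estimated by default: the disposition fixed effects (CL/F, Vc/F, Vp/F,
Q/F), omega^2(CL) and sigma^2.  Absorption fixed effects and the remaining
IIV variances are fixed to their initial values: sparse paediatric designs
(7-8 samples per subject) do not support estimating every component, and
the design question centres on clearance and exposure.  All fixing choices
are configurable and recorded in the result.  Priors: `informative` adds a
normal penalty on log fixed effects; `non-informative` adds nothing (the
analysis default, since the adult prior comes from a different population
and disease).

Per replicate, the ratio estimated/true is recorded for each estimated
disposition parameter and for AUC (= true CL / estimated CL, exact under
linearity — no re-integration).  Summaries report medians, IQRs and the
fraction inside the 0.7–1.3 acceptability band; non-converged replicates
are excluded and counted, with > 20% failures flagging the result unusable.
Replicate seeds are spawned deterministically from the base seed, making
the whole SSE bit-reproducible.

Known behaviour: the central volume is estimated with a small upward bias
(a few percent even on rich designs) — the familiar Laplace/FOCE
interaction bias with proportional error, mirrored by the reference
analysis in which Vc was the one parameter whose IQR excluded 1.0.  The
default replicate count in the CLI is 100 (a documented scaled-down mode);
500 replicates reproduce the full analysis.

## Problem sizes used in the shipped checks

Ratio distributions and weight bands use 10,000 virtual pairs per cell;
SSE checks run 100 replicates on the rich (40 x 14 samples) and 4-group
sparse (12 x 7-8 samples) designs; FIM-vs-SSE consistency is asserted
within a factor of 2 on the predicted vs empirical relative SEs.  These
sizes make every summary statistic stable to well inside the tolerances
asserted in the tests.

## Known limitations

- The fixture is a calibrated stand-in; absolute exposures inherit the
  anchor values, not the unpublished adult estimates.
- FO-based FIM and Laplace estimation are approximations; both are
  cross-checked (against SSE spread and quadrature respectively) but are
  not exact likelihood theory.
- The individualised scenario (one schedule per patient) ships as a
  synthetic stand-in built from the optimised single-group schedule, since
  its exact schedules are only in unpublished supplementary material.
- No covariates beyond body weight; no nonlinear kinetics; no
  between-occasion variability.
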