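# Methods

This note documents the model, the numerical choices and the design
decisions behind `remipkpd`, in the order a reader would meet them:
structural model → population structure → synthetic studies → estimation →
diagnostics → dose design. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structural model and units

The combined system has seven states: parent amounts A1–A3 (central and
two peripheral compartments), a transit amount A4, metabolite amounts
A5–A6, and the effect-site concentration Ce. All parent elimination
(`CL_p·C1`) enters the transit compartment and appears in the metabolite
central compartment at rate `k_tr·A4`; conversion is treated as complete
and 1:1 on a mass basis, with the metabolite volumes absorbing any
molar-mass factor (the source analysis estimated metabolite V and CL
without a molar conversion term). The effect site is driven by the parent
central concentration only — the metabolite is pharmacologically inactive —
through the standard negligible-mass link `dCe/dt = ke0·(Cp − Ce)`.

Units are fixed throughout: amounts mg, volumes L, clearances L/min, time
min, concentrations ng/mL (factor 1000 from mg/L), BIS dimensionless on
0–100. Typical values, variability magnitudes and residual errors default
to the published final estimates (bundled verbatim in
`remipkpd/data/published_model.yaml`).

The BIS response uses the inhibitory sigmoid with the **sum** denominator
`IC50^γ + Ce^γ`. One printed rendering of the equation shows a product
between the two terms; a product is dimensionally and behaviourally
inconsistent with a sigmoid maximum-inhibition model (it removes the
plateau and makes IC50 meaningless), so the standard sum form the model is
named after is implemented. The implementation evaluates the function via
`1/(1 + (IC50/Ce)^γ)` so large `Ce^γ` cannot overflow.

Two published values conflict with the final parameter tables (a
discussion-section clearance of 1.36 L/min vs 1.21, and ke0 of 1.09 vs
1.38 min⁻¹); the tables govern here.

## Solvers

Between dose events the system is linear and time-invariant, so the
workhorse propagator (`analytic_solution` / `solve_linear_system`) solves
each inter-dose segment exactly: eigendecomposition of the state matrix,
with `(e^{λτ}−1)/λ` evaluated by a series for |λτ| < 1e-10, and a dense
augmented-matrix `expm` fallback when the eigenvector matrix is
ill-conditioned (condition number > 1e12, e.g. defective matrices at
coincident rate constants). Boluses are instantaneous state jumps;
evaluation at a bolus time returns the post-dose state. This route is
exact up to floating point and fast enough to sit inside estimation and
VPC loops.

`simulate` is the independent numeric route: LSODA with rtol 1e-8 and
atol 1e-10 mg, restarted at every dose event so no discontinuity is
smoothed over. The two routes are cross-checked on every regimen of the
study design to a maximum error of 1e-6 relative to each trajectory's
maximum; trajectory-scale normalisation is used because terminal
concentrations decay below the integrator's absolute tolerance, where a
pointwise ratio would measure only tolerance noise.

## Population structure

Between-subject variability is log-normal, `P_i = P̂·exp(η_P)`, with the
published "IIV (%)" read as `100·ω` (the usual approximate %CV of a
log-normal); η draws are independent across parameters. BSV placement
follows the final parameter tables — PK: `CL_p, V1, Q2, V2, k_tr, CL_m,
V5, V6`; PD: `Imax`, Hill — not the conflicting prose lists. Weight enters
through fixed allometric scaling (0.75 clearances, 1 volumes, 60-kg
reference); rate constants are not scaled. Screened covariates use a power
model normalised to the covariate median (age, height) or a proportional
model `θ^sex`.

Residual error: proportional for parent concentrations and BIS, combined
proportional + additive for the metabolite. The two concentration
proportional errors at a sampling time are drawn jointly normal with
correlation `rho_pm` (both analytes come from the same sample); the
published correlation value 0.0066 is exposed as the default and treated
as a correlation coefficient (the report does not say whether it is a
correlation or covariance; at this magnitude the distinction is
immaterial).

## Synthetic studies

`default_design()` reproduces the two-study phase-I design: seven
single-bolus arms (0.025–0.4 mg/kg) with 21 plasma samples over 12 h and
10 BIS readings over 1 h, plus an infusion arm (0.2 mg/kg/min loading for
1 min, then 1 mg/kg/h maintenance for 2 h starting at minute 1) with 7
on-infusion + 20 post-infusion plasma samples and 27 + 14 BIS readings.
The printed per-arm sizes sum to 48 against stated totals of 46
single-bolus and 55 overall; the stated totals are honoured by taking the
0.3 mg/kg arm as n = 8 (per-arm sizes remain overridable). The printed
observation totals likewise do not equal the scheduled counts; the
generator reproduces the schedule, not the totals.

Demographics are drawn to match the reported marginals without inventing
correlations: weight uniform on 52–75 kg, BMI uniform on 19.3–24,
height derived from the two, age uniform on 19–43 y, P(female) = 15/55.

Observation handling: pre-dose (t = 0) concentration records are emitted
as below-limit placeholders and pre-dose BIS carries the subject's
baseline plus residual; concentrations below the 2 ng/mL assay LLOQ are
flagged BLQ with no value; observed BIS is clipped to the monitor's 0–100
scale. The dataset format is a rectangular CSV (ID/TIME/AMT/RATE/EVID/
CMT/DV/DVID/MDV/BLQ/WT/AGE/HGT/SEX, absolute minutes) that round-trips
losslessly and is directly NONMEM-translatable.

What the generator does **not** emulate: dropout and adverse events,
arterial/venous site differences, assay batch effects, dose deviations,
and any real-data model misspecification — parameter-recovery results on
these studies therefore measure estimator behaviour under a correctly
specified model, not robustness to real data.

## Estimation

The original analysis used FOCE-I in NONMEM; re-implementing that engine
is out of scope here, and ω and σ are never estimated — they stay fixed at
their supplied (published) values. The estimators are:

**Individual (MAP / empirical Bayes).** Gaussian residual likelihood
(SDs: `σ_prop·F` parent, `sqrt((σ_prop·F)² + σ_add²)` metabolite,
`σ_prop·F` BIS) plus the log-normal prior penalty `Ση²/2ω²`, minimised by
L-BFGS-B within ±4ω bounds, with perturbed restarts on failure. BLQ rows
are excluded (M1 policy); BIS readings at the 100 boundary contribute a
right-censored (survival) term — without it the ~7% boundary readings
bias the fitted baseline and slope visibly downward.

**Pooled PK fit.** Stage A is naive-pooled maximum likelihood (η ≡ 0) on
log-parameters with bounds [typical/100, typical·100], run sequentially:
parent block on parent data (multi-started from log-normally perturbed
inits, SD 0.35, 3 starts), metabolite block with the parent fixed, then a
joint polish — each stage starts at the previous optimum so the objective
never increases. Stage B is an iterative two-stage refinement: MAP η per
subject, shift each BSV-carrying typical by the mean MAP η (so typicals
track the geometric mean of the individual estimates), recentre the η,
and refit the η-free typicals (`Q3, V3, Q4`) with the η fixed; two
iterations by default. Plain naive pooling under the published BSV
magnitudes is measurably biased (−12 to −17% on CL and V1 in replicate
experiments at the generating truth — the pooled "typical curve" is
pulled toward the population-mean curve); the recentring step removes
essentially all of it. Three perturbed starts for the first stage, with
single-start continuation afterwards, replaced an earlier five-start
plan: the stage-wise warm starts make additional starts redundant and
keep one replicate's fit in tens of seconds.

**Sequential PD fit.** Individual PK parameters are first MAP-estimated
from each subject's own concentration data; the effect compartment is then
driven by the individual plasma prediction while the five PD typicals are
fitted on the pooled BIS likelihood. A naive-pooled fit provides the
start; the final estimates maximise a **Laplace-approximate marginal
likelihood** in which the two random effects (on `Imax` and the Hill
exponent) are integrated out per subject — inner 2-parameter modes by
damped Newton with warm starts, the inner Hessian reused for the
½·log det(ΩH) curvature term, effect-site profiles cached per ke0. This
departure from pure naive pooling is forced by identifiability: the data
never observe saturation (peak effect ≈ 68% of Imax at the largest dose),
so `Imax–IC50–Hill` form a soft ridge, and with 27%/49% BSV on Imax/Hill
the naive-pooled objective is inconsistent along it — on synthetic data at
the generating truth it prefers a point drifted by +56%/+87%/−31% in
Imax/IC50/Hill over the truth by ~99 OFV units. Restoring the integral's
curvature term removes the drift; recovery medians across replicate
studies are within a few percent for all five PD typicals (computed by the
acceptance suite). ke0 remains the least precisely recovered PD parameter
(±15% excursions): it acts only in the first 1–3 min of each profile and
carries no BSV, and it is not a reported headline quantity.

**Covariate screening.** Stepwise forward inclusion (ΔOFV > 3.84,
χ²₁ p < 0.05) and backward elimination (retained only if removal raises
the OFV by > 6.63, p < 0.01) of age, height and sex. The ΔOFV statistic is
the likelihood-ratio of regressing the MAP η of the candidate parameter on
the covariate (log-transformed and median-centred for continuous
covariates, 0/1 for sex), on top of terms already included — the standard
empirical-Bayes screening device. This was chosen over refitting the full
structural model per candidate because the naive-pooled ΔOFV ignores
within-subject correlation and is therefore not χ²-calibrated, while the
η-regression statistic is, which is exactly what the published "no
covariates found" outcome requires of a specificity check. The backward
gate means a covariate survives only at the stricter p < 0.01 level, so on
covariate-free data the expected no-selection rate across the default
six candidate pairs ({CL_p, V1} × {age, height, sex}) is ≈ 0.99⁶ ≈ 94%.

## Diagnostics

GOF tables report population and individual predictions, proportional and
standardized residuals per record, and per-analyte summaries; with the
generating η the standardized-residual SD is ≈ 1 by construction (checked
in the suite).

The VPC recovers the design (doses, times, demographics) from the
observation table itself, simulates replicate studies with full BSV, RUV
and LLOQ censoring, and compares observed percentiles to the across-
replicate distribution of the same percentiles per time bin. Default
binning is design-based — one bin per scheduled time, sparse bins merged
rightward — because the schedule is shared across subjects; explicit bin
edges may be supplied. Both percentile conventions from the source
figures are supported (2.5/50/97.5 by default, 5/50/95 and 10/50/90
configurable); BLQ rows are excluded from percentiles and summarised as a
BLQ fraction per bin; no prediction correction is applied by default since
arms are analysed on their own schedules.

## Dose design

`optimize_regimen` grid-searches bolus (default 0–0.4 mg/kg, step 0.01) ×
maintenance rate (default 0–2 mg/kg/h, step 0.05) for the typical subject
at the given weight, simulating on a 0.1-min grid. Feasibility = BIS
enters the band by the deadline (default 3 min, the "rapid attainment"
criterion) and stays inside it at every grid point until the end of
administration (strictest reading of "maintained a consistent level";
the allowed out-of-band fraction is configurable). Among feasible
candidates the total administered dose is minimised with ties broken
toward the smaller bolus — the source describes no objective, and minimal
exposure is the clinically conservative default. The published
recommendation (0.1 mg/kg + 0.6 mg/kg/h for a 60-kg adult, band 60–80) is
reproduced as a feasibility check, not as a unique argmin: the original
search grid and objective are unpublished, and this package's
dose-minimising search finds feasible regimens with less total drug.

## Reproducibility and problem sizes

Every stochastic entry point takes a seed; identical seeds give
bit-identical artifacts. The acceptance script reports recovery as the
median over 7 independent replicates of the full 55-subject design
(sub-seeds derived from the user seed): with ω = 0.49 on the Hill
exponent, the realized mean of 55 η draws alone has ≈ 7% SD, so a
single-replicate value would conflate estimator quality with one draw's
luck. The test suite uses 5 replicates for the recovery property, 10 for
covariate-screen specificity, and 300 VPC replicates — sizes chosen so
the whole suite runs in minutes on one CPU while keeping Monte-Carlo
error well inside the tolerances being asserted.

## Known limitations

* No nonlinear elimination, protein-binding or arterial/venous submodels;
  no inter-occasion variability; no full Ω covariance.
* ω and σ are inputs, not estimates; standard errors (optional, numerical
  Hessian) cover typical values only.
* The Laplace PD marginal integrates exactly two random effects; it is not
  a general NLME engine.
* Estimation quality is demonstrated on self-generated data; transfer to
  real datasets depends on model correctness assumptions listed above.
* The dose designer optimises the typical subject; population percentile
  overlays are available but no Bayesian feedback from measured
  concentrations is implemented.
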