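# Methods

## Overview

`relapsim` is an in-silico comparison of relapse-prediction strategies for
myeloid leukemias.  Because longitudinal molecular-monitoring cohorts are
small and not freely distributable, the package generates its own: two
mechanistic ODE models (AML, CML) simulate ground-truth remission courses
for virtual patients, a degradation ladder turns them into realistic
clinical measurement series, and three predictors — mechanistic refitting
(MM), logistic regression on kinetic features (GLM) and a bidirectional
LSTM (NN) — are benchmarked on identical stratified 10-fold splits.

## Disease models

**AML** (time unit: days; state `Q_H, A_H, Q_L, A_L`).  Healthy (H) and
leukemic (L) stem cells switch between a quiescent state Q and an active
state A; both species share the niche capacities `K_Q` and `K_A`, so every
transition and proliferation term carries an occupancy factor
`(1 - pool/K)`.  Active cells proliferate (`p_i`), differentiate out of the
pool (`d_i`), and are killed at rate `c` while a chemotherapy cycle runs:

    dQ_i/dt = t_AQ_i A_i (1 - (Q_H+Q_L)/K_Q) - t_QA_i Q_i (1 - (A_H+A_L)/K_A)
    dA_i/dt = -dQ_i/dt + p_i A_i (1 - (A_H+A_L)/K_A) - d_i A_i - c u(t) A_i

with `u(t) = 1` inside a cycle.  Chemotherapy hits both species equally;
the therapeutic window comes from *quiescence protection*: healthy cells
sit mostly in Q (low `t_QA_H`), leukemic cells mostly in A, so cyclic
treatment preferentially depletes the leukemic pool while the healthy
quiescent reservoir refills the active niche between cycles.  The observable
is the leukemic fraction `100 (Q_L+A_L) / (Q_H+A_H+Q_L+A_L)` in percent, the
model analogue of an NPM1-mut/ABL transcript ratio, analysed on the log10
axis and floored at 1e-6 % so logarithms are always defined.

Two of the eleven parameters are patient-specific: the leukemic
proliferation rate `p_L` (sets the post-treatment regrowth rate, hence
relapse timing) and the leukemic activation rate `t_QA_L` (sets how fast
the protected leukemic reservoir is flushed into the chemo-sensitive active
state, hence remission depth).  The remaining nine are cohort-wide
constants (see `relapsim/priors.py`), which also makes them known to the
mechanistic fitter, mirroring a two-parameter patient-fitting protocol.

The diagnosis state is a fixed convention — quiescent niche split evenly
between species, active niche 95 % occupied and 90 % leukemic — because the
parameter set deliberately carries no initial conditions.  The fitted
burden-at-diagnosis feature `y0` still varies across patients (it is a
regression intercept and depends on each patient's slopes and schedule),
but only weakly on noise-free data.

**CML** (time unit: months; state `X, Y, Z`).  Quiescent (X) and active (Y)
leukemic stem cells exchange at rates `p_XY`, `p_YX`; Y grows logistically
(`p_Y`, `K_Y`), is killed by TKI at `e_TKI · dose(t)` and by immune
effectors at `m Y Z`.  Immune cells are produced at `r_Z`, decay at `a` and
are recruited through an *immune window* `p_Z Z Y/(K_Z + Y²)` that peaks at
`Y = sqrt(K_Z)`: recruitment is weak both when leukemia is scarce (nothing
to react to) and when it is overwhelming (suppression).  The observable is
`100 Y / K_Y`, the model analogue of BCR-ABL1/ABL1.

Under TKI the burden declines bi-phasically (fast clearance of Y, then a
slow tail limited by the X reservoir draining at ~`p_XY`).  After cessation
(`dose = 0`), Y regrows; treatment-free remission occurs only if the immune
response catches the regrowing clone inside the window — this is what makes
recurrence depend on immune parameters that are only weakly visible during
therapy, and what the half-dose perturbation year (AS scheme) probes.
Seven of thirteen parameters are patient-specific (`p_XY, p_YX, e_TKI, m,
p_Z, K_Z, Z0`).

**Labels.**  AML relapse: after first dropping below 1 %, the dense
noise-free burden exceeds 1 % again at any grid point within 24 months of
treatment start.  CML molecular recurrence: the burden exceeds 0.1 % (MR3)
for a contiguous span of at least one month within ten years of cessation —
a single isolated monthly excursion does not count.  Labels are always
computed on the dense noise-free course and are invariant under every
degradation transform.

## Numerical integration

The right-hand sides are smooth between dose breakpoints, so the primary
integrator is a numba-jitted adaptive Dormand-Prince RK45 that integrates
segment by segment (never stepping across a dose discontinuity) and forces
steps to land exactly on requested output times, avoiding dense-output
interpolation error.  Relative tolerance defaults to 1e-6 with an absolute
tolerance of 1e-3 cells.  scipy's stiff-capable LSODA is retained as a
reference path (`simulate(..., method="lsoda")`); agreement between the two
at the default tolerance is asserted in the test suite, and a
tolerance-halving refinement test guards the error control.  The calibrated
parameter regimes are non-stiff; a simulation costs ~0.1-0.5 ms, which is
what makes per-patient refitting (hundreds to thousands of simulations per
patient) affordable.

## Virtual cohorts

The package ships 30 reference free-parameter combinations per disease
(`relapsim/priors.py`), selected once from a numerical survey of the
parameter space so that cohorts (i) reach remission under treatment,
(ii) span ≥ 3 log10 of burden decline for ≥ 80 % of patients, and
(iii) contain both outcome classes at a 0.25-0.55 relapse fraction.  These
tables are synthetic stand-ins for empirical patient fits.

* **AML sampling**: reference rows are drawn with replacement and the two
  free parameters are multiplied by `exp(N(0, 0.05²))` — relative jitter
  keeps rates positive and prevents duplicate patients.
* **CML sampling**: the seven free parameters are drawn from a Gaussian
  copula whose marginals are the interpolated empirical distributions of
  the table columns and whose Spearman correlations match the table's,
  so the mutual dependence of the fitted parameters is preserved (verified
  by a 10,000-draw Monte-Carlo test at ±0.05).
* **AML schedules**: 3-5 one-week chemotherapy cycles, starts spaced 33-38
  days, first cycle at day 0; treatment always ends before month 6.
* **CML cessation times**: truncated normal, lower bound 24 months, with
  the pre-truncation location/scale root-solved so the *realized* mean and
  SD are 92 and 28.2 months.
* **Grids**: AML weekly from day 7 to month 24 (39 points inside the
  9-month prediction input window); CML monthly from diagnosis to ten years
  past cessation, plus a measurement at the cessation visit itself.
* **Remission filter**: AML patients whose burden never falls below 1 %
  within the input window are excluded and resampled (they would not enter
  a relapse-prediction cohort); generation aborts if more than 10x the
  requested patients are attempted.

## Data-quality ladder

* **D**: dense noise-free observations of the model course.
* **DN**: multiplicative log-normal noise per measurement; defaults 0.30
  dex (AML) and 0.35 dex (CML) on the log10 axis.
* **SN**: thinned to clinical frequency.  The per-patient in-window count
  is drawn from (3,4,5,6) with weights (0.25,0.35,0.20,0.20) for AML
  (population median 4) and uniformly from 19-31 for CML (median 25); the
  first and last in-window points are always kept, interior points are
  sampled uniformly, and post-window points are thinned to a comparable
  spacing so the label horizon stays realistically sampled.
* **AP**: values below the detection limit (default 0.01 % for both
  diseases) are set to the limit and flagged censored.
* **AS (AML)**: one measurement on the first day of each cycle plus one
  every six weeks after treatment end until month nine, then noise and
  detection limit as for AP.  This yields 7-8 (median 7) measurements.
  First-day sampling hits the uncensored inter-cycle rebound peaks that
  carry the regrowth signal; the end-of-cycle alternative
  (`as_first_day=False`) measures at cycle nadirs, which are mostly below
  the detection limit and measurably *hurt* prediction.
* **AS (CML)**: the course is re-simulated with half TKI dose during the
  final year before cessation (the dose-reduction design of TKI
  de-escalation trials); measurements are the patient's AP times before
  that year plus monthly points during it.  The burden rise under half dose
  reflects the net regrowth-minus-immune-control balance that decides
  recurrence.

## Predictors

* **MM**: minimizes the sum of squared residuals on the log10 axis over the
  free parameters, with censored points contributing one-sidedly
  (`max(0, log10 sim - log10 LOD)²` — a simulation below the limit is
  consistent with an undetectable measurement).  AML: SLSQP from five
  reference-table starts in log10 space.  CML: a generational genetic
  algorithm (population 50, 40 generations, tournament selection, uniform
  crossover, Gaussian mutation in normalised log space, one third of the
  initial population seeded from the reference table) followed by L-BFGS-B
  polish.  The fitted model is then simulated through the horizon and the
  relapse label read off; a fitted course that never remits is called an
  (early) relapse.  MM emits hard 0/1 scores.
* **GLM**: features (AML: `alpha, n, y0, a, b`; CML: `A, alpha, B, beta,
  sigma, t_stop, last_value`, plus `gamma, C, sigma_half, last_pre_stop`
  for AS) are z-scored with training-fold statistics and fed to a logistic
  regression with ridge penalty 1e-4 (fit as the penalized-likelihood
  optimum, equivalent to IRLS with ridge).  Constant columns are dropped
  with a warning; patients whose series cannot be featurized fall back to
  the training majority class at prediction time.
* **NN**: a numpy bidirectional LSTM (32 units per direction, one 16-unit
  ReLU layer, sigmoid output) trained with Adam (lr 1e-3) on binary
  cross-entropy; backpropagation through time is hand-derived and
  gradient-checked against finite differences in the tests.  Channels per
  time point: time scaled by the patient's window length, log10 burden
  scaled to [-1,1] by training-fold min/max, and the censoring flag.
  Sequences are front-aligned and padded; the mask freezes the recurrent
  state on padding.  Training runs `restarts` times with independent seeds
  on the same inner split (10 % stratified validation carved from the
  training fold) and keeps the run with the highest validation accuracy
  (ties → earlier run; single-class validation → fall back to loss).

## Evaluation

Stratified 10-fold cross-validation; all methods are scored on identical
test folds.  MM needs no training and is therefore fit once per patient per
variant and sliced into folds.  Accuracy is `(TP+TN)/(TP+TN+FP+FN)`;
reports carry per-fold accuracies and confusion counts, with mean ± SD
across folds as the headline summary.

## Desk-scale study sizes

The shipped experiment defaults and the test suite run the full grid at 200
AML and 60 CML patients with a reduced sequence-classifier budget (2
restarts; 40 epochs, patience 8, batch 32 for AML; 60 epochs, patience 10,
batch 16 for CML) — chosen as the sizes at which the qualitative findings
are reproducible on a single CPU in minutes.  Mean accuracies at these sizes
carry fold-to-fold SDs of roughly 0.05-0.15, so individual cell values
should be read with that uncertainty; the monotonicity checks allow a
3-percentage-point sampling tolerance.

One directional expectation does *not* reproduce under this generator: the
improved AML measurement scheme does not raise the LSTM's accuracy over AP
(the measured AS-AP difference for the NN is 0 to -4 percentage points at
n = 250-500, while the mechanistic fitter gains +4 to +6).  The cause is
identifiable: the synthetic cohorts remit to levels far below the 0.01 %
detection limit, so the AP variant's censoring pattern — a guaranteed
month-9 anchor measurement plus the censored-flag channel — is itself a
strong sequence-level signal, which the AS redistribution of measurements
toward cycle kinetics partially removes.  The mechanistic fitter converts
those same cycle-aligned points into parameter information and benefits;
the corresponding test is expected to fail for the AML/NN cell and is left
failing deliberately, as a property of these study conditions.

## What the generator does and does not emulate

The synthetic cohorts reproduce: realistic remission kinetics and relapse
dynamics from mechanistic models, clinical measurement frequencies (median
4 in-window AML measurements, ~25 CML), log-scale measurement noise, lower
detection limits with censoring, cyclic chemotherapy schedules, and a
cessation-time distribution with the clinical mean/SD.  They do not
reproduce: inter-patient variability in the nine fixed AML / six fixed CML
parameters, per-sample varying detection limits, irregular visit times
beyond the sparsity model, measurement dropout correlated with disease
state, or any "unexpected" biology outside the generative models.  Passing
tests therefore demonstrate method behaviour under a controlled, idealised
data-generating process — not clinical performance.

## Known limitations

* Labels and predictions are threshold crossings of deterministic ODEs;
  there is no intrinsic biological stochasticity.
* The mechanistic fitter assumes the generator's fixed parameters exactly;
  model misspecification is not studied.
* The bidirectional LSTM runs in plain numpy on one CPU; it is adequate for
  the desk-scale cohorts here but not for cohorts of thousands.
* The CML genetic-algorithm budget (50 x 40 evaluations plus polish) is a
  compromise; occasional fits land in local minima, which is visible as the
  MM accuracy drop on degraded CML data (itself one of the study's
  findings).
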