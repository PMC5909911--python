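# Methods

## The model

`tatscore` measures *effective* implementation adherence: not how many
doses a patient took, but how much of the time their modelled drug
concentration stayed above a therapeutic threshold.

Given dose times `t_s` and technique scores `δ_s` (fraction of the full
dose effectively received on each actuation), the concentration in units
of the prescribed dose is the superposition of exponentially decaying
impulses,

    C(t) = Σ_{t_s ≤ t} δ_s · e^(−α(t − t_s)),      α = ln 2 / T½.

Absorption is treated as instantaneous, which is adequate for inhaled
drugs delivered directly to the target tissue; for drugs with slow
absorption a different impulse response would be needed (out of scope
here).  A dose contributes its full `δ_s` from its own instant — this is
the convention under which one perfect dose raises `C` by exactly 1 and
the steady-state algebra below closes.

The concentration passes through a sigmoidal dose–response,

    σ(t) = 1 / (1 + e^(−β(C(t) − θ))),

where `θ` is the threshold concentration (units of prescribed dose) and
`β` the threshold sharpness; large `β` approaches a step function.  The
adherence score over a window of length `T` is

    A = (1/T) ∫ σ(t) dt  ∈ [0, 1],

the (smoothed) proportion of time above threshold (TAT).

### Required dosage

Under perfect adherence at a fixed interval of `h` half-lives, the
steady-state peak is `dose/(1 − 0.5^h)` and the trough `peak · 0.5^h`.
Setting the trough equal to `θ` gives the required per-administration
dose

    δ_r = θ (1 − 0.5^h) / 0.5^h,

which reduces to `δ_r = θ` at `h = 1`: when doses are spaced one
half-life apart, the fitted threshold reads directly as the fraction of
the current prescribed dose needed.  A patient-specific adjustment
divides `δ_r` by the patient's mean effective adherence, capped by
default at twice the current dose; this rule is an extrapolation (the
adjustment formula is not pinned down by the source analyses), is
labelled as such in output metadata, and is pluggable.

## Technique scoring

Technique-error classes carry multiplicative dose-fraction factors
(correct use 1.0; low inspiratory flow 0.7; exhalation into the inhaler
0.5; no blister pierced or no inhalation detected 0).  Factors of
concurrent errors multiply — the calibrated composite for low flow plus
exhalation, 0.35, equals the product of its components — and zero-valued
errors dominate.  The rule table is user-extensible so other
device/drug combinations can supply their own calibration.

## Numerical evaluation

* The adherence integral uses the trapezoidal rule on a uniform grid,
  default step 0.1 h (6 min) for scoring.  Halving the step changes `A`
  by under 1e-4 on the standard fixtures.  Model *fitting* uses a 0.5 h
  step: the likelihood is smooth in `A`, the fitted-parameter tolerances
  are two orders of magnitude above the induced error, and the grid
  search revisits the integral thousands of times.
* Concentration on a grid is evaluated by an exact chunked
  cumulative-sum recurrence (`O(events + grid points)`); within a chunk
  anchored at `g0`, `C(g) = e^(−α(g−g0)) (carry + Σ δ_s e^(α(t_s−g0)))`,
  which bounds all exponents by the chunk span and involves only
  positive sums.  It agrees with direct summation to 1e-9 relative.
* The logistic argument is clipped at ±745 before exponentiation so
  extreme concentrations saturate to exactly 0/1 in double precision
  without overflow.
* Scoring windows are consecutive 30-day blocks from each patient's
  monitoring start (not calendar months); windows are half-open, so an
  event on a boundary belongs to the later window.  A final partial
  window is scored over its actual length and flagged.
* Concentration at monitoring start is zero (no pre-study carry-in).  A
  configurable burn-in (default 48 h where enabled — the fitting and
  validation pipelines enable it, plain scoring does not) shrinks the
  first window from the left so the cold start does not read as
  non-adherence.  Whether the original analyses seeded pre-study
  concentration is unknown; both behaviours are exposed.

## Model fitting

The decay rate `α` and threshold parameters `(β, θ)` reflect cohort
physiology and are fitted so the adherence score best predicts outcomes.

**Monthly exacerbations.**  Window-level binary outcomes enter a
logistic model `P(exacerbation) = expit(γ0 + γ1 A)`.  At each candidate
`(α, β, θ)` the link coefficients are profiled out by a damped Newton
MLE, giving a profiled Bernoulli log-likelihood.  Windows are treated as
independent in the likelihood (the apparent unit of analysis in the
source validation); a cluster-robust variance option exists in the
validation module.

**Daily peak flow.**  Daily (24 h) adherence scores are smoothed by a
trailing exponential moving average with mean lag `τ` — kernel
`e^(−t/τ)/τ` sampled at the daily spacing and renormalised over the
available history.  The exact kernel behind the published lag is not
specified; the exponential choice matches the model's decay formalism
and keeps `τ` continuous.  A Gaussian linear model with per-patient
intercepts (absorbing baseline lung-function differences) is profiled
out analytically at each `(α, β, θ, τ)`.  `τ` can also be estimated
directly by reverse correlation: the lag maximising the Pearson
correlation of peak flow with the smoothed adherence series, ties
breaking toward the smaller lag.

**Optimiser.**  A deterministic coarse grid (defaults: `α` spanning
half-lives 6–24 h in 9 steps; `β ∈ {25, 50, 73, 100, 150}`; `θ` from
0.1 to 1.2 in steps of 0.05; `τ` from 6 to 36 h for peak-flow fits)
followed by Nelder–Mead refinement from the best cell, constrained to
the searched hull — the likelihood is near-flat in `β` over a broad
range, and an unconstrained walk drifts into degenerate step-function
fits.  Seedless and reproducible.  Profile-likelihood 95% intervals use
the χ²(1) cut (drop of 1.92) on the grid profile, widened to include
the refined optimum (whose likelihood is maximal by construction).

**Identifiability.**  With realistic cohort sizes the profile in `θ` is
shallow: simulation shows the point estimate's sampling SD is roughly
0.15 at 300 patients × 3 months with a ~10% monthly event rate, and the
profile intervals are correspondingly wide (the source analysis's own
interval spans ~0.2).  Fits with a near-flat profile are flagged
`theta_weakly_identified`.  Peak-flow fits are far better identified
(thousands of continuous observations rather than hundreds of binary
ones).

## Validation

Window-level exacerbation is regressed (statsmodels `Logit`) on the
standardized adherence score with age and sex covariates (female = 1;
sample SD with denominator n − 1, so odds ratios read "per SD").  The
comparator is an AUC-style cumulative-dose metric: technique-weighted
dose received per scheduled interval, capped at one full dose per
interval so extra actuations cannot compensate for missed intervals,
averaged over the window.  This is a documented stand-in for the prior
published metric, whose exact algorithm is outside scope; it equals the
mean technique score when every interval holds exactly one dose.
Near-perfect separation is flagged rather than raised.

## The synthetic cohort generator

The generator defines the test bed: twice-daily scheduled doses over
30-day months, perturbed and thinned by behaviour, with outcomes
generated from the TAT model itself so every downstream stage has a
known ground truth.

* **Timing jitter**: normal, truncated at ±6 h so dose order cannot
  swap; default SD 1.5 h (asthma-like) or 2 h (COPD-like).
* **Missed doses**: per-patient miss probability drawn from a normal
  centred on the profile mean (default 0.3 asthma-like, 0.45 COPD-like)
  with SD 0.2, clipped to [0, 0.95] — between-patient adherence spread
  is the dominant feature of monitored cohorts and is what identifies
  the threshold at all.  `miss_persistence` turns misses into a
  two-state Markov chain (drug holidays) whose stationary rate is
  unchanged; this is the dose-timing structure that distinguishes the
  TAT metric from count-based ones.
* **Dumping**: Poisson clusters of up to 3 extra actuations within
  2 minutes; default rate 0.
* **Technique errors**: drawn per actuation from class distributions
  with ~15% any-error (asthma-like) or ~60% (COPD-like).
* **Outcomes**: monthly exacerbations `Bernoulli(expit(γ0 + γ1 A))`
  with defaults γ0 = −0.1, γ1 = −3, chosen so a typical cohort shows a
  ~10–13% monthly exacerbation frequency (matching the scale of the
  asthma training data, ~85 events across ~650 patient-months); daily
  PEFR `baseline_i + 80·smoothed_A + N(0, 25)` L/min around a
  376 L/min population mean.
* **Covariates**: age ~ N(49, 16.5) clipped to [18, 90], 64% female.

What the generator does **not** emulate: seasonal exacerbation drivers,
reliever-medication compensation, measurement error in event detection,
informative dropout, or within-patient behavioural change beyond a
linear drift option.  Passing tests therefore demonstrate internal
consistency of the pipeline under the stated behavioural model, not
clinical validity on real data.

`timing_varied_cohort` builds the sharper designed experiment in which
every patient takes exactly the same number of doses and only the
arrangement (scattered misses vs consecutive holidays) varies — the
setting in which outcomes depend on dose timing alone.
`make_fixture_suite` writes canonical fixtures, including a
regular/erratic patient pair with equal monthly dose counts whose
erratic member has a closed-form below-threshold fraction (all doses as
double actuations every 12 h for 15 days, then a 15-day gap: the only
threshold crossing is on the final decay tail).

## Known limitations

* One-compartment, instantaneous-absorption kinetics only.
* A single parameter set describes a whole cohort; no per-patient
  random effects in `θ`.
* The binary-outcome likelihood identifies `θ` weakly at realistic
  cohort sizes (see above); treat point estimates from exacerbation
  fits as accompanied by their profile intervals, not as precise.
* The AUC comparator is a stand-in, not a replication of the published
  algorithm.
* The patient-specific dose adjustment is an explicitly flagged
  extrapolation and not clinical advice.
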