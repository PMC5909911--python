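# tatscore

**Time-above-threshold effective medication adherence from
electronically monitored dose events.**

Electronic inhaler monitors record *when* each dose was taken and *how
well* (technique errors that reduce the delivered dose).  Classical
adherence measures reduce this to a dose count, which cannot tell a
patient who doses like clockwork from one who takes the same number of
doses in bursts separated by week-long gaps.  `tatscore` implements a
pharmacologically grounded alternative for clinical researchers working
with such data: reconstruct the drug concentration implied by the dose
log, and score adherence as the proportion of time the concentration
stayed above a therapeutic threshold.

## The model

Dose times `t_s` with technique scores `δ_s ∈ [0, 1]` generate a
concentration in units of the prescribed dose,

    C(t) = Σ_{t_s ≤ t} δ_s e^(−α(t−t_s)),        α = ln2 / T½,

which is passed through a sigmoidal dose–response
`σ(t) = 1/(1 + e^(−β(C(t)−θ)))` and averaged over an observation
window:

    A(α, β, θ) = (1/T) ∫₀ᵀ σ(t) dt  ∈ [0, 1].

`θ` is the threshold concentration needed to control the condition and
`β` the threshold sharpness.  These physiological parameters are fitted
by maximum likelihood so that `A` best predicts clinical outcomes
(monthly exacerbations, or daily peak expiratory flow via a lagged
moving average).  The fitted threshold then yields the dose actually
required: at a dosing interval of one half-life the required dose *is*
`θ` in units of the current dose (`δ_r = θ(1−0.5^h)/0.5^h` in general).

The package ships the pipeline end to end: event-log parsing with
technique-error scoring, concentration/score computation, fitting,
dosage derivation, logistic validation against a cumulative-dose
comparator, a synthetic-cohort simulator with known ground truth, and a
thin CLI (`score`, `fit`, `dose`, `validate`, `simulate`).

## Worked example

Two patients, each taking 60 doses in a month — one every 12 hours vs
double doses for 15 days and then nothing (`examples/score_events.py`):

```
patient    doses     TAT     AUC
regular       60   0.993   1.000
erratic       60   0.527   0.500
```

A dose counter calls these patients identical.  The TAT score (with the
adverse-event parameter set: half-life 12.4 h, β = 73, θ = 0.69) shows
the erratic patient had therapeutic cover barely half the month.

Dosage from a fitted threshold (`examples/dosing_report.py`):

```
adverse-event fit: theta = 0.69
  required dose  = 0.69 x current dose
  adjusted dose  = 0.99 x current dose (at 70% mean effective adherence)
```

— i.e. this cohort's prescription could control the condition at 69% of
the current dose under perfect adherence, and a patient who effectively
receives 70% of doses needs roughly the full current dose.  Predictive
validation on a simulated cohort whose outcomes depend on dose timing
(`examples/validate_metrics.py`):

```
seed   TAT OR   AUC OR  stronger
   0    0.764    0.840  TAT
   1    0.447    0.520  TAT
   2    0.540    0.596  TAT
   3    0.592    0.639  TAT
   4    0.551    0.608  TAT
```

Odds ratios are per standard deviation of adherence (below 1 = higher
adherence protects); the timing-aware metric carries the stronger
association.  Each `examples/` script is a few lines and prints what the
numbers mean; `docs/methods.md` documents the model, the numerical
choices and the simulator's scope.

## Command line

```sh
tatscore simulate --n-patients 100 --seed 1 --out cohort/
tatscore score cohort/events.csv --preset copd-ae --out scores/
tatscore fit cohort/events.csv cohort/outcomes.csv --out fit/
tatscore dose --theta 0.69 --h 1.0 --mean-adherence 0.7
tatscore validate cohort/events.csv cohort/outcomes.csv --out val/
```

Presets `copd-ae` (α = 0.056 /h, β = 73, θ = 0.69) and `asthma-pefr`
(α = 0.062 /h, β = 63, θ = 0.56, τ = 18.2 h) carry the two reference
parameter sets.

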