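"""Compare the TAT metric against a cumulative-dose comparator.

Simulates cohorts whose outcomes depend on dose timing (patients share
a similar miss rate but differ in how misses cluster into drug
holidays), then fits the same logistic exacerbation model with each
adherence metric as the standardized predictor.  The odds ratio is per
standard deviation of adherence: below 1 means higher adherence
protects.  The two metrics are highly correlated — on any single cohort
either may edge ahead — so the comparison is replicated: across seeds
the TAT metric, which sees the concentration consequences of gap
structure, carries the stronger association more often than not.
"""

import math

import tatscore as ts

truth = ts.COPD_AE
wins = 0
n_rep = 5
print(f"{'seed':>4}  {'TAT OR':>7}  {'AUC OR':>7}  stronger")
for seed in range(n_rep):
    profiles = ts.holiday_heterogeneous_profiles(200, seed=10 + seed)
    cohort = ts.generate_cohort(
        200, months=3, profile=profiles,
        outcome_model=ts.OutcomeModel(true_params=truth), seed=20 + seed,
    )
    tat, auc = ts.compare_metrics(cohort, truth, grid_step=0.25)
    or_t = tat.odds_ratio("standardized_adherence")
    or_a = auc.odds_ratio("standardized_adherence")
    tat_wins = abs(math.log(or_t)) >= abs(math.log(or_a))
    wins += tat_wins
    print(f"{seed:>4}  {or_t:>7.3f}  {or_a:>7.3f}  {'TAT' if tat_wins else 'AUC'}")
print(f"\nTAT carried the stronger association in {wins}/{n_rep} replicates.")
print("(The test suite replicates this twenty-fold at n = 300.)")
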