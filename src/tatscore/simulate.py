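"""Synthetic patient cohorts with realistic dosing behaviour.

The generator emulates the structure of electronically monitored inhaler
data on a twice-daily regimen: scheduled 12-hour dose times perturbed by
timing jitter, thinned by missed doses, optionally augmented by "dumping"
clusters of rapid extra actuations, with per-dose technique errors drawn
from calibrated error classes.  Outcomes are generated from the TAT model
itself: monthly exacerbations are Bernoulli draws on a logistic link of
the true monthly adherence score, and daily peak expiratory flow is a
linear function of the lag-smoothed daily score plus noise.  This defines
the test bed for the fitting and validation machinery; it is not a claim
about any real cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .events_io import DEFAULT_TECHNIQUE_RULES, delta_for_errors, write_event_log
from .model import (
    DoseEvent,
    ModelParams,
    ObservationWindow,
    PatientRecord,
    lagged_daily_scores,
    rate_from_half_life,
    windowed_scores,
)

__all__ = [
    "BehaviorProfile",
    "OutcomeModel",
    "ASTHMA_LIKE",
    "COPD_LIKE",
    "generate_cohort",
    "timing_varied_cohort",
    "holiday_heterogeneous_profiles",
    "make_fixture_suite",
    "write_outcome_table",
    "attach_outcomes",
]


@dataclass(frozen=True)
class BehaviorProfile:
    """Dosing behaviour of a simulated patient group.

    error_distribution maps tuples of technique-error labels (empty tuple
    = correct use) to probabilities summing to 1.  ``drift`` adds a linear
    per-month increment to the miss probability.  Each simulated patient
    draws an individual miss probability from a normal centred on
    ``miss_probability`` with SD ``miss_heterogeneity_sd`` (clipped to
    [0, 0.95]): between-patient adherence spread is the dominant feature
    of monitored cohorts and is what makes the threshold identifiable.

    ``miss_persistence`` makes misses cluster into drug holidays: with
    persistence rho the miss process is a two-state Markov chain with
    P(miss | missed previous) = rho + (1 - rho) * p and
    P(miss | took previous) = (1 - rho) * p, whose stationary miss rate
    is exactly p.  Patients with equal dose counts but different
    clustering then have genuinely different concentration profiles —
    the dose-timing structure a count-based metric cannot see.
    """

    miss_probability: float = 0.3
    miss_heterogeneity_sd: float = 0.2
    miss_persistence: float = 0.0
    timing_jitter_sd: float = 1.5
    dumping_rate: float = 0.0  # dumping clusters per month
    error_distribution: dict[tuple[str, ...], float] = field(
        default_factory=lambda: dict(_ASTHMA_ERRORS)
    )
    drift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_probability <= 1.0:
            raise ValueError("miss probability must lie in [0, 1]")
        if self.miss_heterogeneity_sd < 0:
            raise ValueError("miss heterogeneity SD must be >= 0")
        if not 0.0 <= self.miss_persistence < 1.0:
            raise ValueError("miss persistence must lie in [0, 1)")
        if self.timing_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.dumping_rate < 0:
            raise ValueError("dumping rate must be >= 0")
        total = sum(self.error_distribution.values())
        if abs(total - 1.0) > 1e-9 or any(
            p < 0 for p in self.error_distribution.values()
        ):
            raise ValueError("error distribution must be a probability vector")


# Error mixes for the two behavioural regimes the generator ships: an
# asthma-like cohort with errors on ~15% of uses and a COPD-like cohort
# with errors on ~60% of uses.
_ASTHMA_ERRORS: tuple[tuple[tuple[str, ...], float], ...] = (
    ((), 0.85),
    (("low_pifr",), 0.08),
    (("exhalation",), 0.04),
    (("low_pifr", "exhalation"), 0.01),
    (("no_blister",), 0.01),
    (("no_inhalation",), 0.01),
)
_COPD_ERRORS: tuple[tuple[tuple[str, ...], float], ...] = (
    ((), 0.40),
    (("low_pifr",), 0.25),
    (("exhalation",), 0.15),
    (("low_pifr", "exhalation"), 0.10),
    (("no_blister",), 0.05),
    (("no_inhalation",), 0.05),
)

ASTHMA_LIKE = BehaviorProfile(
    miss_probability=0.3,
    timing_jitter_sd=1.5,
    error_distribution=dict(_ASTHMA_ERRORS),
)
COPD_LIKE = BehaviorProfile(
    miss_probability=0.45,
    timing_jitter_sd=2.0,
    error_distribution=dict(_COPD_ERRORS),
)


@dataclass(frozen=True)
class OutcomeModel:
    """Ground-truth link from adherence to outcomes.

    Monthly exacerbation probability is expit(gamma0 + gamma1 * A) with A
    the true monthly TAT score; daily PEFR (L/min) is
    baseline_i + pefr_slope * smoothed_A + noise with a patient-specific
    baseline.  ``true_params`` is the parameter set treated as truth.
    """

    gamma0: float = -0.1
    gamma1: float = -3.0
    pefr_baseline_mean: float = 376.0
    pefr_baseline_sd: float = 100.0
    pefr_slope: float = 80.0
    pefr_noise_sd: float = 25.0
    true_params: ModelParams = field(
        default_factory=lambda: ModelParams(rate_from_half_life(12.0), 73.0, 0.56, 18.2)
    )
    include_pefr: bool = False

    def __post_init__(self) -> None:
        if self.pefr_noise_sd < 0:
            raise ValueError("PEFR noise SD must be >= 0")


JITTER_BOUND = 6.0  # hours; jitter truncated so dose order cannot swap


def _patient_events(
    rng: np.random.Generator,
    months: int,
    profile: BehaviorProfile,
    interval_hours: float,
) -> list[DoseEvent]:
    span = months * 720.0
    scheduled = np.arange(0.0, span, interval_hours)
    error_classes = list(profile.error_distribution.keys())
    error_probs = np.array(list(profile.error_distribution.values()))
    base_miss = float(np.clip(
        rng.normal(profile.miss_probability, profile.miss_heterogeneity_sd),
        0.0, 0.95,
    ))
    events: list[DoseEvent] = []
    rho = profile.miss_persistence
    missed_prev = False
    for t in scheduled:
        month = int(t // 720.0)
        miss_p = min(max(base_miss + profile.drift * month, 0.0), 1.0)
        if rho > 0:
            miss_p = rho * missed_prev + (1.0 - rho) * miss_p
        if rng.random() < miss_p:
            missed_prev = True
            continue
        missed_prev = False
        jitter = rng.normal(0.0, profile.timing_jitter_sd) if profile.timing_jitter_sd else 0.0
        jitter = float(np.clip(jitter, -JITTER_BOUND, JITTER_BOUND))
        time = float(np.clip(t + jitter, 0.0, span - 1e-6))
        labels = error_classes[rng.choice(len(error_classes), p=error_probs)]
        delta = delta_for_errors(labels, DEFAULT_TECHNIQUE_RULES)
        events.append(DoseEvent(time=time, delta=delta, error_labels=labels))
    if profile.dumping_rate > 0:
        n_dumps = rng.poisson(profile.dumping_rate * months)
        for _ in range(n_dumps):
            anchor = float(rng.uniform(0.0, span - 0.1))
            for k in range(int(rng.integers(1, 4))):  # <= 3 extra actuations
                time = min(anchor + k * (2.0 / 60.0 / 3.0), span - 1e-6)
                labels = error_classes[rng.choice(len(error_classes), p=error_probs)]
                events.append(
                    DoseEvent(
                        time=time,
                        delta=delta_for_errors(labels, DEFAULT_TECHNIQUE_RULES),
                        error_labels=labels,
                    )
                )
    return sorted(events, key=lambda e: e.time)


def generate_cohort(
    n_patients: int,
    months: int = 3,
    profile: BehaviorProfile | Sequence[BehaviorProfile] = ASTHMA_LIKE,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    interval_hours: float = 12.0,
    grid_step: float = 0.25,
    burn_in_hours: float = 48.0,
) -> list[PatientRecord]:
    """Simulate a cohort of patients with events, outcomes and covariates.

    ``profile`` may be a single behaviour profile or one per patient.
    Outcomes are generated from ``outcome_model`` (defaults to the
    standard link) using the model's own true parameters; reproducible
    for a given seed.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    om = outcome_model or OutcomeModel()
    rng = np.random.default_rng(seed)
    if isinstance(profile, BehaviorProfile):
        profiles = [profile] * n_patients
    else:
        profiles = list(profile)
        if len(profiles) != n_patients:
            raise ValueError("need one behaviour profile per patient")
    span = ObservationWindow(0.0, months * 720.0)
    cohort: list[PatientRecord] = []
    for i in range(n_patients):
        events = _patient_events(rng, months, profiles[i], interval_hours)
        age = float(np.clip(rng.normal(49.2, 16.5), 18.0, 90.0))
        sex = int(rng.random() < 0.64)  # female = 1
        rec = PatientRecord(
            patient_id=f"P{i:04d}",
            events=events,
            monitoring_span=span,
            age=age,
            sex=sex,
        )
        _draw_outcomes(rng, rec, om, grid_step, burn_in_hours)
        cohort.append(rec)
    return cohort


def holiday_heterogeneous_profiles(
    n_patients: int,
    seed: int,
    miss_probability: float = 0.35,
    miss_heterogeneity_sd: float = 0.05,
    max_persistence: float = 0.95,
    max_jitter_sd: float = 5.0,
    copd_errors: bool = True,
) -> list[BehaviorProfile]:
    """Profiles for a timing-sensitive validation cohort.

    Patients share a similar overall miss rate but differ widely in how
    their misses cluster into drug holidays (persistence drawn uniformly
    up to ``max_persistence``) and in dose-timing regularity (jitter SD
    drawn uniformly up to ``max_jitter_sd``), with the high technique-error
    mix of a COPD-like population.  Under this behaviour, outcomes
    generated from the TAT model depend on dose timing in ways a
    cumulative-dose metric cannot represent.
    """
    rng = np.random.default_rng(seed)
    errors = dict(_COPD_ERRORS) if copd_errors else dict(_ASTHMA_ERRORS)
    return [
        BehaviorProfile(
            miss_probability=miss_probability,
            miss_heterogeneity_sd=miss_heterogeneity_sd,
            miss_persistence=float(rng.uniform(0.0, max_persistence)),
            timing_jitter_sd=float(rng.uniform(0.3, max_jitter_sd)),
            error_distribution=errors,
        )
        for _ in range(n_patients)
    ]


def _draw_outcomes(
    rng: np.random.Generator,
    rec: PatientRecord,
    om: OutcomeModel,
    grid_step: float,
    burn_in_hours: float,
) -> None:
    """Attach simulated outcomes to a record from its true TAT scores."""
    scores = windowed_scores(
        rec, om.true_params, grid_step=grid_step, burn_in_hours=burn_in_hours
    )
    a = np.array([s.value for s in scores if not s.partial])
    p = expit(om.gamma0 + om.gamma1 * a)
    rec.exacerbations = [int(rng.random() < pi) for pi in p]
    if om.include_pefr:
        daily = lagged_daily_scores(rec, om.true_params, grid_step=grid_step)
        baseline = rng.normal(om.pefr_baseline_mean, om.pefr_baseline_sd)
        noise = rng.normal(0.0, om.pefr_noise_sd, size=daily.smoothed.size)
        rec.pefr = baseline + om.pefr_slope * daily.smoothed + noise


def timing_varied_cohort(
    n_patients: int,
    months: int = 3,
    miss_fraction: float = 0.3,
    block_range: tuple[int, int] = (1, 10),
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    interval_hours: float = 12.0,
    grid_step: float = 0.25,
    burn_in_hours: float = 48.0,
) -> list[PatientRecord]:
    """Cohort in which dose counts are equal and only dose timing varies.

    Every patient misses exactly ``round(miss_fraction * doses_per_month)``
    scheduled doses per month, but the misses are arranged in consecutive
    runs whose typical length is patient-specific (drawn uniformly from
    ``block_range``): scattered single misses at one extreme, week-long
    drug holidays at the other.  A cumulative-dose metric sees these
    patients as identical; their concentration profiles — and hence
    outcomes generated from the TAT model — differ systematically.
    """
    om = outcome_model or OutcomeModel()
    rng = np.random.default_rng(seed)
    per_month = int(round(720.0 / interval_hours))
    n_miss = int(round(miss_fraction * per_month))
    span = ObservationWindow(0.0, months * 720.0)
    error_classes = list(_ASTHMA_ERRORS)
    labels_list = [c[0] for c in error_classes]
    probs = np.array([c[1] for c in error_classes])
    cohort: list[PatientRecord] = []
    for i in range(n_patients):
        block = int(rng.integers(block_range[0], block_range[1] + 1))
        events: list[DoseEvent] = []
        for m in range(months):
            missed: set[int] = set()
            while len(missed) < n_miss:
                start = int(rng.integers(0, per_month))
                for k in range(start, min(start + block, per_month)):
                    if len(missed) < n_miss:
                        missed.add(k)
            for k in range(per_month):
                if k in missed:
                    continue
                jitter = float(np.clip(rng.normal(0.0, 1.5), -JITTER_BOUND, JITTER_BOUND))
                t = float(np.clip(m * 720.0 + k * interval_hours + jitter,
                                  0.0, months * 720.0 - 1e-6))
                labels = labels_list[rng.choice(len(labels_list), p=probs)]
                events.append(DoseEvent(
                    time=t,
                    delta=delta_for_errors(labels, DEFAULT_TECHNIQUE_RULES),
                    error_labels=labels,
                ))
        rec = PatientRecord(
            patient_id=f"T{i:04d}",
            events=sorted(events, key=lambda e: e.time),
            monitoring_span=span,
            age=float(np.clip(rng.normal(49.2, 16.5), 18.0, 90.0)),
            sex=int(rng.random() < 0.64),
        )
        _draw_outcomes(rng, rec, om, grid_step, burn_in_hours)
        cohort.append(rec)
    return cohort


def write_outcome_table(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write per-window outcomes and covariates as CSV."""
    rows = []
    for rec in cohort:
        if rec.exacerbations is None:
            continue
        for w, y in enumerate(rec.exacerbations):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "window": w,
                    "exacerbation": int(y),
                    "age": rec.age,
                    "sex": rec.sex,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def attach_outcomes(
    records: Sequence[PatientRecord], outcomes: pd.DataFrame | str | Path
) -> list[PatientRecord]:
    """Merge an outcome table (patient_id, window, exacerbation, age, sex)
    into parsed records; patients without outcome rows keep ``None``."""
    if not isinstance(outcomes, pd.DataFrame):
        outcomes = pd.read_csv(outcomes, dtype={"patient_id": str})
    out = []
    for rec in records:
        rows = outcomes[outcomes["patient_id"] == rec.patient_id].sort_values("window")
        if rows.empty:
            out.append(rec)
            continue
        rec.exacerbations = [int(v) for v in rows["exacerbation"]]
        if "age" in rows and rows["age"].notna().any():
            rec.age = float(rows["age"].iloc[0])
        if "sex" in rows and rows["sex"].notna().any():
            rec.sex = int(rows["sex"].iloc[0])
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Canonical fixtures


def _regular_events(months: int) -> list[DoseEvent]:
    return [DoseEvent(t) for t in np.arange(0.0, months * 720.0, 12.0)]


def _erratic_events(months: int) -> list[DoseEvent]:
    """Erratic (dumping-style) pattern with the regular pattern's monthly
    dose count: all 60 doses of a month are taken as double actuations
    every 12 h for the first 15 days, then nothing for 15 days."""
    events: list[DoseEvent] = []
    for m in range(months):
        base = m * 720.0
        for k in range(30):
            events.append(DoseEvent(base + k * 12.0))
            events.append(DoseEvent(base + k * 12.0 + 0.02))
    return events


def _erratic_below_fraction(params: ModelParams) -> float:
    """Exact below-threshold fraction of the erratic fixture's first month
    under a step threshold (theta < 1), from the piecewise-exponential
    curve: during the double-dose phase the trough never falls below one
    prescribed-dose unit, so the only crossing is on the decay tail after
    the final pair."""
    alpha, theta = params.alpha, params.theta
    if not theta < 1.0:
        raise ValueError("construction assumes theta < 1")
    events = _erratic_events(1)
    last = events[-1].time
    c_end = sum(e.delta * math.exp(-alpha * (last - e.time)) for e in events)
    cross = last + math.log(c_end / theta) / alpha
    return (720.0 - cross) / 720.0


def make_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical CSV fixtures used across the test suite.

    Produces a regular/erratic patient pair with equal monthly dose
    counts, a two-patient parse fixture with technique errors, a
    300-patient recovery cohort (events + outcomes), and a manifest with
    the erratic fixture's analytically constructed below-threshold
    fraction.  Deterministic: the same seed reproduces identical bytes.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    months = 1
    span = ObservationWindow(0.0, months * 720.0)
    regular = PatientRecord("regular", _regular_events(months), span)
    erratic = PatientRecord("erratic", _erratic_events(months), span)
    paths: dict[str, Path] = {}
    paths["contrast_events"] = out / "contrast_events.csv"
    write_event_log([regular, erratic], paths["contrast_events"])

    parse_rows = []
    base = pd.Timestamp("2000-01-01T08:00:00")
    labels = ["", "low_pifr", "exhalation", "low_pifr;exhalation"]
    for pid in ("A01", "A02"):
        for k in range(4):
            parse_rows.append(
                {
                    "patient_id": pid,
                    "timestamp": (base + pd.Timedelta(hours=12 * k)).isoformat(),
                    "error_labels": labels[k],
                }
            )
    paths["parse_fixture"] = out / "parse_fixture.csv"
    pd.DataFrame(parse_rows).to_csv(paths["parse_fixture"], index=False)

    truth = ModelParams(rate_from_half_life(12.0), 73.0, 0.6)
    cohort = generate_cohort(
        300, months=3, outcome_model=OutcomeModel(true_params=truth), seed=seed
    )
    paths["recovery_events"] = out / "recovery_events.csv"
    paths["recovery_outcomes"] = out / "recovery_outcomes.csv"
    write_event_log(cohort, paths["recovery_events"])
    write_outcome_table(cohort, paths["recovery_outcomes"])

    step_params = ModelParams(rate_from_half_life(12.0), 5000.0, 0.56)
    manifest = {
        "seed": seed,
        "recovery_true_params": {
            "half_life": 12.0, "beta": 73.0, "theta": 0.6,
        },
        "erratic_below_threshold_fraction": _erratic_below_fraction(step_params),
        "erratic_params": {"half_life": 12.0, "theta": 0.56},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
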