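import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tatscore as ts

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

LN2 = math.log(2.0)


@pytest.fixture(scope="session")
def ae_params() -> ts.ModelParams:
    """Adverse-event-rate parameter set (half-life 12.4 h, beta 73, theta 0.69)."""
    return ts.COPD_AE


@pytest.fixture(scope="session")
def asthma_params() -> ts.ModelParams:
    """Peak-flow parameter set (half-life 11.2 h, beta 63, theta 0.56, tau 18.2)."""
    return ts.ASTHMA_PEFR


@pytest.fixture(scope="session")
def perfect_patient() -> ts.PatientRecord:
    """One month of perfect twice-daily dosing."""
    events = [ts.DoseEvent(t) for t in np.arange(0.0, 720.0, 12.0)]
    return ts.PatientRecord("perfect", events, ts.ObservationWindow(0.0, 720.0))


@pytest.fixture(scope="session")
def small_cohort() -> list[ts.PatientRecord]:
    """Sixty simulated patients over three months, default behaviour."""
    truth = ts.ModelParams(ts.rate_from_half_life(12.0), 73.0, 0.6)
    return ts.generate_cohort(
        60, months=3, outcome_model=ts.OutcomeModel(true_params=truth), seed=11
    )


def brute_force_concentration(events, alpha, grid):
    """Quadratic-time reference for the concentration sum."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for e in events:
        mask = grid >= e.time
        out[mask] += e.delta * np.exp(-alpha * (grid[mask] - e.time))
    return out


def step_threshold_above_measure(events, alpha, theta, start, end):
    """Exact measure of {t in [start, end] : C(t) > theta} for few doses.

    Between dose instants the curve decays monotonically, so each segment
    holds at most one downward crossing, solvable in closed form.
    """
    assert theta > 0
    breaks = sorted({start, end, *[e.time for e in events if start < e.time < end]})
    above = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        c0 = sum(
            e.delta * math.exp(-alpha * (a - e.time)) for e in events if e.time <= a
        )
        if c0 > theta:
            above += min(b - a, math.log(c0 / theta) / alpha)
    return above
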