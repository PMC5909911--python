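"""Core time-above-threshold (TAT) adherence model.

The model turns a log of precisely-timed dose events into an *effective
adherence* score.  Each dose event carries a technique score ``delta``
(fraction of the full dose actually received).  Dose events are convolved
with a one-compartment exponential decay to give a drug concentration
curve ``C(t)`` in units of the prescribed dose, the curve is passed through
a sigmoidal threshold function, and the sigmoid output is averaged over an
observation window to give the proportion of time the concentration spends
above the therapeutic threshold — a number between 0 and 1.

Concentration model::

    C(t) = sum_{t_s <= t} delta_s * exp(-alpha * (t - t_s))

with ``alpha = ln 2 / T_half``.  Threshold response::

    sigma(t) = 1 / (1 + exp(-beta * (C(t) - theta)))

Adherence score over a window of length ``T``::

    A = (1/T) * integral_0^T sigma(t) dt
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

__all__ = [
    "DoseEvent",
    "ObservationWindow",
    "ModelParams",
    "ConcentrationCurve",
    "AdherenceScore",
    "PatientRecord",
    "DailyAdherence",
    "rate_from_half_life",
    "half_life_from_rate",
    "concentration",
    "threshold_response",
    "time_above_threshold",
    "windowed_scores",
    "lagged_daily_scores",
]

LN2 = math.log(2.0)

#: Default integration step for the trapezoidal evaluation of the adherence
#: integral, in hours (6 minutes).
DEFAULT_GRID_STEP = 0.1

#: Exponent clip applied before the logistic: at ±745 the logistic
#: saturates to exactly 0 or 1 in double precision without overflow.
_EXP_CLIP = 745.0


@dataclass(frozen=True)
class DoseEvent:
    """One inhaler actuation.

    Parameters
    ----------
    time:
        Hours since the start of observation (non-negative, finite).
    delta:
        Technique score: fraction of the full dose effectively received,
        in [0, 1].  1.0 for a correctly taken dose.
    error_labels:
        Technique-error identifiers attached to this actuation (empty for
        correct use).
    """

    time: float
    delta: float = 1.0
    error_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        object.__setattr__(self, "error_labels", tuple(self.error_labels))


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open scoring window [start, end), in hours."""

    start: float
    end: float
    label: object = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(
                f"window must have end > start, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ModelParams:
    """Physiological parameters of the TAT model.

    alpha : drug decay rate per hour (> 0); half-life is ln2/alpha.
    beta  : threshold sharpness (> 0); large beta approximates a step.
    theta : threshold concentration in units of the prescribed dose (>= 0).
    tau   : outcome lag in hours (>= 0); used only when smoothing daily
            scores against peak-flow outcomes.
    """

    alpha: float
    beta: float
    theta: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    @property
    def half_life(self) -> float:
        return half_life_from_rate(self.alpha)

    @classmethod
    def from_half_life(
        cls, half_life: float, beta: float, theta: float, tau: float = 0.0
    ) -> "ModelParams":
        return cls(rate_from_half_life(half_life), beta, theta, tau)


@dataclass
class ConcentrationCurve:
    """Sampled concentration C(t), in units of the prescribed dose."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentration values must be non-negative")


@dataclass(frozen=True)
class AdherenceScore:
    """A time-above-threshold score for one window."""

    value: float
    window: ObservationWindow
    params: ModelParams
    partial: bool = False

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError(f"adherence score must lie in [0, 1], got {self.value}")


@dataclass
class PatientRecord:
    """Events, monitoring span, outcomes and covariates for one patient.

    ``sex`` uses the indicator coding female = 1.  ``exacerbations`` holds
    one binary indicator per consecutive 30-day window of the monitoring
    span; ``pefr`` holds one peak-expiratory-flow reading (L/min) per day.
    """

    patient_id: str
    events: list[DoseEvent]
    monitoring_span: ObservationWindow
    age: float | None = None
    sex: int | None = None
    exacerbations: list[int] | None = None
    pefr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        end = self.monitoring_span.end
        if any(e.time > end for e in self.events):
            raise ValueError(
                f"patient {self.patient_id}: events after monitoring span end"
            )
        if self.pefr is not None:
            self.pefr = np.asarray(self.pefr, dtype=float)

    @property
    def event_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def event_deltas(self) -> np.ndarray:
        return np.array([e.delta for e in self.events], dtype=float)


# ---------------------------------------------------------------------------
# Half-life algebra


def rate_from_half_life(half_life: float) -> float:
    """Decay rate per hour for a given half-life in hours (alpha = ln2 / T½)."""
    if not half_life > 0:
        raise ValueError(f"half-life must be > 0, got {half_life}")
    return LN2 / half_life


def half_life_from_rate(alpha: float) -> float:
    """Half-life in hours for a given decay rate per hour (T½ = ln2 / alpha)."""
    if not alpha > 0:
        raise ValueError(f"decay rate must be > 0, got {alpha}")
    return LN2 / alpha


# ---------------------------------------------------------------------------
# Concentration


def _as_event_arrays(events: Sequence[DoseEvent]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([e.time for e in events], dtype=float)
    deltas = np.array([e.delta for e in events], dtype=float)
    if np.any(deltas < 0):
        raise ValueError("dose events must have non-negative delta")
    order = np.argsort(times, kind="stable")
    return times[order], deltas[order]


def _concentration_values(
    times: np.ndarray,
    deltas: np.ndarray,
    alpha: float,
    grid: np.ndarray,
    chunk: int = 4096,
) -> np.ndarray:
    """Evaluate sum_{t_s <= t} delta_s exp(-alpha (t - t_s)) on a sorted grid.

    Uses a chunked cumulative-sum recurrence: within a chunk anchored at g0,
    C(g) = exp(-alpha (g - g0)) * (carry + cumsum of delta_s exp(alpha (t_s - g0)))
    so cost is O(n_events + n_grid) and exponents stay bounded by the chunk
    span, avoiding both quadratic work and overflow.
    """
    n = grid.size
    out = np.empty(n, dtype=float)
    if times.size == 0:
        out.fill(0.0)
        return out
    # Fold events strictly before the grid into the initial carry.
    pre = int(np.searchsorted(times, grid[0], side="left"))
    carry = float(np.sum(deltas[:pre] * np.exp(-alpha * (grid[0] - times[:pre]))))
    lo = pre
    prev_last = grid[0]
    start = 0
    first = True
    while start < n:
        stop = min(start + chunk, n)
        g = grid[start:stop]
        g0 = g[0]
        if not first:
            carry *= math.exp(-alpha * (g0 - prev_last))
        hi = int(np.searchsorted(times, g[-1], side="right"))
        ts = times[lo:hi]
        w = deltas[lo:hi] * np.exp(alpha * (ts - g0))
        cw = np.concatenate(([0.0], np.cumsum(w)))
        idx = np.searchsorted(ts, g, side="right")
        out[start:stop] = np.exp(-alpha * (g - g0)) * (carry + cw[idx])
        carry = float(out[stop - 1])
        prev_last = g[-1]
        lo = hi
        start = stop
        first = False
    np.maximum(out, 0.0, out=out)
    return out


def concentration(
    events: Sequence[DoseEvent], alpha: float, grid: np.ndarray
) -> ConcentrationCurve:
    """Drug concentration curve from dose events.

    Each dose contributes ``delta`` units of prescribed dose at its instant
    and decays exponentially at rate ``alpha``; contributions are additive.
    Doses at or before a grid point contribute to it.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a 1-D array with at least one point")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    times, deltas = _as_event_arrays(events)
    values = _concentration_values(times, deltas, alpha, grid)
    return ConcentrationCurve(grid=grid, values=values)


def threshold_response(
    curve: ConcentrationCurve | np.ndarray, beta: float, theta: float
) -> np.ndarray:
    """Sigmoidal dose-response of a concentration curve.

    Returns sigma = 1 / (1 + exp(-beta (C - theta))) elementwise; the
    exponent is clipped so extreme concentrations saturate to exactly 0 or 1
    without overflow.
    """
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    values = curve.values if isinstance(curve, ConcentrationCurve) else np.asarray(curve, dtype=float)
    z = np.clip(beta * (values - theta), -_EXP_CLIP, _EXP_CLIP)
    return expit(z)


# ---------------------------------------------------------------------------
# Time-above-threshold scores


def _window_grid(window: ObservationWindow, grid_step: float) -> np.ndarray:
    if not grid_step > 0:
        raise ValueError(f"grid step must be > 0, got {grid_step}")
    n = max(2, int(round(window.length / grid_step)) + 1)
    return np.linspace(window.start, window.end, n)


def time_above_threshold(
    events: Sequence[DoseEvent],
    params: ModelParams,
    window: ObservationWindow,
    grid_step: float = DEFAULT_GRID_STEP,
    partial: bool = False,
) -> AdherenceScore:
    """Adherence score A = (1/T) ∫ sigma(t) dt over the window.

    Doses before ``window.start`` contribute residual concentration.  The
    integral is evaluated by the trapezoidal rule on a uniform grid
    (default step 0.1 h).
    """
    grid = _window_grid(window, grid_step)
    curve = concentration(events, params.alpha, grid)
    sigma = threshold_response(curve, params.beta, params.theta)
    value = float(np.trapezoid(sigma, grid) / window.length)
    value = min(max(value, 0.0), 1.0)
    return AdherenceScore(value=value, window=window, params=params, partial=partial)


def windowed_scores(
    record: PatientRecord,
    params: ModelParams,
    window_length: float = 720.0,
    grid_step: float = DEFAULT_GRID_STEP,
    burn_in_hours: float = 0.0,
) -> list[AdherenceScore]:
    """Consecutive TAT scores over the patient's monitoring span.

    The span is cut into consecutive windows of ``window_length`` hours
    (default 30 days) from the monitoring start; a final partial window is
    scored over its actual length and flagged.  ``burn_in_hours`` shrinks
    the first scoring window from the left, so the inevitable below-threshold
    stretch before the first doses accumulate does not read as non-adherence.
    """
    if not window_length > 0:
        raise ValueError(f"window length must be > 0, got {window_length}")
    if burn_in_hours < 0:
        raise ValueError(f"burn-in must be >= 0, got {burn_in_hours}")
    span = record.monitoring_span
    scores: list[AdherenceScore] = []
    start = span.start
    index = 0
    while start < span.end - 1e-9:
        end = min(start + window_length, span.end)
        partial = (end - start) < window_length - 1e-9
        score_start = start
        if index == 0 and burn_in_hours > 0:
            score_start = min(start + burn_in_hours, end - grid_step)
        window = ObservationWindow(score_start, end, label=index)
        scores.append(
            time_above_threshold(
                record.events, params, window, grid_step=grid_step, partial=partial
            )
        )
        start += window_length
        index += 1
    return scores


# ---------------------------------------------------------------------------
# Daily scores and lagged smoothing


@dataclass
class DailyAdherence:
    """Per-day adherence with a trailing exponentially-weighted average.

    ``days`` holds the day index (0-based from monitoring start), ``raw``
    the 24-hour TAT scores and ``smoothed`` the trailing average whose mean
    lag is the model's tau.
    """

    days: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray


def exponential_moving_average(
    series: np.ndarray, tau: float, spacing: float = 24.0
) -> np.ndarray:
    """Trailing exponential average with kernel exp(-t/tau)/tau.

    The continuous kernel is sampled at the series spacing (default one
    day) and renormalised over the available history, so early points are
    averages of the partial kernel rather than biased toward zero.
    tau = 0 returns the series unchanged.  Accepts a matrix and smooths
    along the last axis.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    series = np.asarray(series, dtype=float)
    if tau == 0.0:
        return series.copy()
    lam = math.exp(-spacing / tau)
    num = lfilter([1.0], [1.0, -lam], series, axis=-1)
    den = lfilter([1.0], [1.0, -lam], np.ones(series.shape[-1]))
    return num / den


def lagged_daily_scores(
    record: PatientRecord,
    params: ModelParams,
    grid_step: float = DEFAULT_GRID_STEP,
) -> DailyAdherence:
    """Daily (24 h) adherence scores and their tau-lagged moving average.

    Used when relating adherence to daily outcomes such as peak expiratory
    flow: the trailing exponential average with mean lag ``params.tau``
    represents the delayed physiological response to recent dosing.
    """
    span = record.monitoring_span
    n_days = int(math.floor((span.end - span.start) / 24.0 + 1e-9))
    if n_days < 1:
        raise ValueError("monitoring span shorter than one day")
    grid = np.linspace(span.start, span.start + 24.0 * n_days,
                       int(round(24.0 * n_days / grid_step)) + 1)
    curve = concentration(record.events, params.alpha, grid)
    sigma = threshold_response(curve, params.beta, params.theta)
    per_day = int(round(24.0 / grid_step))
    raw = np.empty(n_days)
    for d in range(n_days):
        seg = slice(d * per_day, (d + 1) * per_day + 1)
        raw[d] = np.trapezoid(sigma[seg], grid[seg]) / 24.0
    smoothed = exponential_moving_average(raw, params.tau)
    return DailyAdherence(days=np.arange(n_days), raw=raw, smoothed=smoothed)
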