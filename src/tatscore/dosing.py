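"""Required and patient-adjusted dosage from a fitted threshold.

Under perfect adherence at a fixed interval, the steady-state trough of
the exponential-decay concentration model equals theta exactly when each
dose is

    delta_r = theta * (1 - 0.5**h) / 0.5**h

where ``h`` is the dosing interval in units of the drug's half-life.  At
h = 1 (doses one half-life apart, the usual twice-daily regimen for a
~12 h half-life) this reduces to delta_r = theta: the threshold is
directly the fraction of the current prescribed dose needed to maintain
health.  All doses here are in units of the current prescribed dose; no
drug-specific mass conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DoseRecommendation",
    "required_dose",
    "steady_state_extremes",
    "adjusted_dose",
    "recommend",
]


@dataclass(frozen=True)
class DoseRecommendation:
    """A dosing report: threshold, interval, required and adjusted dose.

    ``adjusted_dose`` compensates for a patient's mean effective adherence
    by dividing the required dose by it (a documented extrapolation, not a
    clinical prescription); ``capped`` flags that the safety cap bound it.
    """

    theta: float
    h: float
    required_dose: float
    adjusted_dose: float | None = None
    mean_adherence: float | None = None
    capped: bool = False
    adjustment_rule: str = "required_dose / mean_adherence, capped"

    def __post_init__(self) -> None:
        if self.required_dose < 0:
            raise ValueError("required dose must be >= 0")
        if not self.h > 0:
            raise ValueError("h must be > 0")


def required_dose(theta: float, h: float) -> float:
    """Per-administration dose whose steady-state trough equals theta.

    Parameters
    ----------
    theta:
        Threshold concentration, units of the current prescribed dose.
    h:
        Dosing interval in half-lives (interval / T½).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if not h > 0:
        raise ValueError(f"h must be > 0, got {h}")
    decay = 0.5 ** h
    return theta * (1.0 - decay) / decay


def steady_state_extremes(dose: float, h: float) -> tuple[float, float]:
    """Steady-state (peak, trough) under perfect adherence.

    Repeated doses of size ``dose`` every ``h`` half-lives accumulate to a
    geometric series: peak = dose / (1 - 0.5**h) just after a dose, trough
    = peak * 0.5**h just before the next.  The trough equals theta exactly
    when dose = required_dose(theta, h).
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if not h > 0:
        raise ValueError(f"h must be > 0, got {h}")
    decay = 0.5 ** h
    peak = dose / (1.0 - decay)
    return peak, peak * decay


def adjusted_dose(
    theta: float,
    h: float,
    mean_adherence: float,
    cap: float | None = 2.0,
) -> tuple[float, bool]:
    """Patient-specific dose given mean effective adherence.

    Default rule: required_dose / mean_adherence — a patient who on
    average receives half their doses effectively needs twice the dose per
    administration to maintain the same trough.  The result is capped at
    ``cap`` times the current dose (None disables the cap).  Returns
    (dose, capped_flag).
    """
    if not 0.0 < mean_adherence <= 1.0:
        raise ValueError(
            f"mean adherence must lie in (0, 1]; no finite dose compensates "
            f"for {mean_adherence}"
        )
    dose = required_dose(theta, h) / mean_adherence
    if cap is not None and dose > cap:
        return cap, True
    return dose, False


def recommend(
    theta: float,
    h: float = 1.0,
    mean_adherence: float | None = None,
    cap: float | None = 2.0,
) -> DoseRecommendation:
    """Assemble a full dosing recommendation report."""
    req = required_dose(theta, h)
    adj = None
    capped = False
    if mean_adherence is not None:
        adj, capped = adjusted_dose(theta, h, mean_adherence, cap=cap)
    return DoseRecommendation(
        theta=theta,
        h=h,
        required_dose=req,
        adjusted_dose=adj,
        mean_adherence=mean_adherence,
        capped=capped,
    )
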