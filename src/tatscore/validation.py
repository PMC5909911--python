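"""Predictive-validity analysis: logistic regression of exacerbations.

Window-level binary exacerbation indicators are regressed on a
standardized adherence score with age and sex covariates, reporting odds
ratios (per standard deviation of adherence), Wald 95% confidence
intervals and p-values.  Two metrics are compared on identical windows:
the TAT score, and a cumulative-dose "AUC-style" comparator that weights
doses by technique and caps each scheduled interval at one full dose, so
extra actuations cannot make up for missed intervals.  The comparator is
a documented stand-in for the prior art, not a bit-exact replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .events_io import DEFAULT_TECHNIQUE_RULES, TechniqueRule
from .model import (
    ModelParams,
    ObservationWindow,
    PatientRecord,
    windowed_scores,
)

__all__ = [
    "RegressionReport",
    "standardize",
    "logistic_validation",
    "auc_comparator",
    "compare_metrics",
    "cohort_window_table",
]


@dataclass
class RegressionReport:
    """Odds ratios, Wald 95% CIs and p-values for one logistic fit.

    ``table`` has one row per variable (plus intercept) with columns
    odds_ratio, ci_low, ci_high, p.  Sex is coded female = 1.
    """

    metric: str
    table: pd.DataFrame
    n_obs: int
    log_likelihood: float
    separation: bool = False
    notes: dict = field(default_factory=dict)

    def odds_ratio(self, variable: str) -> float:
        return float(self.table.loc[variable, "odds_ratio"])


def standardize(scores: Sequence[float]) -> np.ndarray:
    """Z-scores with sample standard deviation (denominator n - 1).

    Odds ratios on a standardized predictor read as "per SD increase".
    Raises on constant input, where no scale exists.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standardize requires at least two distinct values")
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


def logistic_validation(
    windows: pd.DataFrame,
    predictor: str = "adherence",
    covariates: Sequence[str] = ("age", "sex"),
    metric_label: str = "TAT",
    cluster_by: str | None = None,
    standardize_predictor: bool = True,
) -> RegressionReport:
    """Maximum-likelihood logistic regression of exacerbation on adherence.

    ``windows`` must carry an ``exacerbation`` column (binary, both
    classes present) plus the predictor and covariates; the predictor is
    standardized by default.  ``cluster_by`` names a column for
    cluster-robust (per-patient) variance.  Near-perfect separation is
    flagged rather than raised.
    """
    required = {"exacerbation", predictor, *covariates}
    missing = required - set(windows.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    y = windows["exacerbation"].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("exacerbation must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("exacerbation has no variation")

    design = pd.DataFrame(index=windows.index)
    label = f"standardized_{predictor}" if standardize_predictor else predictor
    design[label] = (
        standardize(windows[predictor]) if standardize_predictor
        else windows[predictor].to_numpy(dtype=float)
    )
    for cov in covariates:
        design[cov] = windows[cov].to_numpy(dtype=float)
    design = sm.add_constant(design, prepend=False)

    model = sm.Logit(y, design)
    fit_kwargs: dict = {"disp": 0, "maxiter": 200}
    if cluster_by is not None:
        fit_kwargs["cov_type"] = "cluster"
        fit_kwargs["cov_kwds"] = {"groups": windows[cluster_by].to_numpy()}
    result = model.fit(**fit_kwargs)

    coefs = result.params
    ci = result.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(coefs),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": result.pvalues,
        }
    )
    table.index = [("Intercept" if v == "const" else v) for v in design.columns]
    separation = bool(np.any(np.abs(coefs) > 15) or not result.mle_retvals.get("converged", True))
    return RegressionReport(
        metric=metric_label,
        table=table,
        n_obs=int(y.size),
        log_likelihood=float(result.llf),
        separation=separation,
        notes={"sex_coding": "female=1", "cluster_by": cluster_by},
    )


def auc_comparator(
    record: PatientRecord,
    window: ObservationWindow,
    interval_hours: float = 12.0,
    rules: Sequence[TechniqueRule] = DEFAULT_TECHNIQUE_RULES,
) -> float:
    """Technique-weighted cumulative-dose adherence for one window.

    The window is cut into scheduled intervals (default 12 h); each
    interval receives the sum of technique scores of the doses taken in
    it, capped at one full dose, and the score is the mean over
    intervals.  Equals the mean technique delta when every interval holds
    exactly one dose; extra doses cannot compensate missed intervals.
    """
    n_intervals = int(round(window.length / interval_hours))
    if n_intervals < 1:
        raise ValueError("window shorter than one scheduled interval")
    received = np.zeros(n_intervals)
    for event in record.events:
        if window.start <= event.time < window.end:
            k = min(int((event.time - window.start) / interval_hours), n_intervals - 1)
            received[k] += event.delta
    np.minimum(received, 1.0, out=received)
    return float(received.mean())


def cohort_window_table(
    cohort: Sequence[PatientRecord],
    params: ModelParams,
    window_length: float = 720.0,
    interval_hours: float = 12.0,
    grid_step: float = 0.1,
    burn_in_hours: float = 48.0,
) -> pd.DataFrame:
    """Patient-month table with both adherence metrics and outcomes.

    One row per complete window: patient_id, window index, TAT score, AUC
    comparator score, exacerbation, age, sex.
    """
    rows = []
    for rec in cohort:
        scores = windowed_scores(
            rec, params, window_length=window_length,
            grid_step=grid_step, burn_in_hours=burn_in_hours,
        )
        for w, score in enumerate(scores):
            if score.partial:
                continue
            if rec.exacerbations is None or w >= len(rec.exacerbations):
                continue
            span = rec.monitoring_span
            window = ObservationWindow(
                span.start + w * window_length,
                span.start + (w + 1) * window_length,
                label=w,
            )
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "window": w,
                    "adherence_tat": score.value,
                    "adherence_auc": auc_comparator(
                        rec, window, interval_hours=interval_hours
                    ),
                    "exacerbation": int(rec.exacerbations[w]),
                    "age": rec.age,
                    "sex": rec.sex,
                }
            )
    return pd.DataFrame(rows)


def compare_metrics(
    cohort: Sequence[PatientRecord],
    params: ModelParams,
    window_length: float = 720.0,
    interval_hours: float = 12.0,
    covariates: Sequence[str] = ("age", "sex"),
    cluster_by: str | None = None,
    grid_step: float = 0.1,
    burn_in_hours: float = 48.0,
) -> tuple[RegressionReport, RegressionReport]:
    """Side-by-side logistic validation of the TAT and AUC metrics.

    Both metrics are computed on identical patient-month windows and fed
    through the same logistic model; returns (TAT report, AUC report).
    """
    table = cohort_window_table(
        cohort, params, window_length=window_length,
        interval_hours=interval_hours, grid_step=grid_step,
        burn_in_hours=burn_in_hours,
    )
    if table.empty:
        raise ValueError("no complete windows with outcomes in the cohort")
    usable = [c for c in covariates if table[c].notna().all()]
    tat = logistic_validation(
        table.rename(columns={"adherence_tat": "adherence"}),
        covariates=usable, metric_label="TAT", cluster_by=cluster_by,
    )
    auc = logistic_validation(
        table.rename(columns={"adherence_auc": "adherence"}),
        covariates=usable, metric_label="AUC", cluster_by=cluster_by,
    )
    return tat, auc


def side_by_side(tat: RegressionReport, auc: RegressionReport) -> pd.DataFrame:
    """Combine two reports into one comparison table."""
    left = tat.table.add_prefix("tat_")
    right = auc.table.add_prefix("auc_")
    return left.join(right, how="outer")
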