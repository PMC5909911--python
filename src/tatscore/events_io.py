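"""Event-log parsing and technique-error scoring.

Inhaler monitoring devices label each actuation with zero or more
technique errors (low inspiratory flow, exhalation into the mouthpiece,
no blister pierced, no inhalation detected).  Each error class carries a
multiplicative dose-fraction factor from device calibration; the technique
score ``delta`` of an actuation is the product of the factors of all its
errors, so a dose taken with both low flow and an exhalation error scores
0.7 × 0.5 = 0.35, and errors that deliver no drug at all force delta to 0.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import DoseEvent, ObservationWindow, PatientRecord

__all__ = [
    "TechniqueRule",
    "DEFAULT_TECHNIQUE_RULES",
    "delta_for_errors",
    "read_rules",
    "read_event_log",
    "write_event_log",
    "read_stata_dataset",
    "ParseResult",
]


@dataclass(frozen=True)
class TechniqueRule:
    """One technique-error class and its multiplicative dose fraction."""

    error_label: str
    delta_factor: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_factor <= 1.0:
            raise ValueError(
                f"delta factor must lie in [0, 1], got {self.delta_factor}"
            )


#: Calibration factors for the canonical error classes of an acoustic
#: inhaler monitor on a dry-powder device.  User-extensible: pass your own
#: rule list for other devices or drugs.
DEFAULT_TECHNIQUE_RULES: tuple[TechniqueRule, ...] = (
    TechniqueRule("none", 1.0),
    TechniqueRule("low_pifr", 0.7),       # peak inspiratory flow < 35 L/min
    TechniqueRule("exhalation", 0.5),     # patient exhales into inhaler
    TechniqueRule("no_blister", 0.0),     # drug not released
    TechniqueRule("no_inhalation", 0.0),  # no inhalation detected
)


def _rule_map(rules: Sequence[TechniqueRule]) -> dict[str, float]:
    out: dict[str, float] = {}
    for rule in rules:
        if rule.error_label in out:
            raise ValueError(f"duplicate technique rule for {rule.error_label!r}")
        out[rule.error_label] = rule.delta_factor
    return out


def delta_for_errors(
    error_labels: Iterable[str],
    rules: Sequence[TechniqueRule] = DEFAULT_TECHNIQUE_RULES,
) -> float:
    """Dose fraction for a list of technique errors.

    Factors combine multiplicatively (the calibrated composite
    low-flow + exhalation value equals the product of the two single-error
    values); an empty list means correct use and scores 1.0.  Zero-valued
    errors dominate any combination.
    """
    table = _rule_map(rules)
    delta = 1.0
    for label in error_labels:
        if label == "none" or label == "":
            continue
        if label not in table:
            raise KeyError(f"unknown technique-error label: {label!r}")
        delta *= table[label]
    return delta


def read_rules(path: str | Path) -> list[TechniqueRule]:
    """Read a technique-rule table from CSV (columns error_label, delta_factor)."""
    frame = pd.read_csv(path)
    missing = {"error_label", "delta_factor"} - set(frame.columns)
    if missing:
        raise ValueError(f"rules file missing columns: {sorted(missing)}")
    return [
        TechniqueRule(str(row.error_label), float(row.delta_factor))
        for row in frame.itertuples()
    ]


@dataclass
class ParseResult:
    """Parsed patient records plus a report of rejected rows."""

    records: list[PatientRecord]
    rejects: pd.DataFrame  # columns: row, patient_id, reason

    def write_rejects(self, path: str | Path) -> None:
        self.rejects.to_csv(path, index=False)


REQUIRED_COLUMNS = ("patient_id", "timestamp")


def _parse_labels(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    return tuple(tok.strip() for tok in text.split(";") if tok.strip())


def read_event_log(
    path: str | Path | io.StringIO,
    rules: Sequence[TechniqueRule] = DEFAULT_TECHNIQUE_RULES,
    span_hours: float | None = None,
    origin: str | None = None,
) -> ParseResult:
    """Parse a dose-event CSV into per-patient records.

    Expected columns: ``patient_id``, ``timestamp`` (ISO-8601), optional
    ``error_labels`` (semicolon-separated; empty = correct use) and
    ``delta_override``.  Event times become hours since each patient's
    first actuation, or since ``origin`` (an ISO timestamp marking the
    monitoring start) when given.  Malformed rows are collected into the
    rejects report rather than silently dropped.  ``span_hours`` fixes
    every patient's monitoring span; by default the span runs to the end
    of the last full day containing an event.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"event log missing required columns: {sorted(missing)}")

    rejects: list[dict] = []
    parsed: list[dict] = []
    for i, row in enumerate(frame.itertuples(), start=2):  # 1-based + header
        pid = row.patient_id
        if not isinstance(pid, str) or not pid.strip():
            rejects.append({"row": i, "patient_id": "", "reason": "missing patient_id"})
            continue
        stamp = pd.to_datetime(getattr(row, "timestamp"), errors="coerce")
        if pd.isna(stamp):
            rejects.append({"row": i, "patient_id": pid, "reason": "bad timestamp"})
            continue
        labels = _parse_labels(getattr(row, "error_labels", None))
        override = getattr(row, "delta_override", None)
        try:
            if override is not None and not pd.isna(override):
                delta = float(override)
            else:
                delta = delta_for_errors(labels, rules)
        except (KeyError, ValueError) as exc:
            rejects.append({"row": i, "patient_id": pid, "reason": str(exc)})
            continue
        if not 0.0 <= delta <= 1.0:
            rejects.append(
                {"row": i, "patient_id": pid, "reason": f"delta out of range: {delta}"}
            )
            continue
        parsed.append(
            {"patient_id": pid, "stamp": stamp, "delta": delta, "labels": labels}
        )

    records: list[PatientRecord] = []
    if parsed:
        table = pd.DataFrame(parsed)
        origin_stamp = pd.Timestamp(origin) if origin is not None else None
        for pid, group in table.groupby("patient_id", sort=True):
            t0 = origin_stamp if origin_stamp is not None else group["stamp"].min()
            hours = (group["stamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
            events = [
                DoseEvent(time=float(h), delta=float(d), error_labels=tuple(lab))
                for h, d, lab in zip(hours, group["delta"], group["labels"])
            ]
            if span_hours is not None:
                span = span_hours
            else:
                span = max(24.0, math.ceil((hours.max() + 1e-9) / 24.0) * 24.0)
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    events=events,
                    monitoring_span=ObservationWindow(0.0, span),
                )
            )
    reject_frame = pd.DataFrame(rejects, columns=["row", "patient_id", "reason"])
    return ParseResult(records=records, rejects=reject_frame)


def write_event_log(
    records: Sequence[PatientRecord],
    path: str | Path,
    origin: str = "2000-01-01T00:00:00",
) -> None:
    """Serialize patient records back to the event-log CSV dialect.

    Event hours are mapped onto ISO timestamps from ``origin``; parsing the
    output with :func:`read_event_log` reproduces the event set exactly
    (times are written to the second).
    """
    t0 = pd.Timestamp(origin)
    rows = []
    for rec in records:
        for ev in rec.events:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "timestamp": (t0 + pd.Timedelta(hours=ev.time)).isoformat(),
                    "error_labels": ";".join(ev.error_labels),
                    "delta_override": ev.delta,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stata_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Stata .dta file into a DataFrame with canonical column names.

    ``column_map`` maps canonical names (keys) to the file's column names
    (values); mapped columns are renamed, others pass through.  Raises a
    mapping error naming any canonical column whose source is absent.
    """
    try:
        frame = pd.read_stata(path)
    except Exception as exc:  # noqa: BLE001 - surface the reader's message
        raise ValueError(f"could not read Stata file {path}: {exc}") from exc
    if column_map:
        missing = [src for src in column_map.values() if src not in frame.columns]
        if missing:
            raise ValueError(f"Stata file missing mapped columns: {missing}")
        frame = frame.rename(columns={src: dst for dst, src in column_map.items()})
    return frame


def records_from_table(
    frame: pd.DataFrame,
    rules: Sequence[TechniqueRule] = DEFAULT_TECHNIQUE_RULES,
    span_hours: float | None = None,
) -> ParseResult:
    """Convert a raw event table (e.g. from a Stata export) to records.

    The table must carry ``patient_id`` and ``timestamp`` columns in the
    event-log dialect; this just routes through :func:`read_event_log`.
    """
    buffer = io.StringIO()
    frame.to_csv(buffer, index=False)
    buffer.seek(0)
    return read_event_log(buffer, rules=rules, span_hours=span_hours)
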