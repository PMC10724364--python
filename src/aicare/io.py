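"""Cohort container and CSV ingest/export.

A cohort is three tables:

* ``visits.csv``    — one row per clinic visit: ``patient_id, date`` plus one
  column per dynamic feature (empty cell = missing).
* ``baseline.csv``  — one row per patient: ``patient_id, age, gender, height,
  diabetes`` (or whatever the schema's static features are).
* ``outcomes.csv``  — one row per patient: ``patient_id, status
  ({deceased, alive}), event_date, censor_date, cause``.

Dates are ISO-8601, files UTF-8. Binary statics accept ``0/1`` as well as
common string encodings (``male/female``, ``yes/no``, ``true/false``);
the canonical in-memory form is 0/1.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_pd_schema

__all__ = [
    "Visit",
    "OutcomeStatus",
    "Outcome",
    "PatientRecord",
    "Cohort",
    "ValidationReport",
    "read_cohort",
    "write_cohort",
    "cohort_statistics",
]

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


class OutcomeStatus(enum.Enum):
    DECEASED = "deceased"
    ALIVE = "alive"


#: causes of death recognised in the outcomes table
CAUSES = (
    "CVE", "CVD", "PVD", "GI", "cachexia", "cancer",
    "infection", "PDAP", "other", "unknown",
)


@dataclass(frozen=True)
class Visit:
    """A single clinic visit: calendar date and observed feature values.

    ``values`` maps dynamic-feature name to a finite float; a missing
    measurement is simply absent from the mapping (never NaN).
    """

    date: _dt.date
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if v is None or not np.isfinite(v):
                raise ValueError(f"visit {self.date}: non-finite value for {k}")


@dataclass(frozen=True)
class Outcome:
    status: OutcomeStatus
    event_date: _dt.date | None = None  # death date if deceased
    censor_date: _dt.date | None = None  # end-of-collection date
    cause: str | None = None

    def __post_init__(self) -> None:
        if self.status is OutcomeStatus.DECEASED and self.event_date is None:
            raise ValueError("deceased outcome requires an event_date")
        if self.status is OutcomeStatus.ALIVE and self.censor_date is None:
            raise ValueError("alive outcome requires a censor_date")

    @property
    def end_date(self) -> _dt.date:
        """Death date for the deceased, censoring date for survivors."""
        d = self.event_date if self.status is OutcomeStatus.DECEASED else self.censor_date
        assert d is not None
        return d


@dataclass
class PatientRecord:
    patient_id: str
    baseline: dict[str, float]
    visits: list[Visit]
    outcome: Outcome

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"patient {self.patient_id}: at least one visit required")
        dates = [v.date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visit dates must be strictly increasing"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class Cohort:
    schema: FeatureSchema
    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def n_visits(self) -> int:
        return sum(p.n_visits for p in self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass
class ValidationReport:
    """What the reader had to coerce, drop or flag while ingesting."""

    n_unparseable_cells: int = 0
    n_out_of_range: int = 0
    dropped_visits: list[tuple[str, str]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (
            self.n_unparseable_cells == 0
            and self.n_out_of_range == 0
            and not self.dropped_visits
        )


class SchemaError(ValueError):
    """A required column is absent or misnamed."""


class ReferentialError(ValueError):
    """Cross-table patient references do not line up."""


def _parse_date(s) -> _dt.date:
    if isinstance(s, _dt.date):
        return s
    return _dt.date.fromisoformat(str(s).strip())


_BINARY_STRINGS = {
    "0": 0.0, "1": 1.0, "female": 0.0, "male": 1.0,
    "f": 0.0, "m": 1.0, "no": 0.0, "yes": 1.0,
    "false": 0.0, "true": 1.0,
}


def _parse_binary(cell) -> float:
    s = str(cell).strip().lower()
    if s in _BINARY_STRINGS:
        return _BINARY_STRINGS[s]
    v = float(s)
    if v not in (0.0, 1.0):
        raise ValueError(f"binary feature value {cell!r} not in {{0,1}}")
    return v


def _is_missing(cell) -> bool:
    return cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == ""


def read_cohort(
    visits_path,
    baseline_path,
    outcomes_path,
    schema: FeatureSchema | None = None,
) -> tuple[Cohort, ValidationReport]:
    """Read the three cohort CSVs into a validated :class:`Cohort`.

    Rows are grouped by patient and visits sorted ascending by date, so the
    result is invariant to the on-disk row order. Unparseable numeric cells
    are treated as missing and counted in the report.
    """
    schema = schema or default_pd_schema()
    report = ValidationReport()

    visits_df = pd.read_csv(visits_path, dtype=str, keep_default_na=False)
    baseline_df = pd.read_csv(baseline_path, dtype=str, keep_default_na=False)
    outcomes_df = pd.read_csv(outcomes_path, dtype=str, keep_default_na=False)

    for df, req, label in (
        (visits_df, ["patient_id", "date"] + schema.dynamic_names, "visits"),
        (baseline_df, ["patient_id"] + schema.static_names, "baseline"),
        (outcomes_df, ["patient_id", "status"], "outcomes"),
    ):
        missing_cols = [c for c in req if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"{label} table missing column(s): {missing_cols}")

    outcomes: dict[str, Outcome] = {}
    for _, row in outcomes_df.iterrows():
        pid = str(row["patient_id"])
        status = OutcomeStatus(str(row["status"]).strip().lower())
        event = None if _is_missing(row.get("event_date")) else _parse_date(row["event_date"])
        censor = None if _is_missing(row.get("censor_date")) else _parse_date(row["censor_date"])
        cause = None if _is_missing(row.get("cause")) else str(row["cause"]).strip()
        outcomes[pid] = Outcome(status=status, event_date=event, censor_date=censor, cause=cause)

    baselines: dict[str, dict[str, float]] = {}
    for _, row in baseline_df.iterrows():
        pid = str(row["patient_id"])
        b: dict[str, float] = {}
        for f in schema.static_features:
            cell = row[f.name]
            if f.binary:
                b[f.name] = _parse_binary(cell)
            else:
                b[f.name] = float(cell)
        baselines[pid] = b

    visits_by_pid: dict[str, list[Visit]] = {}
    for _, row in visits_df.iterrows():
        pid = str(row["patient_id"])
        if pid not in outcomes:
            raise ReferentialError(f"patient {pid} in visits but not in outcomes")
        if pid not in baselines:
            raise ReferentialError(f"patient {pid} in visits but not in baseline")
        values: dict[str, float] = {}
        for f in schema.dynamic_features:
            cell = row[f.name]
            if _is_missing(cell):
                continue
            try:
                v = float(str(cell).strip())
            except ValueError:
                report.n_unparseable_cells += 1
                continue
            if not np.isfinite(v):
                report.n_unparseable_cells += 1
                continue
            if not (f.lower <= v <= f.upper):
                report.n_out_of_range += 1
                report.messages.append(
                    f"{pid} {row['date']}: {f.name}={v} outside plausible "
                    f"range [{f.lower}, {f.upper}]"
                )
            values[f.name] = v
        visits_by_pid.setdefault(pid, []).append(
            Visit(date=_parse_date(row["date"]), values=values)
        )

    patients = []
    for pid, vlist in visits_by_pid.items():
        vlist.sort(key=lambda v: v.date)
        deduped = []
        for v in vlist:
            if deduped and v.date == deduped[-1].date:
                report.dropped_visits.append((pid, v.date.isoformat()))
                report.messages.append(f"{pid}: duplicate visit date {v.date}")
                continue
            deduped.append(v)
        patients.append(
            PatientRecord(
                patient_id=pid,
                baseline=baselines[pid],
                visits=deduped,
                outcome=outcomes[pid],
            )
        )
    patients.sort(key=lambda p: p.patient_id)
    return Cohort(schema=schema, patients=patients), report


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a cohort back to the three-CSV on-disk layout.

    Round-trips: ``read_cohort(*write_cohort(c).values())`` reproduces ``c``
    up to patient ordering (patients are written sorted by id).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = cohort.schema

    visit_rows = []
    baseline_rows = []
    outcome_rows = []
    for p in sorted(cohort.patients, key=lambda p: p.patient_id):
        for v in p.visits:
            row = {"patient_id": p.patient_id, "date": v.date.isoformat()}
            for f in schema.dynamic_features:
                row[f.name] = "" if f.name not in v.values else repr(v.values[f.name])
            visit_rows.append(row)
        brow = {"patient_id": p.patient_id}
        for f in schema.static_features:
            val = p.baseline[f.name]
            brow[f.name] = str(int(val)) if f.binary else repr(val)
        baseline_rows.append(brow)
        o = p.outcome
        outcome_rows.append(
            {
                "patient_id": p.patient_id,
                "status": o.status.value,
                "event_date": o.event_date.isoformat() if o.event_date else "",
                "censor_date": o.censor_date.isoformat() if o.censor_date else "",
                "cause": o.cause or "",
            }
        )

    visit_cols = ["patient_id", "date"] + schema.dynamic_names
    base_cols = ["patient_id"] + schema.static_names
    out_cols = ["patient_id", "status", "event_date", "censor_date", "cause"]
    paths = {
        "visits": out / "visits.csv",
        "baseline": out / "baseline.csv",
        "outcomes": out / "outcomes.csv",
    }
    pd.DataFrame(visit_rows, columns=visit_cols).to_csv(paths["visits"], index=False)
    pd.DataFrame(baseline_rows, columns=base_cols).to_csv(paths["baseline"], index=False)
    pd.DataFrame(outcome_rows, columns=out_cols).to_csv(paths["outcomes"], index=False)
    return paths


def _stats_row(x: np.ndarray) -> dict[str, float]:
    return {
        "avg": float(np.mean(x)),
        "med": float(np.median(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "std": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
    }


def cohort_statistics(cohort: Cohort, labels: pd.DataFrame | None = None) -> dict:
    """Summary statistics of a cohort, mirroring a follow-up study's Table-style
    description: per-feature distribution and missingness (optionally stratified
    by visit label), visits per patient, visit intervals in months, age in years.

    Parameters
    ----------
    labels
        Optional visit-label table with columns ``patient_id, date, label``
        (``label`` in {"positive", "negative", "uncertain"}); when given,
        per-feature statistics are additionally stratified into high-risk
        (positive) and low-risk (negative) visits.
    """
    if not cohort.patients:
        raise ValueError("cohort is empty")
    schema = cohort.schema

    label_of: dict[tuple[str, str], str] = {}
    if labels is not None:
        for _, r in labels.iterrows():
            label_of[(str(r["patient_id"]), str(r["date"]))] = str(r["label"])

    per_feature = []
    for f in schema.dynamic_features:
        pooled, pos, neg = [], [], []
        n_cells = 0
        for p in cohort.patients:
            for v in p.visits:
                n_cells += 1
                if f.name in v.values:
                    val = v.values[f.name]
                    pooled.append(val)
                    lab = label_of.get((p.patient_id, v.date.isoformat()))
                    if lab == "positive":
                        pos.append(val)
                    elif lab == "negative":
                        neg.append(val)
        row = {"feature": f.name, "unit": f.unit,
               "missing_rate": 1.0 - len(pooled) / n_cells}
        for tag, vals in (("", pooled), ("pos_", pos), ("neg_", neg)):
            if tag and labels is None:
                continue
            if vals:
                arr = np.asarray(vals)
                row[tag + "mean"] = float(arr.mean())
                row[tag + "std"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
                row[tag + "median"] = float(np.median(arr))
            else:
                row[tag + "mean"] = row[tag + "std"] = row[tag + "median"] = np.nan
        per_feature.append(row)

    visits_per_patient = np.array([p.n_visits for p in cohort.patients], float)
    ages = np.array([p.baseline.get("age", np.nan) for p in cohort.patients], float)
    intervals = []
    for p in cohort.patients:
        for a, b in zip(p.visits, p.visits[1:]):
            intervals.append((b.date - a.date).days / DAYS_PER_MONTH)

    out = {
        "n_patients": len(cohort.patients),
        "n_visits": cohort.n_visits,
        "features": pd.DataFrame(per_feature).set_index("feature"),
        "visits_per_patient": _stats_row(visits_per_patient),
        "age_years": _stats_row(ages[~np.isnan(ages)]) if np.any(~np.isnan(ages)) else None,
        "visit_interval_months": _stats_row(np.asarray(intervals)) if intervals else None,
    }
    if labels is not None:
        counts = {"positive": 0, "negative": 0, "uncertain": 0}
        for lab in label_of.values():
            if lab in counts:
                counts[lab] += 1
        out["label_counts"] = counts
    return out
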