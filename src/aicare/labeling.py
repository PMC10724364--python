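"""Visit-level 1-year mortality labels and patient-level fold splitting.

The dynamic prediction task asks, at every clinic visit, whether the patient
will die within the following year. Ground truth cannot be established for
every visit:

* deceased patient, death date ``d`` — a visit at ``v`` is *positive* when
  ``0 <= d - v <= 1`` year; *uncertain* when ``1 < d - v <= 2`` years (the
  patient's true state in the run-up to death is ambiguous); *negative*
  otherwise;
* surviving patient censored at ``c`` — a visit is *uncertain* when
  ``c - v <= 1`` year (the one-year outcome extends past the end of data
  collection); *negative* otherwise.

Uncertain visits stay in the encoder's input sequence but are excluded from
the loss and from evaluation metrics. Boundary convention: the positive
window is closed at both ends, so a visit exactly one year before death is
positive, never uncertain. A "year" is 365.25 days throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, OutcomeStatus, PatientRecord, DAYS_PER_YEAR

__all__ = [
    "Label",
    "LabeledVisit",
    "FoldAssignment",
    "assign_visit_labels",
    "labeled_dataset",
    "split_folds",
]


class Label(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class LabeledVisit:
    patient_id: str
    t: int  # 0-based visit index
    date: "object"  # datetime.date
    label: Label


def assign_visit_labels(
    patient: PatientRecord,
    horizon_years: float = 1.0,
    uncertain_lead_years: float = 1.0,
) -> tuple[list[LabeledVisit], list[int]]:
    """Label every visit of one patient under the dynamic-mortality rule.

    Returns ``(labels, dropped)`` where ``dropped`` lists the indices of
    visits dated after the death date (a data error; such visits get no
    label and should be reported upstream).
    """
    horizon_days = horizon_years * DAYS_PER_YEAR
    lead_days = (horizon_years + uncertain_lead_years) * DAYS_PER_YEAR
    out: list[LabeledVisit] = []
    dropped: list[int] = []
    o = patient.outcome
    for t, visit in enumerate(patient.visits):
        if o.status is OutcomeStatus.DECEASED:
            delta = (o.event_date - visit.date).days
            if delta < 0:
                dropped.append(t)
                continue
            if delta <= horizon_days:
                lab = Label.POSITIVE
            elif delta <= lead_days:
                lab = Label.UNCERTAIN
            else:
                lab = Label.NEGATIVE
        else:
            delta = (o.censor_date - visit.date).days
            lab = Label.UNCERTAIN if delta <= horizon_days else Label.NEGATIVE
        out.append(LabeledVisit(patient.patient_id, t, visit.date, lab))
    return out, dropped


def labeled_dataset(
    cohort: Cohort,
    horizon_years: float = 1.0,
    uncertain_lead_years: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Label every visit in the cohort.

    Returns a table with columns ``patient_id, t, date, label`` and a summary
    dict with the positive/negative/uncertain counts, the visit-level
    prevalence ``positives / (positives + negatives)``, and the number of
    dropped after-death visits. Uncertain visits are retained in the table
    (the sequence model consumes them as history) but carry the "uncertain"
    label so loss and metrics can exclude them.
    """
    rows = []
    n_dropped = 0
    for p in cohort.patients:
        labels, dropped = assign_visit_labels(p, horizon_years, uncertain_lead_years)
        n_dropped += len(dropped)
        for lv in labels:
            rows.append(
                {
                    "patient_id": lv.patient_id,
                    "t": lv.t,
                    "date": lv.date.isoformat(),
                    "label": lv.label.value,
                }
            )
    df = pd.DataFrame(rows, columns=["patient_id", "t", "date", "label"])
    n_pos = int((df["label"] == "positive").sum())
    n_neg = int((df["label"] == "negative").sum())
    n_unc = int((df["label"] == "uncertain").sum())
    denom = n_pos + n_neg
    summary = {
        "n_positive": n_pos,
        "n_negative": n_neg,
        "n_uncertain": n_unc,
        "n_dropped_after_death": n_dropped,
        "prevalence": (n_pos / denom) if denom else float("nan"),
    }
    return df, summary


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict[str, int]

    def test_ids(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.fold_of.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.fold_of.items() if f != fold)


def split_folds(cohort: Cohort, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Patient-level k-fold split, stratified on vital status.

    Every patient's visits land in exactly one fold (splitting by visit would
    leak near-duplicate records of the same patient across folds). Deceased
    and surviving patients are dealt to folds separately so each fold carries
    its share of events; fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cohort.patients):
        raise ValueError("k exceeds the number of patients")
    rng = np.random.default_rng(seed)
    deceased = sorted(
        p.patient_id for p in cohort.patients
        if p.outcome.status is OutcomeStatus.DECEASED
    )
    alive = sorted(
        p.patient_id for p in cohort.patients
        if p.outcome.status is OutcomeStatus.ALIVE
    )
    rng.shuffle(deceased)
    rng.shuffle(alive)
    # deal deceased first, then continue the same round-robin cycle with the
    # survivors: stratification within each group, total sizes within +/-1
    order = deceased + alive
    fold_of = {pid: i % k for i, pid in enumerate(order)}
    return FoldAssignment(k=k, fold_of=fold_of)
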