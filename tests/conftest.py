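"""Shared fixtures: tiny hand-built cohorts and a small planted cohort."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from aicare.io import Cohort, Outcome, OutcomeStatus, PatientRecord, Visit
from aicare.schema import default_pd_schema


def make_visit(date, **values):
    return Visit(date=date, values=values)


def make_patient(pid, visits, *, death=None, censor=dt.date(2018, 10, 31),
                 cause=None, age=60.0, gender=1.0, height=165.0,
                 diabetes=0.0):
    if death is not None:
        outcome = Outcome(status=OutcomeStatus.DECEASED, event_date=death,
                          censor_date=censor, cause=cause or "other")
    else:
        outcome = Outcome(status=OutcomeStatus.ALIVE, censor_date=censor)
    return PatientRecord(
        patient_id=pid,
        baseline={"age": age, "gender": gender, "height": height,
                  "diabetes": diabetes},
        visits=visits,
        outcome=outcome,
    )


@pytest.fixture(scope="session")
def schema():
    return default_pd_schema()


@pytest.fixture()
def two_patient_cohort(schema):
    """Two patients, three visits each, a couple of missing values."""
    d0 = dt.date(2010, 1, 1)
    p1 = make_patient(
        "A1",
        [
            make_visit(d0, albumin=38.0, sbp=130.0, wbc=7.0),
            make_visit(d0 + dt.timedelta(days=90), albumin=36.5, sbp=125.0),
            make_visit(d0 + dt.timedelta(days=180), sbp=120.0, wbc=8.2),
        ],
        death=d0 + dt.timedelta(days=400),
        cause="GI",
    )
    p2 = make_patient(
        "A2",
        [
            make_visit(d0 + dt.timedelta(days=10), albumin=41.0, dbp=80.0),
            make_visit(d0 + dt.timedelta(days=100), albumin=40.0, dbp=78.0),
            make_visit(d0 + dt.timedelta(days=190), albumin=39.0, dbp=75.0),
        ],
    )
    return Cohort(schema=schema, patients=[p1, p2])


def random_cohort(seed: int, n_patients: int = 12, schema=None):
    """Small random-but-valid cohort for property tests."""
    schema = schema or default_pd_schema()
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n_patients):
        n_visits = int(rng.integers(1, 8))
        start = dt.date(2008, 1, 1) + dt.timedelta(days=int(rng.integers(0, 2000)))
        visits = []
        date = start
        for _ in range(n_visits):
            values = {}
            for f in schema.dynamic_features:
                if rng.random() > 0.3:
                    lo, hi = f.lower, f.upper
                    values[f.name] = round(float(rng.uniform(lo, hi)), 3)
            visits.append(Visit(date=date, values=values))
            date = date + dt.timedelta(days=int(rng.integers(30, 150)))
        deceased = rng.random() < 0.4
        last = visits[-1].date
        if deceased:
            outcome = Outcome(
                status=OutcomeStatus.DECEASED,
                event_date=last + dt.timedelta(days=int(rng.integers(1, 700))),
                censor_date=dt.date(2018, 10, 31),
                cause=str(rng.choice(["GI", "CVE", "cancer", "unknown"])),
            )
        else:
            outcome = Outcome(status=OutcomeStatus.ALIVE,
                              censor_date=dt.date(2018, 10, 31))
        patients.append(
            PatientRecord(
                patient_id=f"R{i:03d}",
                baseline={"age": float(rng.uniform(18, 95)),
                          "gender": float(rng.integers(0, 2)),
                          "height": float(rng.uniform(145, 190)),
                          "diabetes": float(rng.integers(0, 2))},
                visits=visits,
                outcome=outcome,
            )
        )
    return Cohort(schema=schema, patients=patients)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """120-patient planted cohort for fast training tests."""
    import dataclasses

    from aicare.simulate import generate_cohort, planted_scenario_default

    cfg = dataclasses.replace(planted_scenario_default(seed=5), n_patients=120)
    cohort, gt = generate_cohort(cfg)
    return cohort, gt
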