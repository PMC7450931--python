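"""Shared fixtures: record builders and a random-record generator used by
the property suites."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from ckdcare.cohort import ParticipantRecord, VisitRecord

BASE_DATE = date(2020, 1, 1)

#: A fully-observed visit with every value inside its alert-safe band.
#: HbA1c sits in (6.5, 7.5] because the registry also alerts on
#: over-treatment (HbA1c < 6.5); medications are deliberately unrecorded
#: because the on/off-RAAS-blockade rules are complementary whenever the
#: medication list is known.
NORMAL_VISIT = dict(
    serum_creatinine=0.8,
    sbp=120.0,
    dbp=75.0,
    uacr=10.0,
    upcr=100.0,
    hba1c=7.0,
    hb=13.0,
    ldl=90.0,
    potassium=4.0,
    bicarbonate=25.0,
    phosphate=3.5,
    pth_abnormal=False,
    urine_protein_strip="neg",
    urine_rbc=False,
    medications=None,
)


def make_visit(day: int = 0, **overrides) -> VisitRecord:
    fields = dict(NORMAL_VISIT)
    fields.update(overrides)
    return VisitRecord(date=BASE_DATE + timedelta(days=day), **fields)


def make_record(visits=None, **overrides) -> ParticipantRecord:
    base = dict(id="T0001", age=50.0, sex="female", conditions=frozenset())
    base.update(overrides)
    return ParticipantRecord(visits=visits if visits is not None else [make_visit()], **base)


MED_POOL = ["ACEI", "ARB", "metformin", "NSAID", "statin", "insulin", "CCB"]
STRIPS = [None, "neg", "trace", "1+", "2+", "3+"]
ANNOTATION_KEYS = [
    "hemodialysis_started",
    "avf_prepared",
    "education_class",
    "egfr_ckd_notice",
    "acei_arb_stopped_adverse",
    "aki_history",
]
CONDITION_POOL = ["gout", "sle", "cardiovascular_disease", "recurrent_uti"]


def random_record(rng: np.random.Generator, max_visits: int = 5) -> ParticipantRecord:
    """A random partial record spanning the alert thresholds and gaps."""

    def maybe(value, p_missing=0.35):
        return None if rng.random() < p_missing else value

    n_visits = int(rng.integers(0, max_visits + 1))
    days = sorted(int(d) for d in rng.choice(800, size=n_visits, replace=False))
    visits = []
    for d in days:
        dbp = float(rng.uniform(55, 105))
        meds = None
        if rng.random() > 0.4:
            meds = frozenset(
                m for m in MED_POOL if rng.random() < 0.25
            )
        visits.append(
            VisitRecord(
                date=BASE_DATE + timedelta(days=d),
                serum_creatinine=maybe(float(rng.uniform(0.4, 6.0)), 0.25),
                sbp=maybe(dbp + float(rng.uniform(10, 80))),
                dbp=maybe(dbp),
                uacr=maybe(float(np.exp(rng.uniform(np.log(2), np.log(2000))))),
                upcr=maybe(float(np.exp(rng.uniform(np.log(20), np.log(3000))))),
                urine_protein_24h=maybe(float(rng.uniform(0, 1500)), 0.7),
                hba1c=maybe(float(rng.uniform(4.5, 12.0))),
                hb=maybe(float(rng.uniform(7, 17))),
                ldl=maybe(float(rng.uniform(50, 220))),
                potassium=maybe(float(rng.uniform(3.0, 6.5))),
                bicarbonate=maybe(float(rng.uniform(15, 30))),
                phosphate=maybe(float(rng.uniform(2.0, 7.0))),
                pth_abnormal=maybe(bool(rng.random() < 0.3)),
                urine_protein_strip=STRIPS[int(rng.integers(len(STRIPS)))],
                urine_rbc=maybe(bool(rng.random() < 0.15)),
                medications=meds,
            )
        )
    annotations = {k: True for k in ANNOTATION_KEYS if rng.random() < 0.12}
    conditions = None
    if rng.random() > 0.3:
        conditions = frozenset(c for c in CONDITION_POOL if rng.random() < 0.15)
    return ParticipantRecord(
        id=f"R{int(rng.integers(1e6)):06d}",
        age=float(rng.uniform(18, 95)),
        sex="female" if rng.random() < 0.5 else "male",
        diabetes=bool(rng.random() < 0.3),
        hypertension=bool(rng.random() < 0.3),
        known_renal_cause=bool(rng.random() < 0.1),
        weight_kg=None if rng.random() < 0.3 else float(rng.uniform(40, 100)),
        conditions=conditions,
        annotations=annotations,
        visits=visits,
    )


@pytest.fixture(scope="session")
def small_cohort():
    from ckdcare.cohort import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(n_participants=400, seed=123))
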