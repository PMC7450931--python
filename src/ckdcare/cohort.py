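"""Synthetic rural screening cohorts and two-arm trial data.

The generator is latent-status-first: each participant is first assigned a
latent CKD status (with probability rising with age but averaging the
configured target prevalence), then comorbidity and CKDu status
conditionally, then a stage-consistent eGFR set point and albuminuria set
point, and finally per-visit measurements — serum creatinine obtained by
inverting the CKD-EPI equation around the latent eGFR trajectory with
log-normal noise, plus blood pressure, labs and medications.  Downstream
KDIGO classification of the generated records recovers the configured
prevalence targets up to binomial sampling error, which is what makes the
staging, alerting and summary stages testable without any real registry
extract.

Everything is driven by a single master seed; each random stream is derived
from it through a fixed sub-stream label, so identical configurations
produce byte-identical serialized cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .staging import creatinine_for_egfr

__all__ = [
    "GeneratorConfig",
    "ParticipantRecord",
    "VisitRecord",
    "TrialArms",
    "generate_cohort",
    "generate_trial_arms",
    "arm_summary",
    "cohort_to_csv",
    "cohort_from_csv",
    "cohort_to_json",
    "cohort_from_json",
]

# Fixed sub-stream labels so adding a stream never perturbs existing ones.
_STREAMS = {
    "demographics": 11,
    "latent": 12,
    "comorbidity": 13,
    "severity": 14,
    "visits": 15,
    "labs": 16,
    "missing": 17,
    "medications": 18,
    "trial": 19,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration targets and mechanics for the screening-cohort generator.

    The fraction targets are what downstream KDIGO classification should
    recover, not raw latent rates; the defaults reproduce the screening
    figures the package is calibrated to (26.8% CKD prevalence, 43.2%
    hypertension and 35.8% diabetes among CKD, 28.9% CKDu among CKD).
    """

    n_participants: int
    seed: int = 0
    age_range: tuple[float, float] = (18.0, 90.0)
    p_ckd_target: float = 0.268
    p_htn_given_ckd: float = 0.432
    p_dm_given_ckd: float = 0.358
    p_ckdu_given_ckd: float = 0.289
    p_htn_background: float = 0.22
    p_dm_background: float = 0.10
    p_known_cause_background: float = 0.02
    creatinine_noise_cv: float = 0.08
    visit_schedule: tuple[int, ...] = (0, 120, 365)
    missing_rate: float = 0.10
    start_date: date = date(2018, 1, 1)
    trial_effect_egfr: float = 3.34
    trial_effect_sbp_dbp: tuple[float, float] = (6.2, 7.5)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError(
                f"n_participants: must be >= 1, got {self.n_participants}"
            )
        for name in (
            "p_ckd_target",
            "p_htn_given_ckd",
            "p_dm_given_ckd",
            "p_ckdu_given_ckd",
            "p_htn_background",
            "p_dm_background",
            "p_known_cause_background",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: fraction must be in [0, 1], got {v}")
        if self.creatinine_noise_cv < 0:
            raise ValidationError(
                f"creatinine_noise_cv: must be >= 0, got {self.creatinine_noise_cv}"
            )
        lo, hi = self.age_range
        if lo < 18 or hi <= lo:
            raise ValidationError(f"age_range: need 18 <= lo < hi, got {self.age_range}")
        offs = sorted(self.visit_schedule)
        if len(offs) < 2 or offs[-1] - offs[0] < 90:
            raise ValidationError(
                "visit_schedule: need at least two visit offsets >= 90 days apart "
                "so the chronicity rule is decidable"
            )
        # residual CKDu mass must fit among participants without DM/HTN
        free = (1.0 - self.p_htn_given_ckd) * (1.0 - self.p_dm_given_ckd)
        if self.p_ckdu_given_ckd > free + 1e-12:
            raise ValidationError(
                "p_ckdu_given_ckd: exceeds the fraction of CKD participants "
                f"without diabetes/hypertension ({free:.3f})"
            )


@dataclass
class VisitRecord:
    """One time-stamped measurement set; any field other than date may be missing."""

    date: date
    serum_creatinine: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    uacr: float | None = None
    upcr: float | None = None
    urine_protein_24h: float | None = None
    hba1c: float | None = None
    hb: float | None = None
    ldl: float | None = None
    potassium: float | None = None
    bicarbonate: float | None = None
    phosphate: float | None = None
    pth_abnormal: bool | None = None
    urine_protein_strip: str | None = None
    urine_rbc: bool | None = None
    medications: frozenset[str] | None = None

    def __post_init__(self):
        if self.serum_creatinine is not None and not self.serum_creatinine > 0:
            raise ValidationError(
                f"serum_creatinine: must be > 0 when present, got {self.serum_creatinine}"
            )
        if self.sbp is not None and self.dbp is not None and not self.sbp > self.dbp:
            raise ValidationError(
                f"sbp/dbp: systolic ({self.sbp}) must exceed diastolic ({self.dbp})"
            )
        if self.medications is not None:
            object.__setattr__(self, "medications", frozenset(self.medications))


@dataclass
class ParticipantRecord:
    """One person's demographics, comorbidities and visit history.

    ``conditions`` holds additional risk conditions (gout, SLE, cardiovascular
    disease, ...) used by the screening alert rules; ``None`` means the risk
    history was never collected.  ``annotations`` carries registry-level
    notes (dialysis start, AVF preparation, education-class attendance, AKI
    history, ...) keyed by a documented name.
    """

    id: str
    age: float
    sex: str
    diabetes: bool = False
    hypertension: bool = False
    known_renal_cause: bool = False
    weight_kg: float | None = None
    conditions: frozenset[str] | None = None
    annotations: dict = field(default_factory=dict)
    visits: list[VisitRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.age < 18:
            raise ValidationError(f"age: screening cohorts are adults (>= 18), got {self.age}")
        self.visits = sorted(self.visits, key=lambda v: v.date)
        if self.conditions is not None:
            self.conditions = frozenset(self.conditions)


# Latent stage mixture among CKD participants and the eGFR set-point range
# (ml/min/1.73 m^2) drawn uniformly within each stage.  G1/G2 CKD carries
# persistent albuminuria (its only qualifying criterion); ranges stop short
# of the 60 boundary so measurement noise rarely undoes the latent status.
_CKD_STAGE_MIX = (
    ("G1", 0.12, (92.0, 115.0)),
    ("G2", 0.33, (62.0, 88.0)),
    ("G3a", 0.30, (45.0, 57.0)),
    ("G3b", 0.15, (31.0, 44.0)),
    ("G4", 0.07, (16.0, 29.0)),
    ("G5", 0.03, (6.0, 14.0)),
)

# Albuminuria set-point (mg/g) ranges, sampled log-uniformly.
_UACR_RANGES = {"A1": (4.0, 18.0), "A2": (60.0, 250.0), "A3": (400.0, 1500.0)}


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_cohort(config: GeneratorConfig) -> list[ParticipantRecord]:
    """Generate a synthetic adult screening cohort.

    Deterministic under ``config.seed``; the latent CKD assignment is
    calibrated so that KDIGO classification of the generated records
    recovers ``p_ckd_target`` up to binomial sampling error.
    """
    n = config.n_participants
    lo, hi = config.age_range

    demo = _rng(config.seed, "demographics")
    age = demo.uniform(lo, hi, n)
    sex = np.where(demo.random(n) < 0.55, "female", "male")  # screening skews female
    weight = np.clip(demo.normal(60.0, 11.0, n), 35.0, 120.0)

    # Latent CKD: probability linear in age with mean equal to the target.
    latent = _rng(config.seed, "latent")
    u = (age - lo) / (hi - lo)
    p_i = np.clip(config.p_ckd_target * (0.4 + 1.2 * u), 0.0, 1.0)
    is_ckd = latent.random(n) < p_i

    # Comorbidity, conditional on latent status.
    com = _rng(config.seed, "comorbidity")
    htn = np.where(is_ckd, com.random(n) < config.p_htn_given_ckd, com.random(n) < config.p_htn_background)
    dm = np.where(is_ckd, com.random(n) < config.p_dm_given_ckd, com.random(n) < config.p_dm_background)
    # Known renal cause: among CKD without DM/HTN, set so that the CKDu
    # fraction among CKD equals the target; background rate elsewhere.
    free = (1.0 - config.p_htn_given_ckd) * (1.0 - config.p_dm_given_ckd)
    p_krc_free = 0.0 if free == 0 else np.clip(1.0 - config.p_ckdu_given_ckd / free, 0.0, 1.0)
    krc_draw = com.random(n)
    krc = np.where(
        is_ckd & ~htn & ~dm, krc_draw < p_krc_free, krc_draw < config.p_known_cause_background
    )

    # Severity: stage, eGFR set point, annual slope, albuminuria set point.
    sev = _rng(config.seed, "severity")
    stage_idx = sev.choice(len(_CKD_STAGE_MIX), size=n, p=[w for _, w, _ in _CKD_STAGE_MIX])
    egfr_sp = np.empty(n)
    uacr_sp = np.empty(n)
    for k, (_, _, (g_lo, g_hi)) in enumerate(_CKD_STAGE_MIX):
        mask = stage_idx == k
        egfr_sp[mask] = sev.uniform(g_lo, g_hi, int(mask.sum()))
    # Non-CKD set point: high-normal filtration declining mildly with age.
    non = ~is_ckd
    egfr_sp[non] = np.clip(sev.normal(100.0 - 0.45 * (age[non] - 40.0), 11.0), 72.0, 130.0)

    # A-category assignment: G1/G2 CKD must carry albuminuria; G3+ mixed.
    a_draw = sev.random(n)
    early = is_ckd & (stage_idx <= 1)
    late = is_ckd & (stage_idx >= 2)
    a_cat = np.full(n, "A1", dtype=object)
    a_cat[early] = np.where(a_draw[early] < 0.75, "A2", "A3")
    a_cat[late] = np.select(
        [a_draw[late] < 0.40, a_draw[late] < 0.82], ["A1", "A2"], default="A3"
    )
    for cat, (u_lo, u_hi) in _UACR_RANGES.items():
        mask = a_cat == cat
        uacr_sp[mask] = _loguniform(sev, u_lo, u_hi, int(mask.sum()))

    # Annual eGFR slope: most CKD declines slowly, a minority rapidly
    # (exercising the decline-rate alert rules); non-CKD is nearly flat.
    rapid = sev.random(n) < 0.15
    slope = np.where(
        is_ckd,
        np.where(rapid, sev.normal(-6.5, 1.5, n), sev.normal(-2.0, 1.0, n)),
        sev.normal(-0.4, 0.4, n),
    )
    slope = np.minimum(slope, 1.0)

    offsets = np.array(sorted(config.visit_schedule), dtype=float)
    nv = len(offsets)
    t_years = offsets / 365.25

    vis = _rng(config.seed, "visits")
    # Per-visit latent eGFR and measured creatinine.
    egfr_t = egfr_sp[:, None] + slope[:, None] * t_years[None, :]
    egfr_t = np.clip(egfr_t, 2.0, 150.0)
    scr_base = np.empty((n, nv))
    for i in range(n):
        for j in range(nv):
            scr_base[i, j] = creatinine_for_egfr(egfr_t[i, j], age[i], sex[i])
    scr = scr_base * np.exp(vis.normal(0.0, config.creatinine_noise_cv, (n, nv)))

    uacr_vals = uacr_sp[:, None] * np.exp(vis.normal(0.0, 0.3, (n, nv)))

    labs = _rng(config.seed, "labs")
    dbp = np.where(htn[:, None], labs.normal(86.0, 9.0, (n, nv)), labs.normal(76.0, 7.0, (n, nv)))
    gap = np.clip(
        np.where(htn[:, None], labs.normal(58.0, 10.0, (n, nv)), labs.normal(46.0, 9.0, (n, nv))),
        12.0,
        None,
    )
    dbp = np.clip(dbp, 45.0, 130.0)
    sbp = dbp + gap
    hba1c = np.clip(
        np.where(dm[:, None], labs.normal(7.5, 1.2, (n, nv)), labs.normal(5.4, 0.4, (n, nv))),
        4.0,
        15.0,
    )
    sev_idx = np.where(is_ckd, stage_idx, 0)[:, None]
    hb = np.clip(labs.normal(13.5 - 0.7 * sev_idx, 1.3, (n, nv)), 6.0, 18.0)
    ldl = np.clip(labs.normal(112.0, 30.0, (n, nv)), 30.0, 300.0)
    potassium = np.clip(labs.normal(4.1 + 0.17 * sev_idx, 0.45, (n, nv)), 2.5, 8.0)
    bicarbonate = np.clip(labs.normal(25.0 - 0.8 * sev_idx, 2.2, (n, nv)), 8.0, 35.0)
    phosphate = np.clip(labs.normal(3.6 + 0.28 * sev_idx, 0.6, (n, nv)), 1.0, 10.0)
    pth_abn = labs.random((n, nv)) < np.clip(0.03 + 0.08 * sev_idx, 0.0, 0.6)
    urine_rbc = labs.random((n, nv)) < 0.04
    # Dipstick tracks albuminuria on the log scale; the reading noise is
    # kept below one ordinal step so normal albuminuria essentially never
    # reads 1+ twice (that would manufacture spurious chronic proteinuria).
    strip_noise = labs.normal(0.0, 0.25, (n, nv))
    log_uacr = np.log10(uacr_vals)
    strip_score = log_uacr - 1.48 + strip_noise  # ~0 at 30 mg/g, ~1 at 300
    strip = np.select(
        [strip_score < 0.0, strip_score < 0.35, strip_score < 1.0, strip_score < 1.6],
        ["neg", "trace", "1+", "2+"],
        default="3+",
    )

    meds_rng = _rng(config.seed, "medications")
    raas_draw = meds_rng.random(n)
    on_acei = htn & (raas_draw < 0.35)
    on_arb = htn & (raas_draw >= 0.35) & (raas_draw < 0.60)
    on_ccb = htn & (meds_rng.random(n) < 0.35)
    on_metformin = dm & (meds_rng.random(n) < 0.70)
    on_insulin = dm & (meds_rng.random(n) < 0.20)
    on_statin = meds_rng.random(n) < 0.30
    on_nsaid = meds_rng.random(n) < 0.08

    miss = _rng(config.seed, "missing")
    missing_fields = (
        "sbp", "dbp", "uacr", "hba1c", "hb", "ldl", "potassium",
        "bicarbonate", "phosphate", "pth_abnormal", "urine_protein_strip",
        "urine_rbc", "medications",
    )
    missing_mask = {f: miss.random((n, nv)) < config.missing_rate for f in missing_fields}
    # BP is measured as a pair: one missingness draw drops both.
    missing_mask["dbp"] = missing_mask["sbp"]

    cohort: list[ParticipantRecord] = []
    for i in range(n):
        meds = set()
        if on_acei[i]:
            meds.add("ACEI")
        if on_arb[i]:
            meds.add("ARB")
        if on_ccb[i]:
            meds.add("CCB")
        if on_metformin[i]:
            meds.add("metformin")
        if on_insulin[i]:
            meds.add("insulin")
        if on_statin[i]:
            meds.add("statin")
        if on_nsaid[i]:
            meds.add("NSAID")
        meds = frozenset(meds)

        visits = []
        for j in range(nv):
            def take(name, value):
                return None if missing_mask[name][i, j] else value

            visits.append(
                VisitRecord(
                    date=config.start_date + timedelta(days=int(offsets[j])),
                    serum_creatinine=float(scr[i, j]),  # never missing at screening
                    sbp=take("sbp", float(round(sbp[i, j], 1))),
                    dbp=take("dbp", float(round(dbp[i, j], 1))),
                    uacr=take("uacr", float(round(uacr_vals[i, j], 1))),
                    hba1c=take("hba1c", float(round(hba1c[i, j], 2))),
                    hb=take("hb", float(round(hb[i, j], 1))),
                    ldl=take("ldl", float(round(ldl[i, j], 1))),
                    potassium=take("potassium", float(round(potassium[i, j], 2))),
                    bicarbonate=take("bicarbonate", float(round(bicarbonate[i, j], 1))),
                    phosphate=take("phosphate", float(round(phosphate[i, j], 2))),
                    pth_abnormal=take("pth_abnormal", bool(pth_abn[i, j])),
                    urine_protein_strip=take("urine_protein_strip", str(strip[i, j])),
                    urine_rbc=take("urine_rbc", bool(urine_rbc[i, j])),
                    medications=take("medications", meds),
                )
            )
        cohort.append(
            ParticipantRecord(
                id=f"P{i + 1:06d}",
                age=float(round(age[i], 1)),
                sex=str(sex[i]),
                diabetes=bool(dm[i]),
                hypertension=bool(htn[i]),
                known_renal_cause=bool(krc[i]),
                weight_kg=float(round(weight[i], 1)),
                conditions=frozenset(),
                visits=visits,
            )
        )
    return cohort


@dataclass
class TrialArms:
    """Two-arm trial cohort with arm labels on each participant."""

    intervention: list[ParticipantRecord]
    control: list[ParticipantRecord]


def generate_trial_arms(
    config: GeneratorConfig, n_per_arm: int, n_control: int | None = None
) -> TrialArms:
    """Generate a two-arm comprehensive-care trial in CKD stages 2-4.

    Both arms share the baseline distribution; after 12 months the
    intervention arm's mean eGFR exceeds the control arm's by
    ``config.trial_effect_egfr`` (default 3.34 ml/min/1.73 m^2, the observed
    49.57 vs 46.23 difference) and its blood pressure is lower by
    ``config.trial_effect_sbp_dbp`` (default 6.2/7.5 mmHg).
    """
    if n_per_arm < 2:
        raise ValidationError(f"n_per_arm: must be >= 2, got {n_per_arm}")
    n_control = n_per_arm if n_control is None else n_control
    if n_control < 2:
        raise ValidationError(f"n_control: must be >= 2, got {n_control}")
    rng = _rng(config.seed, "trial")

    def make_arm(label: str, n: int, egfr_shift: float, sbp_shift: float, dbp_shift: float):
        age = rng.uniform(40.0, 75.0, n)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        egfr0 = np.clip(rng.normal(47.5, 9.0, n), 16.0, 88.0)
        egfr12 = np.clip(rng.normal(46.23, 9.0, n) + egfr_shift, 10.0, 95.0)
        dbp12 = np.clip(rng.normal(83.6, 8.0, n) - dbp_shift, 45.0, 130.0)
        sbp12 = dbp12 + np.clip(rng.normal(52.2, 9.0, n) - (sbp_shift - dbp_shift), 15.0, None)
        dbp0 = np.clip(rng.normal(83.6, 8.0, n), 45.0, 130.0)
        sbp0 = dbp0 + np.clip(rng.normal(52.2, 9.0, n), 15.0, None)
        noise = rng.normal(0.0, config.creatinine_noise_cv, (n, 2))
        arm = []
        for i in range(n):
            visits = [
                VisitRecord(
                    date=config.start_date,
                    serum_creatinine=float(
                        creatinine_for_egfr(egfr0[i], age[i], sex[i]) * np.exp(noise[i, 0])
                    ),
                    sbp=float(round(sbp0[i], 1)),
                    dbp=float(round(dbp0[i], 1)),
                ),
                VisitRecord(
                    date=config.start_date + timedelta(days=365),
                    # 12-month eGFR is the trial endpoint: encode it exactly
                    # so arm means carry the configured shift.
                    serum_creatinine=float(creatinine_for_egfr(egfr12[i], age[i], sex[i])),
                    sbp=float(round(sbp12[i], 1)),
                    dbp=float(round(dbp12[i], 1)),
                ),
            ]
            arm.append(
                ParticipantRecord(
                    id=f"{label[0].upper()}{i + 1:05d}",
                    age=float(round(age[i], 1)),
                    sex=str(sex[i]),
                    annotations={"arm": label},
                    visits=visits,
                )
            )
        return arm

    de, (ds, dd) = config.trial_effect_egfr, config.trial_effect_sbp_dbp
    return TrialArms(
        intervention=make_arm("intervention", n_per_arm, de, ds, dd),
        control=make_arm("control", n_control, 0.0, 0.0, 0.0),
    )


def arm_summary(arm: Sequence[ParticipantRecord]) -> dict:
    """Mean 12-month eGFR and blood pressure for one trial arm."""
    from .staging import egfr as _egfr

    last = [p.visits[-1] for p in arm]
    egfrs = [_egfr(v.serum_creatinine, p.age, p.sex) for p, v in zip(arm, last)]
    return {
        "n": len(arm),
        "mean_egfr_12m": float(np.mean(egfrs)),
        "mean_sbp_12m": float(np.mean([v.sbp for v in last if v.sbp is not None])),
        "mean_dbp_12m": float(np.mean([v.dbp for v in last if v.dbp is not None])),
    }


# ---------------------------------------------------------------------------
# Serialization: CSV (one row per visit) and nested JSON
# ---------------------------------------------------------------------------

_PARTICIPANT_COLS = [
    "id", "age", "sex", "diabetes", "hypertension", "known_renal_cause",
    "weight_kg", "conditions", "annotations",
]
_VISIT_COLS = [
    "visit_date", "serum_creatinine", "sbp", "dbp", "uacr", "upcr",
    "urine_protein_24h", "hba1c", "hb", "ldl", "potassium", "bicarbonate",
    "phosphate", "pth_abnormal", "urine_protein_strip", "urine_rbc",
    "medications",
]

# CSV cannot distinguish an empty cell (not recorded) from a documented
# empty set, so sets serialize "none documented" with a sentinel.
_EMPTY_SET = "(none)"


def _set_to_cell(values: frozenset | None) -> str | None:
    if values is None:
        return None
    return ";".join(sorted(values)) if values else _EMPTY_SET


def _cell_to_set(cell) -> frozenset | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    if cell == _EMPTY_SET:
        return frozenset()
    return frozenset(m for m in str(cell).split(";") if m)


def cohort_to_frame(cohort: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per visit (participant columns repeated)."""
    rows = []
    for p in cohort:
        base = {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "diabetes": p.diabetes,
            "hypertension": p.hypertension,
            "known_renal_cause": p.known_renal_cause,
            "weight_kg": p.weight_kg,
            "conditions": _set_to_cell(p.conditions),
            "annotations": json.dumps(p.annotations, sort_keys=True, default=str)
            if p.annotations
            else None,
        }
        for v in p.visits:
            row = dict(base)
            row["visit_date"] = v.date.isoformat()
            for c in _VISIT_COLS[1:]:
                row[c] = _set_to_cell(v.medications) if c == "medications" else getattr(v, c)
            rows.append(row)
    return pd.DataFrame(rows, columns=_PARTICIPANT_COLS + _VISIT_COLS)


def cohort_to_csv(cohort: Iterable[ParticipantRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_from_frame(frame: pd.DataFrame) -> list[ParticipantRecord]:
    cohort = []
    for pid, grp in frame.groupby("id", sort=False):
        first = grp.iloc[0]

        def opt(v):
            return None if pd.isna(v) else v

        visits = []
        for _, r in grp.iterrows():
            strip = opt(r["urine_protein_strip"])
            visits.append(
                VisitRecord(
                    date=date.fromisoformat(r["visit_date"]),
                    serum_creatinine=opt(r["serum_creatinine"]),
                    sbp=opt(r["sbp"]),
                    dbp=opt(r["dbp"]),
                    uacr=opt(r["uacr"]),
                    upcr=opt(r["upcr"]),
                    urine_protein_24h=opt(r["urine_protein_24h"]),
                    hba1c=opt(r["hba1c"]),
                    hb=opt(r["hb"]),
                    ldl=opt(r["ldl"]),
                    potassium=opt(r["potassium"]),
                    bicarbonate=opt(r["bicarbonate"]),
                    phosphate=opt(r["phosphate"]),
                    pth_abnormal=None if pd.isna(r["pth_abnormal"]) else bool(r["pth_abnormal"]),
                    urine_protein_strip=strip,
                    urine_rbc=None if pd.isna(r["urine_rbc"]) else bool(r["urine_rbc"]),
                    medications=_cell_to_set(r["medications"]),
                )
            )
        cond = opt(first["conditions"])
        ann = opt(first["annotations"])
        cohort.append(
            ParticipantRecord(
                id=str(pid),
                age=float(first["age"]),
                sex=str(first["sex"]),
                diabetes=bool(first["diabetes"]),
                hypertension=bool(first["hypertension"]),
                known_renal_cause=bool(first["known_renal_cause"]),
                weight_kg=opt(first["weight_kg"]),
                conditions=_cell_to_set(cond),
                annotations={} if ann is None else json.loads(ann),
                visits=visits,
            )
        )
    return cohort


def cohort_from_csv(path) -> list[ParticipantRecord]:
    return cohort_from_frame(pd.read_csv(path))


def _participant_to_dict(p: ParticipantRecord) -> dict:
    d = dataclasses.asdict(p)
    d["conditions"] = None if p.conditions is None else sorted(p.conditions)
    for v, vd in zip(p.visits, d["visits"]):
        vd["date"] = v.date.isoformat()
        vd["medications"] = None if v.medications is None else sorted(v.medications)
    return d


def cohort_to_json(cohort: Iterable[ParticipantRecord], path) -> None:
    data = [_participant_to_dict(p) for p in cohort]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True, default=str)


def cohort_from_json(path) -> list[ParticipantRecord]:
    with open(path) as fh:
        data = json.load(fh)
    cohort = []
    for d in data:
        visits = [
            VisitRecord(
                **{
                    **{k: v for k, v in vd.items() if k != "date" and k != "medications"},
                    "date": date.fromisoformat(vd["date"]),
                    "medications": None
                    if vd["medications"] is None
                    else frozenset(vd["medications"]),
                }
            )
            for vd in d["visits"]
        ]
        cohort.append(
            ParticipantRecord(
                id=d["id"],
                age=d["age"],
                sex=d["sex"],
                diabetes=d["diabetes"],
                hypertension=d["hypertension"],
                known_renal_cause=d["known_renal_cause"],
                weight_kg=d.get("weight_kg"),
                conditions=None if d.get("conditions") is None else frozenset(d["conditions"]),
                annotations=d.get("annotations", {}),
                visits=visits,
            )
        )
    return cohort
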