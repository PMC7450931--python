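"""KDIGO-based CKD staging and screening summaries.

This module computes the estimated glomerular filtration rate (eGFR) from
serum creatinine, applies the KDIGO chronic kidney disease definition
(kidney damage and/or eGFR < 60 ml/min/1.73 m^2 persisting for three months
or longer) to longitudinal participant records, assigns G- and A-stages,
flags CKD of unknown etiology (CKDu), and summarises prevalence and risk
factors for a screened cohort.  It also provides the sodium content audit
used to evaluate a salt-intake reduction campaign in canteen food.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "egfr",
    "classify",
    "prevalence_summary",
    "sodium_audit",
    "sodium_audit_from_counts",
    "load_sodium_counts",
    "CkdClassification",
    "PrevalenceSummary",
    "SodiumAudit",
    "SodiumAuditResult",
    "G_STAGES",
    "g_stage_of",
    "a_category_of",
    "STRIP_LEVELS",
]

#: Chronicity window operationalising "3 months or longer".
CHRONICITY_DAYS = 90

#: Albuminuria threshold (mg/g) marking kidney damage (A2 and above).
UACR_DAMAGE_THRESHOLD = 30.0

#: Ordered urine protein dipstick levels; "1+" and above marks proteinuria.
STRIP_LEVELS = ("neg", "trace", "1+", "2+", "3+")

G_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")

# CKD-EPI creatinine equation coefficients, keyed by (equation, sex):
# kappa, alpha, exponent above kappa, age base, sex multiplier, scale.
_CKD_EPI = {
    ("ckd-epi-2009", "female"): (0.7, -0.329, -1.209, 0.993, 1.018, 141.0),
    ("ckd-epi-2009", "male"): (0.9, -0.411, -1.209, 0.993, 1.0, 141.0),
    ("ckd-epi-2021", "female"): (0.7, -0.241, -1.200, 0.9938, 1.012, 142.0),
    ("ckd-epi-2021", "male"): (0.9, -0.302, -1.200, 0.9938, 1.0, 142.0),
}


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("f", "female"):
        return "female"
    if s in ("m", "male"):
        return "male"
    raise ValidationError(f"sex: expected 'male' or 'female', got {sex!r}")


def egfr(scr: float, age: float, sex: str, equation: str = "ckd-epi-2009") -> float:
    """Estimated GFR (ml/min/1.73 m^2) from serum creatinine.

    Uses the CKD-EPI creatinine equation without the race coefficient
    (default: the 2009 equation; ``equation="ckd-epi-2021"`` selects the
    race-free 2021 refit).  Strictly decreasing in both creatinine and age.

    Parameters
    ----------
    scr : serum creatinine in mg/dl (must be positive)
    age : age in years (adults, >= 18)
    sex : "male" or "female"
    """
    if not scr > 0:
        raise ValidationError(f"scr: serum creatinine must be positive, got {scr}")
    if age < 18:
        raise ValidationError(f"age: adult equation requires age >= 18, got {age}")
    key = (equation, _norm_sex(sex))
    if key not in _CKD_EPI:
        raise ValidationError(f"equation: unknown eGFR equation {equation!r}")
    kappa, alpha, beta, age_base, sex_mult, scale = _CKD_EPI[key]
    r = scr / kappa
    return scale * min(r, 1.0) ** alpha * max(r, 1.0) ** beta * age_base**age * sex_mult


def creatinine_for_egfr(
    target: float, age: float, sex: str, equation: str = "ckd-epi-2009"
) -> float:
    """Invert the CKD-EPI equation: creatinine (mg/dl) yielding ``target`` eGFR.

    Used by the synthetic cohort generator to turn latent eGFR trajectories
    into serum creatinine measurements.
    """
    if not target > 0:
        raise ValidationError(f"target: eGFR must be positive, got {target}")
    key = (equation, _norm_sex(sex))
    kappa, alpha, beta, age_base, sex_mult, scale = _CKD_EPI[key]
    c = scale * age_base**age * sex_mult  # eGFR at scr == kappa
    if target <= c:  # scr >= kappa branch (exponent beta)
        return kappa * (target / c) ** (1.0 / beta)
    return kappa * (target / c) ** (1.0 / alpha)


def g_stage_of(value: float) -> str:
    """Map an eGFR value to its KDIGO G-stage (half-open, exhaustive bins)."""
    if value >= 90:
        return "G1"
    if value >= 60:
        return "G2"
    if value >= 45:
        return "G3a"
    if value >= 30:
        return "G3b"
    if value >= 15:
        return "G4"
    return "G5"


def a_category_of(uacr: float) -> str:
    """Map urine albumin/creatinine ratio (mg/g) to KDIGO A-category.

    Exactly 30 is A2 and exactly 300 is A2 (KDIGO convention: A3 is > 300).
    """
    if uacr < 30:
        return "A1"
    if uacr <= 300:
        return "A2"
    return "A3"


def strip_at_least(level: str | None, cutoff: str = "1+") -> bool | None:
    """Whether a dipstick reading is at or above ``cutoff``; None if missing."""
    if level is None:
        return None
    try:
        return STRIP_LEVELS.index(level) >= STRIP_LEVELS.index(cutoff)
    except ValueError:
        raise ValidationError(f"urine_protein_strip: unknown level {level!r}")


@dataclass
class CkdClassification:
    """Per-person KDIGO classification result.

    ``is_ckd`` requires chronicity: two qualifying findings (eGFR < 60, or a
    kidney-damage marker) at least 90 days apart.  ``provisional`` marks
    records with a suggestive finding whose chronicity could not be
    confirmed; ``undetermined`` marks records with no usable creatinine.
    CKDu is CKD without diabetes, hypertension or another known renal cause.
    """

    id: str
    is_ckd: bool
    g_stage: str | None
    a_category: str | None
    is_ckdu: bool
    latest_egfr: float | None
    egfr_slope: float | None
    provisional: bool = False
    undetermined: bool = False
    diabetes: bool = False
    hypertension: bool = False


def _ols_slope(days: Sequence[float], values: Sequence[float]) -> float:
    """Ordinary least-squares slope of values on time, per year."""
    t = np.asarray(days, dtype=float) / 365.25
    y = np.asarray(values, dtype=float)
    t = t - t.mean()
    denom = float((t * t).sum())
    if denom == 0.0:
        return 0.0
    return float((t * (y - y.mean())).sum() / denom)


def classify(participant, equation: str = "ckd-epi-2009") -> CkdClassification:
    """Classify one participant record against the KDIGO CKD definition.

    CKD is present iff either criterion is met with chronicity:

    * two eGFR values < 60 ml/min/1.73 m^2 at visits >= 90 days apart, or
    * a kidney-damage marker (UACR >= 30 mg/g, or urine protein dipstick
      >= 1+) at two visits >= 90 days apart.

    The G-stage comes from the latest confirmed low eGFR when the reduced
    filtration criterion holds, otherwise from the latest eGFR; the
    A-category comes from the latest UACR.
    """
    visits = sorted(participant.visits, key=lambda v: v.date)
    egfr_points: list[tuple[date, float]] = []
    for v in visits:
        if v.serum_creatinine is not None:
            egfr_points.append(
                (v.date, egfr(v.serum_creatinine, participant.age, participant.sex, equation))
            )

    if not egfr_points:
        return CkdClassification(
            id=participant.id,
            is_ckd=False,
            g_stage=None,
            a_category=_latest_a_category(visits),
            is_ckdu=False,
            latest_egfr=None,
            egfr_slope=None,
            undetermined=True,
            diabetes=participant.diabetes,
            hypertension=participant.hypertension,
        )

    low = [(d, g) for d, g in egfr_points if g < 60]
    low_confirmed = _pair_at_least_apart([d for d, _ in low])

    damage_dates = []
    for v in visits:
        uacr_hit = v.uacr is not None and v.uacr >= UACR_DAMAGE_THRESHOLD
        strip_hit = strip_at_least(v.urine_protein_strip) is True
        if uacr_hit or strip_hit:
            damage_dates.append(v.date)
    damage_confirmed = _pair_at_least_apart(damage_dates)

    is_ckd = low_confirmed or damage_confirmed
    latest_egfr = egfr_points[-1][1]
    if low_confirmed:
        staging_egfr = low[-1][1]  # latest confirmed reduced value
    else:
        staging_egfr = latest_egfr
    g_stage = g_stage_of(staging_egfr)

    provisional = (not is_ckd) and (bool(low) or bool(damage_dates))

    is_ckdu = bool(
        is_ckd
        and not participant.diabetes
        and not participant.hypertension
        and not participant.known_renal_cause
    )

    slope = None
    if len(egfr_points) >= 2:
        day0 = egfr_points[0][0]
        slope = _ols_slope(
            [(d - day0).days for d, _ in egfr_points], [g for _, g in egfr_points]
        )

    return CkdClassification(
        id=participant.id,
        is_ckd=is_ckd,
        g_stage=g_stage,
        a_category=_latest_a_category(visits),
        is_ckdu=is_ckdu,
        latest_egfr=latest_egfr,
        egfr_slope=slope,
        provisional=provisional,
        diabetes=participant.diabetes,
        hypertension=participant.hypertension,
    )


def _latest_a_category(visits) -> str | None:
    for v in reversed(visits):
        if v.uacr is not None:
            return a_category_of(v.uacr)
    return None


def _pair_at_least_apart(dates: Sequence[date], days: int = CHRONICITY_DAYS) -> bool:
    if len(dates) < 2:
        return False
    return (max(dates) - min(dates)).days >= days


@dataclass
class PrevalenceSummary:
    """Cohort-level screening summary, computed from raw counts only."""

    n: int
    n_determined: int
    n_ckd: int
    n_ckdu: int
    n_ckd_hypertension: int
    n_ckd_diabetes: int

    @property
    def prevalence(self) -> float:
        """CKD fraction of the screened (determined) population."""
        return self.n_ckd / self.n_determined

    @property
    def ckdu_given_ckd(self) -> float:
        return self.n_ckdu / self.n_ckd if self.n_ckd else float("nan")

    @property
    def ckdu_overall(self) -> float:
        return self.n_ckdu / self.n_determined

    @property
    def hypertension_given_ckd(self) -> float:
        return self.n_ckd_hypertension / self.n_ckd if self.n_ckd else float("nan")

    @property
    def diabetes_given_ckd(self) -> float:
        return self.n_ckd_diabetes / self.n_ckd if self.n_ckd else float("nan")

    def as_dict(self) -> dict:
        """Percentages rounded to one decimal, each from raw counts."""
        pct = lambda x: round(100.0 * x, 1)
        return {
            "n_screened": self.n,
            "n_determined": self.n_determined,
            "n_ckd": self.n_ckd,
            "ckd_prevalence_pct": pct(self.prevalence),
            "ckdu_given_ckd_pct": pct(self.ckdu_given_ckd) if self.n_ckd else None,
            "ckdu_overall_pct": pct(self.ckdu_overall),
            "hypertension_given_ckd_pct": pct(self.hypertension_given_ckd)
            if self.n_ckd
            else None,
            "diabetes_given_ckd_pct": pct(self.diabetes_given_ckd) if self.n_ckd else None,
        }


def prevalence_summary(classifications: Iterable[CkdClassification]) -> PrevalenceSummary:
    """Summarise CKD/CKDu prevalence and risk factors from classifications.

    All fractions are ratios of raw counts (never products of rounded
    percentages), so ``ckdu_overall == ckdu_given_ckd * prevalence`` holds
    exactly at the count level.  Undetermined records are excluded from the
    denominator.
    """
    cls = list(classifications)
    if not cls:
        raise ValidationError("classifications: empty input")
    det = [c for c in cls if not c.undetermined]
    if not det:
        raise ValidationError("classifications: no determinable records")
    ckd = [c for c in det if c.is_ckd]
    return PrevalenceSummary(
        n=len(cls),
        n_determined=len(det),
        n_ckd=len(ckd),
        n_ckdu=sum(c.is_ckdu for c in ckd),
        n_ckd_hypertension=sum(c.hypertension for c in ckd),
        n_ckd_diabetes=sum(c.diabetes for c in ckd),
    )


# ---------------------------------------------------------------------------
# Sodium audit
# ---------------------------------------------------------------------------


@dataclass
class SodiumAudit:
    """Per-site dish counts against a sodium standard (default 600 mg/dish)."""

    site: str
    n_meet: int
    n_over: int
    threshold: float = 600.0

    @property
    def total(self) -> int:
        return self.n_meet + self.n_over

    @property
    def percent_over(self) -> float:
        return 100.0 * self.n_over / self.total if self.total else float("nan")


@dataclass
class SodiumAuditResult:
    sites: list[SodiumAudit]
    threshold: float

    @property
    def n_meet(self) -> int:
        return sum(s.n_meet for s in self.sites)

    @property
    def n_over(self) -> int:
        return sum(s.n_over for s in self.sites)

    @property
    def total(self) -> int:
        return self.n_meet + self.n_over

    @property
    def percent_over(self) -> float:
        return 100.0 * self.n_over / self.total if self.total else float("nan")

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": s.site,
                "n_meet": s.n_meet,
                "n_over": s.n_over,
                "total": s.total,
                "percent_over": round(s.percent_over, 1),
            }
            for s in self.sites
        ]
        rows.append(
            {
                "site": "Total",
                "n_meet": self.n_meet,
                "n_over": self.n_over,
                "total": self.total,
                "percent_over": round(self.percent_over, 1),
            }
        )
        return pd.DataFrame(rows)


def sodium_audit(
    measurements: pd.DataFrame,
    threshold: float = 600.0,
    site_col: str = "site",
    value_col: str = "mg_sodium",
) -> SodiumAuditResult:
    """Audit per-dish sodium measurements against a mg/dish standard.

    A dish "meets" the standard when its sodium content is at or below the
    threshold; anything strictly above is "over".  Percentages are computed
    from counts.
    """
    if site_col not in measurements or value_col not in measurements:
        raise ValidationError(
            f"measurements: required columns {site_col!r}, {value_col!r}"
        )
    values = measurements[value_col].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"{value_col}: sodium measurements must be >= 0")
    sites = []
    for site, grp in measurements.groupby(site_col, sort=False):
        over = int((grp[value_col] > threshold).sum())
        sites.append(
            SodiumAudit(site=str(site), n_meet=len(grp) - over, n_over=over, threshold=threshold)
        )
    return SodiumAuditResult(sites=sites, threshold=threshold)


def sodium_audit_from_counts(
    counts: pd.DataFrame, threshold: float = 600.0
) -> SodiumAuditResult:
    """Run the audit from a per-site count table (columns site, n_meet, n_over).

    Reconstructs one synthetic dish measurement per counted dish (meeting
    dishes at 70% of the threshold, exceeding dishes at 140%) and runs
    :func:`sodium_audit` on the expanded table, so published count tables can
    be pushed through the same code path as raw measurements.
    """
    for col in ("site", "n_meet", "n_over"):
        if col not in counts:
            raise ValidationError(f"counts: required column {col!r}")
    rows = []
    for _, r in counts.iterrows():
        if r["n_meet"] < 0 or r["n_over"] < 0:
            raise ValidationError("counts: n_meet/n_over must be >= 0")
        rows.extend({"site": r["site"], "mg_sodium": 0.7 * threshold} for _ in range(int(r["n_meet"])))
        rows.extend({"site": r["site"], "mg_sodium": 1.4 * threshold} for _ in range(int(r["n_over"])))
    return sodium_audit(pd.DataFrame(rows, columns=["site", "mg_sodium"]), threshold)


def load_sodium_counts() -> pd.DataFrame:
    """Packaged canteen sodium count table (columns site, phase, n_meet, n_over).

    Seven university canteen sites measured before and after a salt-intake
    reduction campaign against the 600 mg/dish healthy-dish standard.
    """
    with resources.files("ckdcare.data").joinpath("sodium_canteen_counts.csv").open() as fh:
        return pd.read_csv(fh)
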