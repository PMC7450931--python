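"""Declarative registry alert engine.

Thirty-eight alert conditions — blood-pressure and laboratory thresholds,
eGFR decline-rate trends, medication-safety combinations, missing-test
process checks and informational registry notices — are shipped as a
structured YAML ruleset and evaluated over a longitudinal participant
record at a given date.

Evaluation semantics: each rule's predicate yields fired / silent /
not-evaluable.  Missing data never fires an alert except for the rules that
are explicitly about absence of testing (11, 12, 28, 33), which fire on
documented absence of the test within a one-year lookback.  A record with
no visits makes every rule not-evaluable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from functools import cached_property
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .staging import STRIP_LEVELS, _ols_slope, classify, egfr

__all__ = [
    "AlertRule",
    "AlertEvent",
    "AlertReport",
    "EvalContext",
    "load_ruleset",
    "default_ruleset",
    "evaluate_alerts",
    "evaluate_cohort",
    "egfr_slope",
    "cockcroft_gault",
]

#: Conditions whose presence marks a person at risk of CKD (rule 33),
#: matched against ``ParticipantRecord.conditions``.
RISK_CONDITIONS = frozenset(
    {
        "gout",
        "sle",
        "nephrotoxic_drugs",
        "recurrent_uti",
        "cardiovascular_disease",
        "polycystic_kidney",
        "congenital_kidney",
        "family_history_kidney",
    }
)

_URINE_PROTEIN_FIELDS = ("urine_protein_strip", "uacr", "upcr", "urine_protein_24h")


def egfr_slope(points: Sequence[tuple[date, float]]) -> float | None:
    """Least-squares eGFR slope in ml/min/1.73 m^2 per year.

    ``points`` is a sequence of (date, eGFR) pairs.  Negative means
    declining.  Returns None (undefined-slope signal) with fewer than two
    points, in which case the decline-rate rules do not fire.
    """
    pts = sorted(points)
    if len(pts) < 2:
        return None
    day0 = pts[0][0]
    return _ols_slope([(d - day0).days for d, _ in pts], [v for _, v in pts])


def cockcroft_gault(scr: float, age: float, weight_kg: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance (ml/min), for dose adjustment."""
    if not scr > 0:
        raise ValidationError(f"scr: must be positive, got {scr}")
    crcl = (140.0 - age) * weight_kg / (72.0 * scr)
    if str(sex).lower().startswith("f"):
        crcl *= 0.85
    return crcl


@dataclass(frozen=True)
class AlertRule:
    rule_id: int
    description: str
    category: str
    condition: dict


@dataclass(frozen=True)
class AlertEvent:
    """A fired rule, with the values that suffice to re-verify it by hand."""

    rule_id: int
    participant_id: str
    date: date
    values: dict


@dataclass
class AlertReport:
    """Outcome of evaluating a ruleset on one record at one date."""

    events: list[AlertEvent]
    not_evaluable: list[int]

    @property
    def fired_ids(self) -> set[int]:
        return {e.rule_id for e in self.events}

    def __iter__(self):
        return iter(self.events)


@dataclass
class EvalContext:
    """Tunable evaluation settings.

    ``lookback_days`` bounds the absence-of-testing rules; ``slope_window_years``
    bounds the history used by the decline-rate rules; ``crcl_drug_table``
    maps drug code -> CrCl cutoff (ml/min) below which dispensing needs
    adjustment (empty by default, leaving rule 31 not-evaluable).
    """

    lookback_days: int = 365
    slope_window_years: float = 5.0
    crcl_drug_table: dict = field(default_factory=dict)
    equation: str = "ckd-epi-2009"


_CATEGORIES = {"threshold", "trend", "medication", "process", "informational"}


def load_ruleset(path) -> list[AlertRule]:
    """Load a ruleset file; ids must be unique integers with known conditions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse_ruleset(raw)


def _parse_ruleset(raw) -> list[AlertRule]:
    rules = []
    seen = set()
    for r in raw["rules"]:
        rid = int(r["id"])
        if rid in seen:
            raise ValidationError(f"rules: duplicate rule id {rid}")
        seen.add(rid)
        if r.get("category") not in _CATEGORIES:
            raise ValidationError(f"rules: rule {rid} has unknown category {r.get('category')!r}")
        cond = r["condition"]
        _validate_condition(rid, cond)
        rules.append(
            AlertRule(rule_id=rid, description=r["description"], category=r["category"], condition=cond)
        )
    return rules


_CONDITION_TYPES = {
    "latest", "latest_true", "strip_at_least", "egfr_latest", "egfr_slope",
    "med_current", "med_absent_all", "med_duration", "flag", "not_flag",
    "annotation", "no_annotation", "absent_test", "scr_rise", "is_ckd",
    "not_ckd", "crcl_dispense", "risk_screening", "any_of", "all_of",
}


def _validate_condition(rid: int, cond: dict) -> None:
    ctype = cond.get("type")
    if ctype not in _CONDITION_TYPES:
        raise ValidationError(f"rules: rule {rid} has unknown condition type {ctype!r}")
    for sub in cond.get("conditions", []):
        _validate_condition(rid, sub)


def default_ruleset() -> list[AlertRule]:
    """The packaged 38-rule registry alert list."""
    with resources.files("ckdcare.data").joinpath("alert_rules.yaml").open() as fh:
        rules = _parse_ruleset(yaml.safe_load(fh))
    assert len(rules) == 38 and {r.rule_id for r in rules} == set(range(1, 39))
    return rules


_OPS = {
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "eq": lambda a, b: a == b,
}


class _RecordView:
    """Pre-digested view of a record at an evaluation date."""

    def __init__(self, record, on_date: date, ctx: EvalContext):
        self.record = record
        self.on_date = on_date
        self.ctx = ctx
        self.visits = sorted(
            (v for v in record.visits if v.date <= on_date), key=lambda v: v.date
        )

    def latest(self, field_name: str):
        """Most recent (date, value) with the field present, or None."""
        for v in reversed(self.visits):
            val = getattr(v, field_name)
            if val is not None:
                return v.date, val
        return None

    @cached_property
    def egfr_points(self) -> list[tuple[date, float]]:
        return [
            (v.date, egfr(v.serum_creatinine, self.record.age, self.record.sex, self.ctx.equation))
            for v in self.visits
            if v.serum_creatinine is not None
        ]

    @cached_property
    def classification(self):
        # classify only what is known at the evaluation date
        rec = dataclasses.replace(self.record, visits=list(self.visits))
        return classify(rec, self.ctx.equation)

    @cached_property
    def current_meds(self) -> frozenset[str] | None:
        for v in reversed(self.visits):
            if v.medications is not None:
                return v.medications
        return None

    def tested_within_lookback(self, fields: Sequence[str], min_count: int = 1) -> bool:
        cutoff = self.on_date - timedelta(days=self.ctx.lookback_days)
        count = 0
        for v in self.visits:
            if v.date > cutoff and any(getattr(v, f) is not None for f in fields):
                count += 1
        return count >= min_count


def _eval(cond: dict, view: _RecordView):
    """Evaluate one condition: (status, values) with status True/False/None."""
    ctype = cond["type"]

    if ctype == "latest":
        hit = view.latest(cond["field"])
        if hit is None:
            return None, {}
        _, val = hit
        return _OPS[cond["op"]](val, cond["value"]), {cond["field"]: val}

    if ctype == "latest_true":
        hit = view.latest(cond["field"])
        if hit is None:
            return None, {}
        _, val = hit
        return bool(val), {cond["field"]: val}

    if ctype == "strip_at_least":
        hit = view.latest("urine_protein_strip")
        if hit is None:
            return None, {}
        _, val = hit
        status = STRIP_LEVELS.index(val) >= STRIP_LEVELS.index(cond["level"])
        return status, {"urine_protein_strip": val}

    if ctype == "egfr_latest":
        if not view.egfr_points:
            return None, {}
        _, val = view.egfr_points[-1]
        return _OPS[cond["op"]](val, cond["value"]), {"egfr": round(val, 2)}

    if ctype == "egfr_slope":
        cutoff_date = view.on_date - timedelta(days=round(view.ctx.slope_window_years * 365.25))
        pts = [(d, g) for d, g in view.egfr_points if d > cutoff_date]
        slope = egfr_slope(pts)
        if slope is None:
            return None, {}
        return _OPS[cond["op"]](slope, cond["value"]), {"egfr_slope_per_year": round(slope, 2)}

    if ctype == "med_current":
        meds = view.current_meds
        if meds is None:
            return None, {}
        hits = meds.intersection(cond["any_of"])
        return bool(hits), {"medications": sorted(hits) if hits else sorted(meds)}

    if ctype == "med_absent_all":
        meds = view.current_meds
        if meds is None:
            return None, {}
        return not meds.intersection(cond["codes"]), {"medications": sorted(meds)}

    if ctype == "med_duration":
        code, min_days = cond["code"], cond["min_days"]
        med_visits = [v for v in view.visits if v.medications is not None]
        if not med_visits:
            return None, {}
        if code not in med_visits[-1].medications:
            return False, {}
        # walk back through the unbroken run of visits carrying the drug
        start = med_visits[-1].date
        for v in reversed(med_visits):
            if code not in v.medications:
                break
            start = v.date
        span = (med_visits[-1].date - start).days
        return span > min_days, {"medication": code, "days_on_record": span}

    if ctype == "flag":
        return _flag_status(cond["name"], view)

    if ctype == "not_flag":
        status, vals = _flag_status(cond["name"], view)
        return (None if status is None else not status), vals

    if ctype == "annotation":
        present = bool(view.record.annotations.get(cond["key"]))
        if present:
            return True, {cond["key"]: view.record.annotations.get(cond["key"])}
        return False, {}

    if ctype == "no_annotation":
        return not bool(view.record.annotations.get(cond["key"])), {}

    if ctype == "absent_test":
        fields = cond["fields"]
        min_count = cond.get("min_count", 1)
        absent = not view.tested_within_lookback(fields, min_count)
        if absent:
            return True, {"missing_tests": list(fields)}
        return False, {}

    if ctype == "scr_rise":
        scrs = [
            (v.date, v.serum_creatinine)
            for v in view.visits
            if v.serum_creatinine is not None
        ]
        if len(scrs) < 2:
            return None, {}
        for (d0, s0), (d1, s1) in zip(scrs, scrs[1:]):
            if s1 - s0 >= cond["delta"]:
                return True, {"scr_from": s0, "scr_to": s1, "date_from": d0, "date_to": d1}
        return False, {}

    if ctype == "is_ckd":
        c = view.classification
        if c.undetermined:
            return None, {}
        if c.is_ckd:
            return True, {"g_stage": c.g_stage}
        return False, {}

    if ctype == "not_ckd":
        c = view.classification
        if c.undetermined:
            return None, {}
        return not c.is_ckd, {}

    if ctype == "crcl_dispense":
        table = view.ctx.crcl_drug_table
        if not table:
            return None, {}
        meds = view.current_meds
        scr_hit = view.latest("serum_creatinine")
        if meds is None or scr_hit is None or view.record.weight_kg is None:
            return None, {}
        crcl = cockcroft_gault(
            scr_hit[1], view.record.age, view.record.weight_kg, view.record.sex
        )
        flagged = sorted(d for d in meds if d in table and crcl < table[d])
        if flagged:
            return True, {"crcl": round(crcl, 1), "drugs_needing_adjustment": flagged}
        return False, {"crcl": round(crcl, 1)}

    if ctype == "risk_screening":
        return _risk_screening(view)

    if ctype in ("any_of", "all_of"):
        statuses, values = [], {}
        for sub in cond["conditions"]:
            s, v = _eval(sub, view)
            statuses.append(s)
            if s:
                values.update(v)
        if ctype == "any_of":
            if any(s is True for s in statuses):
                return True, values
            return (None if any(s is None for s in statuses) else False), {}
        # all_of: a definite False silences the rule even with gaps elsewhere
        if any(s is False for s in statuses):
            return False, {}
        if any(s is None for s in statuses):
            return None, {}
        return True, values

    raise ValidationError(f"condition: unknown type {ctype!r}")


def _flag_status(name: str, view: _RecordView):
    rec = view.record
    if name in ("diabetes", "hypertension", "known_renal_cause"):
        val = getattr(rec, name)
        return bool(val), {name: bool(val)}
    if rec.conditions is None:
        return None, {}
    return name in rec.conditions, {name: name in rec.conditions}


def _risk_screening(view: _RecordView):
    rec = view.record
    risks = []
    if rec.diabetes:
        risks.append("diabetes")
    if rec.hypertension:
        risks.append("hypertension")
    if rec.age > 60:
        risks.append("age>60")
    if rec.known_renal_cause:
        risks.append("known_renal_cause")
    if rec.conditions is None:
        if not risks:
            return None, {}  # risk history never collected
    else:
        risks.extend(sorted(rec.conditions & RISK_CONDITIONS))
    if not risks:
        return False, {}
    scr_ok = view.tested_within_lookback(["serum_creatinine"])
    urine_ok = view.tested_within_lookback(list(_URINE_PROTEIN_FIELDS))
    if scr_ok and urine_ok:
        return False, {}
    missing = [] if scr_ok else ["serum_creatinine"]
    if not urine_ok:
        missing.append("urine_protein_or_albumin")
    return True, {"risk_conditions": risks, "missing_tests": missing}


def evaluate_alerts(
    record,
    on_date: date | None = None,
    ruleset: Sequence[AlertRule] | None = None,
    context: EvalContext | None = None,
    rule_ids: Sequence[int] | None = None,
) -> AlertReport:
    """Evaluate a ruleset over one record at ``on_date``.

    ``on_date`` defaults to the record's last visit date.  ``rule_ids``
    restricts evaluation to a subset; referencing an id not in the ruleset
    is an error.  Returns the fired events together with the ids of rules
    that could not be evaluated for lack of data.
    """
    ruleset = default_ruleset() if ruleset is None else list(ruleset)
    context = context or EvalContext()
    if rule_ids is not None:
        known = {r.rule_id for r in ruleset}
        unknown = sorted(set(rule_ids) - known)
        if unknown:
            raise ValidationError(f"rule_ids: unknown rule id(s) {unknown}")
        ruleset = [r for r in ruleset if r.rule_id in set(rule_ids)]
    if on_date is None:
        if not record.visits:
            raise ValidationError("on_date: required for a record with no visits")
        on_date = max(v.date for v in record.visits)

    view = _RecordView(record, on_date, context)
    events: list[AlertEvent] = []
    not_evaluable: list[int] = []
    for rule in ruleset:
        if not view.visits:
            not_evaluable.append(rule.rule_id)
            continue
        status, values = _eval(rule.condition, view)
        if status is True:
            events.append(
                AlertEvent(rule_id=rule.rule_id, participant_id=record.id, date=on_date, values=values)
            )
        elif status is None:
            not_evaluable.append(rule.rule_id)
    return AlertReport(events=events, not_evaluable=not_evaluable)


def evaluate_cohort(cohort, on_date=None, ruleset=None, context=None):
    """Evaluate alerts for every record; returns a tidy DataFrame of events."""
    import pandas as pd

    rows = []
    for p in cohort:
        if not p.visits and on_date is None:
            continue
        report = evaluate_alerts(p, on_date=on_date, ruleset=ruleset, context=context)
        for e in report.events:
            rows.append(
                {
                    "participant_id": e.participant_id,
                    "date": e.date.isoformat(),
                    "rule_id": e.rule_id,
                    "values": str(e.values),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "date", "rule_id", "values"])
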