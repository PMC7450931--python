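"""Independent, deliberately naive re-implementations used as oracles:

* ``naive_classify`` — brute-force evaluation of the KDIGO CKD predicates
  (all visit pairs enumerated explicitly);
* ``naive_alerts`` — straight-line, per-rule re-implementation of the
  38-rule registry alert list.

These share nothing with the engine's condition interpreter; they operate
directly on the record fields with explicit if-statements.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np

from ckdcare.staging import egfr

STRIP_ORDER = {"neg": 0, "trace": 1, "1+": 2, "2+": 3, "3+": 4}
NOT_EVALUABLE = "NE"


def _visits(record, on_date):
    return sorted((v for v in record.visits if v.date <= on_date), key=lambda v: v.date)


def _latest(visits, field):
    for v in reversed(visits):
        val = getattr(v, field)
        if val is not None:
            return val
    return None


def _egfrs(record, visits):
    return [
        (v.date, egfr(v.serum_creatinine, record.age, record.sex))
        for v in visits
        if v.serum_creatinine is not None
    ]


def naive_classify(record, on_date=None):
    """Brute-force KDIGO predicate: returns (is_ckd, undetermined).

    Enumerates every pair of visits for the two chronic criteria.
    """
    visits = sorted(record.visits, key=lambda v: v.date)
    if on_date is not None:
        visits = [v for v in visits if v.date <= on_date]
    pts = _egfrs(record, visits)
    if not pts:
        return False, True
    low = False
    for i in range(len(pts)):
        for j in range(len(pts)):
            if i == j:
                continue
            di, gi = pts[i]
            dj, gj = pts[j]
            if gi < 60 and gj < 60 and abs((dj - di).days) >= 90:
                low = True
    damage = False
    marks = []
    for v in visits:
        hit = (v.uacr is not None and v.uacr >= 30) or (
            v.urine_protein_strip is not None and STRIP_ORDER[v.urine_protein_strip] >= 2
        )
        if hit:
            marks.append(v.date)
    for a in marks:
        for b in marks:
            if abs((b - a).days) >= 90:
                damage = True
    return (low or damage), False


def _naive_slope(pts, on_date, window_years=5.0):
    cutoff = on_date - timedelta(days=round(window_years * 365.25))
    pts = [(d, g) for d, g in pts if d > cutoff]
    if len(pts) < 2:
        return None
    x = np.array([(d - pts[0][0]).days / 365.25 for d, _ in pts])
    y = np.array([g for _, g in pts])
    return float(np.polyfit(x, y, 1)[0])


def naive_alerts(record, on_date, lookback_days=365):
    """Evaluate every rule with explicit logic; returns (fired, not_evaluable)."""
    fired, ne = set(), set()
    visits = _visits(record, on_date)
    if not visits:
        return set(), set(range(1, 39))

    def latest(field):
        return _latest(visits, field)

    def thresh(rid, field, test):
        val = latest(field)
        if val is None:
            ne.add(rid)
        elif test(val):
            fired.add(rid)

    thresh(1, "sbp", lambda v: v > 130)
    thresh(2, "dbp", lambda v: v > 90)
    thresh(3, "hb", lambda v: v < 10)

    meds = latest("medications")
    if meds is None:
        ne.add(4)
    elif "ACEI" not in meds and "ARB" not in meds:
        fired.add(4)

    pts = _egfrs(record, visits)
    slope = _naive_slope(pts, on_date)
    if slope is None:
        ne.update({5, 20})
    else:
        if slope <= -4:
            fired.add(5)
        if slope < -5:
            fired.add(20)

    thresh(6, "hba1c", lambda v: v < 6.5)
    thresh(7, "hba1c", lambda v: v > 7.5)
    thresh(8, "ldl", lambda v: v > 100)
    thresh(9, "potassium", lambda v: v > 5.5)
    thresh(10, "bicarbonate", lambda v: v < 22)

    cutoff = on_date - timedelta(days=lookback_days)

    def tested(fields, min_count=1):
        return (
            sum(
                1
                for v in visits
                if v.date > cutoff and any(getattr(v, f) is not None for f in fields)
            )
            >= min_count
        )

    if not tested(["urine_protein_strip"]):
        fired.add(11)
    if not tested(["upcr", "urine_protein_24h"]):
        fired.add(12)

    upcr, up24 = latest("upcr"), latest("urine_protein_24h")
    if (upcr is not None and upcr >= 500) or (up24 is not None and up24 >= 500):
        fired.add(13)
    elif upcr is None or up24 is None:
        ne.add(13)

    thresh(14, "phosphate", lambda v: v > 4.5)
    pth = latest("pth_abnormal")
    if pth is None:
        ne.add(15)
    elif pth:
        fired.add(15)

    ann = record.annotations
    if ann.get("hemodialysis_started") and not ann.get("avf_prepared"):
        fired.add(16)
    if ann.get("education_class"):
        fired.add(17)
    if ann.get("egfr_ckd_notice"):
        fired.add(18)

    if pts:
        g = pts[-1][1]
        if g < 60:
            fired.add(19)
        if g < 30:
            fired.update({21, 36})
        if g < 15:
            fired.add(37)
        if g < 30:
            if meds is None:
                ne.add(22)
            elif "metformin" in meds:
                fired.add(22)
    else:
        ne.update({19, 21, 36, 37})
        if meds is not None and "metformin" not in meds:
            pass  # definitely not on metformin: rule 22 is silent
        else:
            ne.add(22)

    uacr = latest("uacr")
    # 23: diabetic, albuminuria > 30, no RAAS blockade
    if not record.diabetes:
        pass
    elif uacr is not None and uacr <= 30:
        pass
    elif meds is not None and ("ACEI" in meds or "ARB" in meds):
        pass
    elif uacr is None or meds is None:
        ne.add(23)
    else:
        fired.add(23)
    # 24: non-diabetic, albuminuria > 300, no RAAS blockade
    if record.diabetes:
        pass
    elif uacr is not None and uacr <= 300:
        pass
    elif meds is not None and ("ACEI" in meds or "ARB" in meds):
        pass
    elif uacr is None or meds is None:
        ne.add(24)
    else:
        fired.add(24)

    if meds is None:
        ne.add(25)
    elif "ACEI" in meds or "ARB" in meds:
        fired.add(25)

    if ann.get("acei_arb_stopped_adverse"):
        fired.add(26)

    strip = latest("urine_protein_strip")
    if strip is None:
        ne.add(27)
    elif STRIP_ORDER[strip] >= 2:
        fired.add(27)

    if record.diabetes and not tested(["uacr"], min_count=2):
        fired.add(28)

    def nsaid_long():
        mv = [v for v in visits if v.medications is not None]
        if not mv:
            return None
        if "NSAID" not in mv[-1].medications:
            return False
        start = mv[-1].date
        for v in reversed(mv):
            if "NSAID" not in v.medications:
                break
            start = v.date
        return (mv[-1].date - start).days > 14

    is_ckd, undet = naive_classify(record, on_date)
    long_nsaid = nsaid_long()
    # 29: not CKD, NSAIDs for more than two weeks
    if undet or long_nsaid is None:
        if long_nsaid is False or (not undet and is_ckd):
            pass
        else:
            ne.add(29)
    elif not is_ckd and long_nsaid:
        fired.add(29)
    # 30: CKD on NSAIDs
    if undet or meds is None:
        if (not undet and not is_ckd) or (meds is not None and "NSAID" not in meds):
            pass
        else:
            ne.add(30)
    elif is_ckd and "NSAID" in meds:
        fired.add(30)

    ne.add(31)  # no CrCl dispensing table configured

    if ann.get("aki_history"):
        fired.add(32)

    # 33: at risk of CKD but not screened within a year
    risk_known_pos = (
        record.diabetes
        or record.hypertension
        or record.age > 60
        or record.known_renal_cause
        or (
            record.conditions is not None
            and bool(
                record.conditions
                & {
                    "gout", "sle", "nephrotoxic_drugs", "recurrent_uti",
                    "cardiovascular_disease", "polycystic_kidney",
                    "congenital_kidney", "family_history_kidney",
                }
            )
        )
    )
    if record.conditions is None and not (
        record.diabetes or record.hypertension or record.age > 60 or record.known_renal_cause
    ):
        ne.add(33)
    elif risk_known_pos:
        scr_ok = tested(["serum_creatinine"])
        urine_ok = tested(["urine_protein_strip", "uacr", "upcr", "urine_protein_24h"])
        if not (scr_ok and urine_ok):
            fired.add(33)

    rbc = latest("urine_rbc")
    if (strip is not None and STRIP_ORDER[strip] >= 2) or rbc:
        fired.add(34)
    elif strip is None or rbc is None:
        ne.add(34)

    scrs = [v.serum_creatinine for v in visits if v.serum_creatinine is not None]
    if len(scrs) < 2:
        ne.add(35)
    elif any(b - a >= 0.3 for a, b in zip(scrs, scrs[1:])):
        fired.add(35)

    k = latest("potassium")
    on_raas = None if meds is None else ("ACEI" in meds or "ARB" in meds)
    if on_raas is False:
        pass
    elif k is not None and k <= 5:
        pass
    elif on_raas is None or k is None:
        ne.add(38)
    else:
        fired.add(38)

    return fired, ne
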