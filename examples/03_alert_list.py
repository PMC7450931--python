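"""Evaluate the 38-rule registry alert list on one patient record.

The record below is a 68-year-old man with advancing CKD: eGFR has fallen
below 30, potassium is high while on an ACE inhibitor, and he is still on
metformin.  Each fired rule prints with the values that justify it; rules
that lack the data they need are listed as not-evaluable rather than
silently skipped.
"""

from datetime import date

from ckdcare import ParticipantRecord, VisitRecord, default_ruleset, evaluate_alerts

patient = ParticipantRecord(
    id="DEMO-68M",
    age=68,
    sex="male",
    diabetes=True,
    hypertension=True,
    conditions=frozenset(),
    visits=[
        VisitRecord(
            date=date(2023, 1, 10), serum_creatinine=2.1, sbp=142, dbp=84,
            potassium=4.9, hba1c=8.1, urine_protein_strip="1+", uacr=180.0,
            medications=frozenset({"ACEI", "metformin"}),
        ),
        VisitRecord(
            date=date(2023, 11, 20), serum_creatinine=2.6, sbp=138, dbp=82,
            potassium=5.3, hba1c=7.9, urine_protein_strip="2+", uacr=260.0,
            medications=frozenset({"ACEI", "metformin"}),
        ),
    ],
)

rules = {r.rule_id: r for r in default_ruleset()}
report = evaluate_alerts(patient)

print(f"fired {len(report.events)} of 38 rules:\n")
for event in report.events:
    print(f"  [{event.rule_id:>2}] {rules[event.rule_id].description[:64]}")
    print(f"       values: {event.values}")
print(f"\nnot evaluable (missing data): {report.not_evaluable}")
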