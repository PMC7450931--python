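# Registry alert list: 38 parameters/conditions evaluated over a patient's
# EMR to flag unmet care targets or unsafe prescribing.  `description` is the
# registry wording; `condition` is the machine-readable predicate evaluated
# by ckdcare.alerts.  Categories: threshold, trend, medication, process,
# informational.
rules:
- id: 1
  description: "Systolic blood pressure > 130 mm of Hg"
  category: threshold
  condition: {type: latest, field: sbp, op: gt, value: 130}
- id: 2
  description: "Diastolic blood pressure > 90 mm of Hg"
  category: threshold
  condition: {type: latest, field: dbp, op: gt, value: 90}
- id: 3
  description: "Hemoglobin < 10 g/dl"
  category: threshold
  condition: {type: latest, field: hb, op: lt, value: 10}
- id: 4
  description: "Not receiving angiotensin-converting-enzyme inhibitor (ACEI) and angiotensin II-receptor blocker (ARB)"
  category: medication
  condition: {type: med_absent_all, codes: [ACEI, ARB]}
- id: 5
  description: "Slope of estimated glomerular filtration rate (eGFR) per period >=4"
  category: trend
  condition: {type: egfr_slope, op: le, value: -4}
- id: 6
  description: "HbA1C < 6.5%"
  category: threshold
  condition: {type: latest, field: hba1c, op: lt, value: 6.5}
- id: 7
  description: "HbA1C > 7.5%"
  category: threshold
  condition: {type: latest, field: hba1c, op: gt, value: 7.5}
- id: 8
  description: "LDL cholesterol > 100 mg/dl"
  category: threshold
  condition: {type: latest, field: ldl, op: gt, value: 100}
- id: 9
  description: "Serum potassium > 5.5 mEq/L"
  category: threshold
  condition: {type: latest, field: potassium, op: gt, value: 5.5}
- id: 10
  description: "Serum bicarbonate < 22 mEq/L"
  category: threshold
  condition: {type: latest, field: bicarbonate, op: lt, value: 22}
- id: 11
  description: "Not evaluated with urine protein strip"
  category: process
  condition: {type: absent_test, fields: [urine_protein_strip]}
- id: 12
  description: "Not evaluated for urine protein to creatinine ratio (UPCR) or urine protein 24 h"
  category: process
  condition: {type: absent_test, fields: [upcr, urine_protein_24h]}
- id: 13
  description: "UPCR >=500 mg/g or Urine protein 24 h >= 500 mg /day"
  category: threshold
  condition:
    type: any_of
    conditions:
    - {type: latest, field: upcr, op: ge, value: 500}
    - {type: latest, field: urine_protein_24h, op: ge, value: 500}
- id: 14
  description: "Serum phosphate > 4.5 mg/L"
  category: threshold
  condition: {type: latest, field: phosphate, op: gt, value: 4.5}
- id: 15
  description: "Serum parathyroid hormone (PTH) is not normal"
  category: threshold
  condition: {type: latest_true, field: pth_abnormal}
- id: 16
  description: "Did not receive AVF preparation before starting hemodialysis"
  category: process
  condition:
    type: all_of
    conditions:
    - {type: annotation, key: hemodialysis_started}
    - {type: no_annotation, key: avf_prepared}
- id: 17
  description: "Participated in educational classes on various topics"
  category: informational
  condition: {type: annotation, key: education_class}
- id: 18
  description: "Notify this eGFR and CKD period and within the past 3 months"
  category: informational
  condition: {type: annotation, key: egfr_ckd_notice}
- id: 19
  description: "eGFR value < 60 should see a doctor"
  category: threshold
  condition: {type: egfr_latest, op: lt, value: 60}
- id: 20
  description: "There is a decrease in the rate of GFR over 5 ml/min/1.73 m^2 per year"
  category: trend
  condition: {type: egfr_slope, op: lt, value: -5}
- id: 21
  description: "eGFR< 30 received a consultation on RRT"
  category: threshold
  condition: {type: egfr_latest, op: lt, value: 30}
- id: 22
  description: "eGFR< 30 also received metformin"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: egfr_latest, op: lt, value: 30}
    - {type: med_current, any_of: [metformin]}
- id: 23
  description: "Diabetic patients with albuminuria > 30 mg/day and not receiving ACEI or ARB"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: flag, name: diabetes}
    - {type: latest, field: uacr, op: gt, value: 30}
    - {type: med_absent_all, codes: [ACEI, ARB]}
- id: 24
  description: "No diabetes, have albuminuria > 300 mg/day and do not receive ACEI or ARB"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: not_flag, name: diabetes}
    - {type: latest, field: uacr, op: gt, value: 300}
    - {type: med_absent_all, codes: [ACEI, ARB]}
- id: 25
  description: "Received ACEI/ARB, be aware of the occurrence of AKI and hyperkalemia. Advice should be given."
  category: medication
  condition: {type: med_current, any_of: [ACEI, ARB]}
- id: 26
  description: "Have received ACEI or ARB but had to stop the drug because of an adverse event"
  category: informational
  condition: {type: annotation, key: acei_arb_stopped_adverse}
- id: 27
  description: "Protein content in urine >=1+"
  category: threshold
  condition: {type: strip_at_least, level: "1+"}
- id: 28
  description: "Diabetics who do not check urine albumin at least 2 times a year"
  category: process
  condition:
    type: all_of
    conditions:
    - {type: flag, name: diabetes}
    - {type: absent_test, fields: [uacr], min_count: 2}
- id: 29
  description: "Not being a CKD and receiving NSAIDs for more than 2 weeks"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: not_ckd}
    - {type: med_duration, code: NSAID, min_days: 14}
- id: 30
  description: "CKD patients receiving NSAIDs"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: is_ckd}
    - {type: med_current, any_of: [NSAID]}
- id: 31
  description: "Time for dispensing in the program if there is a drug that needs to be adjusted according to creatinine clearance (CrCl), if wrongly ordered, there will be a warning every time or if there is no adjustment according to CrCl, remind every time"
  category: medication
  condition: {type: crcl_dispense}
- id: 32
  description: "The history of diagnosing an acute kidney injury last day, month, year"
  category: informational
  condition: {type: annotation, key: aki_history}
- id: 33
  description: "There is a disease or condition that is at risk of CKD, being tested for serum creatinine and urine protein or albumin once a year (diabetes, hypertension, gout, SLE, over 60 years old, receiving nephrotoxic drugs, upper urinary tract infection >=3 times a year, with cardiovascular disease, polycystic kidney disease, kidney disease from birth, have a history of kidney disease in the family)"
  category: process
  condition: {type: risk_screening}
- id: 34
  description: "UA detection of proteins or red blood cells in urine, consider sending a doctor"
  category: threshold
  condition:
    type: any_of
    conditions:
    - {type: strip_at_least, level: "1+"}
    - {type: latest_true, field: urine_rbc}
- id: 35
  description: "Serum creatinine increases more than or equal to 0.3 mg/dl: acute kidney injury should determine the cause"
  category: trend
  condition: {type: scr_rise, delta: 0.3}
- id: 36
  description: "GFR < 30 ml/min/1.73m^2 consider sending for consultation to a doctor"
  category: threshold
  condition: {type: egfr_latest, op: lt, value: 30}
- id: 37
  description: "GFR < 15 ml/min/1.73m^2 should submit assessment for preparation for renal replacement therapy"
  category: threshold
  condition: {type: egfr_latest, op: lt, value: 15}
- id: 38
  description: "Being on ACEI/ARB and serum potassium > 5 mEq/L"
  category: medication
  condition:
    type: all_of
    conditions:
    - {type: med_current, any_of: [ACEI, ARB]}
    - {type: latest, field: potassium, op: gt, value: 5}
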