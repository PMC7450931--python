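# ckdcare

Tools for studying community chronic kidney disease (CKD) programs when the
underlying registry and screening data cannot be shared: a calibrated
synthetic screening-cohort generator, a KDIGO-based staging and prevalence
module, a 38-rule registry alert engine, and a Markov cohort
cost-effectiveness model comparing a comprehensive CKD-care program with
conventional care. It is aimed at health-services researchers and
epidemiologists who need the full computational chain of such a program —
generate → stage → alert → cost-effectiveness — to be runnable, testable
and reproducible on a laptop.

## The models

**KDIGO classification.** A participant has CKD when kidney damage or
reduced filtration persists for at least three months: two eGFR values
< 60 ml/min/1.73 m² at visits ≥ 90 days apart, or a damage marker
(UACR ≥ 30 mg/g or urine dipstick ≥ 1+) on two such visits. eGFR comes from
the CKD-EPI 2009 creatinine equation (no race term; the 2021 refit is
selectable). G-stages follow the standard bins (G1 ≥ 90 … G5 < 15);
A-categories follow UACR (A1 < 30, A2 30–300, A3 > 300 mg/g). CKD without
diabetes, hypertension, or another recognized renal cause is flagged CKDu
(CKD of unknown etiology).

**Synthetic cohorts.** Generation is latent-status-first: each participant
draws a latent CKD status (mean prevalence = `p_ckd_target`, rising with
age), then comorbidity and CKDu status conditionally, then a
stage-consistent eGFR set point, annual slope and albuminuria set point,
and finally per-visit serum creatinine by inverting CKD-EPI around the
latent trajectory with log-normal noise (default CV 0.08), plus blood
pressure, labs, dipstick and medications with 10% per-field missingness.
Classifying the generated records recovers the configured targets to
within binomial error.

**Alert engine.** The 38 registry alert conditions (BP and lab thresholds,
eGFR decline-rate trends, medication-safety combinations such as
RAAS-blockade with potassium > 5 mEq/L or metformin below eGFR 30,
missing-test process checks, and informational notices) ship as a
declarative YAML ruleset. Missing data never fires an alert — except the
rules explicitly about absence of testing, which fire on documented absence
within a one-year lookback.

**Markov cost-effectiveness.** A discrete-time cohort model over
{CKD3, CKD4, CKD5/ESRD, post-stroke, post-AMI, CHF, dead} with annual
cycles accrues discounted costs (Baht) and QALYs over a lifetime horizon.
A care strategy applies relative risks to stage-progression and
complication transitions for a limited effect duration (freed probability
mass returns to the stay-in-state probability) and charges an annual
program cost to living patients. The incremental cost-effectiveness ratio
is ICER = ΔC/ΔE on unrounded totals, with dominance labels when the signs
disagree; threshold, scenario, one-way (tornado) and PSA-hook analyses are
built in. The packaged parameter set is synthetic (see
`src/ckdcare/data/markov_params_synthetic.yaml`): it is structurally
faithful but not a transcription of any published costing table.

## Worked example

```python
from ckdcare import GeneratorConfig, classify, generate_cohort, prevalence_summary

cohort = generate_cohort(GeneratorConfig(n_participants=2205, seed=20170512))
print(prevalence_summary([classify(p) for p in cohort]).as_dict())
```

```
{'n_screened': 2205, 'n_determined': 2205, 'n_ckd': 590,
 'ckd_prevalence_pct': 26.8, 'ckdu_given_ckd_pct': 32.4,
 'ckdu_overall_pct': 8.7, 'hypertension_given_ckd_pct': 39.8,
 'diabetes_given_ckd_pct': 31.5}
```

Of 2,205 screened adults, 26.8% are classified CKD through the full
eGFR/chronicity chain; about a third of the CKD group has no known cause
(8.7% of everyone screened), and hypertension and diabetes are the leading
comorbidities of the CKD group. At n = 2,205 the conditional percentages
carry sampling noise of a couple of points around their calibration
targets (43.2% hypertension, 35.8% diabetes, 28.9% CKDu among CKD).

The cost-effectiveness base case (`python examples/04_cost_effectiveness.py`):

```
comprehensive-care: cost 379,513 Baht, 9.04 QALYs
conventional-care:  cost 378,037 Baht, 8.69 QALYs
incremental: +1,476 Baht for +0.355 QALYs -> ICER 4,156 Baht/QALY
```

A 1,000 Baht/patient/year program buys 0.355 discounted QALYs per patient
for a net 1,476 Baht — far below typical willingness-to-pay. The threshold
analysis shows the ICER rising linearly with program cost and crossing
160,000 Baht/QALY between 13,000 and 14,000 Baht/yr under the synthetic
parameter set.

The `examples/` directory holds one short narrative script per capability;
the `ckdcare` console command exposes the same stages
(`synth`, `stage`, `alerts`, `cea`, `pipeline`) for shell use.

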