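# Methods

This note records the models, default parameters and design choices behind
`ckdcare`, and what its tests do and do not establish.

## KDIGO staging

eGFR uses the CKD-EPI 2009 creatinine equation without the race
coefficient; the 2021 refit is selectable per call (`equation=
"ckd-epi-2021"`). The race term is inapplicable to the Thai practice
setting the package emulates. The classifier implements the chronic
definition directly:

* **Reduced filtration**: two eGFR values < 60 ml/min/1.73 m² at visits at
  least 90 days apart (90 days operationalises "three months or longer").
* **Kidney damage**: UACR ≥ 30 mg/g or urine dipstick ≥ 1+ at two visits at
  least 90 days apart. Imaging-based damage markers are out of scope — only
  laboratory markers exist in the record schema.

Boundary conventions: eGFR exactly 60 is *not* reduced (strict `<`); UACR
exactly 30 is already A2 and exactly 300 still A2 (A3 is strictly
`> 300`). G-stage bins are half-open and exhaustive, so every computable
eGFR maps to exactly one stage. When the reduced-filtration criterion
holds, the G-stage comes from the latest *confirmed* (< 60) value, so a
single noisy rebound above 60 cannot promote a confirmed G3 patient to G2.
A record with a suggestive single finding is flagged `provisional`; a
record with no usable creatinine is `undetermined` and excluded from
prevalence denominators.

CKDu is defined operationally: classified CKD without diabetes,
hypertension, or a known renal cause (stones, lupus, polycystic disease and
similar, collapsed into one flag). Reported percentages are always ratios
of raw counts — never products of rounded fractions — so the "CKDu among
all screened" figure equals "CKDu among CKD" × prevalence exactly at the
count level. Published screening reports that derive these three
percentages by independent rounding will not reconcile exactly; the
package does not force them to.

## Synthetic screening cohorts

The generator is latent-status-first: measurement distributions are derived
from an assigned status rather than the reverse, because the quantities a
screening program reports (prevalences, comorbidity fractions) are exactly
the targets a generator must be steerable toward.

Defaults (the study conditions the package is calibrated to): CKD
prevalence target 26.8%; hypertension 43.2% and diabetes 35.8% among CKD;
CKDu 28.9% among CKD; background hypertension 22%, diabetes 10%, known
renal cause 2% in the non-CKD pool; adults 18–90 (uniform age, CKD
probability linear in age with the configured mean); visits at days
{0, 120, 365} so the chronicity rule is decidable; creatinine log-normal
noise CV 0.08; 10% independent per-field missingness except screening
creatinine, which is never missing. The stage mixture among latent CKD is
G1 12%, G2 33%, G3a 30%, G3b 15%, G4 7%, G5 3%; G1/G2 CKD always carries
albuminuria (it is their only qualifying criterion). Stage eGFR set points
are drawn uniformly within each stage but stop a few units short of the 60
boundary, and the dipstick reading noise is kept below one ordinal step:
both choices keep the probability that measurement noise undoes (or
manufactures) a chronic finding at the few-per-thousand level, which is
what lets downstream classification recover the configured targets within
binomial error without any correction factor. Measured on one 50,000-person
cohort, classifier sensitivity against the latent assignment is ≈ 99.6%
and the false-positive rate ≈ 0.1%.

The CKDu target is honoured by deriving the known-renal-cause probability
among CKD participants free of diabetes/hypertension as
`1 − p_ckdu / ((1 − p_htn)(1 − p_dm))`; a target exceeding the free mass is
rejected at validation. The "CKDu among the no-risk population" figure that
screening programs sometimes quote has an ambiguous denominator (which
risks? assessed when?), so the generator deliberately exposes only
`p_ckdu_given_ckd`.

Annual eGFR slopes: 85% of CKD declines at N(−2, 1) ml/min/1.73 m²/yr and
15% at N(−6.5, 1.5) (rapid progressors, which exercise the decline-rate
alerts); non-CKD drifts at N(−0.4, 0.4). Creatinine is obtained by
inverting CKD-EPI at the visit's latent eGFR, then multiplying log-normal
noise — so the noise model is exact on the creatinine scale, and
approximately CV × 1.209 on the eGFR scale.

Trial arms encode the program's observed 12-month effects as
distributional shifts: intervention mean eGFR higher by 3.34 ml/min/1.73 m²
(49.57 vs 46.23 around the shared control distribution) and blood pressure
lower by 6.2/7.5 mmHg (129.6/76.1 vs 135.8/83.6). The 12-month eGFR is the
endpoint and is encoded exactly (noise enters at baseline), so arm means
carry the configured shift without attenuation.

What the generator does **not** emulate: village/spatial structure,
ultrasound findings, body-composition variables, informative missingness,
within-person measurement batch effects, or loss to follow-up. Passing
calibration tests therefore shows the pipeline recovers the *configured*
statistical structure — it says nothing about how any real registry
deviates from that structure.

Randomness: one integer master seed; every stream (demographics, latent
status, comorbidity, severity, visit noise, labs, missingness, medications,
trial) derives from it through a fixed sub-stream label, so adding a stream
never perturbs existing ones and identical configurations serialize
byte-identically.

## Alert engine

Rules are data (`data/alert_rules.yaml`): id, registry wording, category,
and a machine-readable condition evaluated by a small interpreter. Each
evaluation returns fired / silent / not-evaluable. Semantics fixed here:

* Missing data never fires a rule, with the single exception of the four
  rules that are *about* absent testing (11, 12, 28, 33); those fire on
  documented absence within a one-year lookback (configurable).
* In a conjunction, a definitely-false clause silences the rule even when
  other clauses lack data; otherwise any data gap makes it not-evaluable.
  A record with no visits makes every rule not-evaluable.
* The eGFR decline rules use the least-squares slope of eGFR on time over
  a configurable window (default: all history up to 5 years; negative =
  declining). "Slope per period ≥ 4" is read as decline ≥ 4 ml/min/1.73
  m²/yr, i.e. OLS slope ≤ −4; the over-5 rule is strict (< −5). Fewer than
  two dated values is an undefined-slope signal and neither rule fires.
* Thresholds are implemented exactly as worded, including the strictness
  of each inequality, the 130/90 mmHg pair (which mixes guideline
  conventions — intent is not second-guessed), and the low-HbA1c
  over-treatment alert that fires on literally normal values. Two
  consequences worth knowing: the "not on RAAS blockade" rule and the
  "on RAAS blockade, counsel about AKI/hyperkalemia" rule are
  complementary — every record with a known medication list fires exactly
  one of them — and the two eGFR < 30 rules (RRT consultation and doctor
  referral) always fire together.
* The renally-dosed-drug rule is a hook: it needs a user-supplied
  drug → CrCl cutoff table (none is bundled, so it is not-evaluable by
  default) and uses Cockcroft–Gault clearance, which requires body weight.
* Informational rules (education class, eGFR/CKD notice, AKI history,
  RAAS-blockade stopped for adverse event) fire on the presence of the
  corresponding registry annotation.

Every fired event carries the triggering values, sufficient to re-verify
the predicate by hand. The test suite checks each rule against a dedicated
firing and silencing fixture and checks the whole engine against an
independent straight-line re-implementation on 1,000 random partial
records.

## Markov cost-effectiveness model

States: CKD stage 3, stage 4, stage 5/ESRD, post-stroke, post-AMI, CHF,
dead. One-year cycles; start-of-cycle accrual by default with an optional
half-cycle correction (off by default so matrix-power hand calculations
reproduce the trace exactly); discounting at (1+r)^(−t·cycle) with r = 3%/yr
(standard health-technology-assessment practice in the region);
lifetime horizon = cohort age 100 or living occupancy < 1e-6, whichever
comes first. Mass conservation is asserted at 1e-10 every cycle and the
dead state must be absorbing.

Strategy application is the replication-critical convention: a relative
risk multiplies the targeted off-diagonal probability and the freed mass
is added to the *stay-in-state* probability (not redistributed
proportionally). Program effects and the program cost apply only within
the effect duration (default 5 years); the cost is charged only to living
occupancy. Complications are event transitions: entering post-stroke,
post-AMI or CHF charges a one-off acute cost at incidence, and the state
carries its own chronic cost and utility decrement thereafter. Background
age-indexed other-cause mortality is deliberately not layered on top: the
packaged matrices are static, which keeps the matrix-power oracle exact;
an age-dependent parameterization can be expressed by supplying the
matrix per run.

Default strategy: 1,000 Baht/patient/year for five years; relative risks
0.8 on stage 3→4, 0.75 on stage 4→5, 0.8 on complication incidence —
"slowed by 20%/25%" is read as a relative risk on the per-cycle
probability, not a rate reduction; at these magnitudes the two differ by
under one percent of the probability.

The packaged parameter file is **synthetic** (marked so in its name and
header): the costing and utility assumptions behind published lifetime
totals for this kind of program live in supplementary material that is not
publicly deposited, so no transcription exists here and the package makes
no claim to reproduce published cost/QALY/ICER totals. The synthetic set
was chosen to be internally consistent and structurally faithful: a CKD5
state representing the rural mix of dialysis and conservative management
(blended 95,000 Baht/yr, 35%/yr mortality — a pure-dialysis costing would
make the program strongly cost-saving, which is not the decision problem
being modelled), a steep cost gradient across stages, and utilities
declining from 0.85 (stage 3) to 0.55–0.62 (post-complication states).
Under it the base case yields a small positive incremental cost and an
ICER in the low thousands of Baht/QALY, rising linearly with the annual
program cost and crossing 160,000 Baht/QALY between 13,000 and 14,000
Baht/yr; with no complication effect at 6,000 Baht/yr the program stays
below that region. Replacing the file with a transcribed table is the
supported route to replicating a specific published model; correctness of
the engine itself rests on the property suite (matrix-power oracle,
closed-form geometric QALY sums, exact null-strategy recovery, cost
linearity, discount monotonicity).

The probabilistic-sensitivity hook runs user-specified override
distributions only; it ships uncalibrated because no patient-level utility
or cost data are packaged.

## Pipeline and reproducibility

`run_pipeline` validates the entire config before any stage runs, executes
generate → classify → alert → CEA, and writes a manifest (tool version,
SHA-256 of the config text, master seed, per-stage outputs, timestamps).
Environment variables are never consulted. All outputs except the
manifest's timestamps are byte-reproducible from config + seed.

Problem sizes used by the packaged checks: screening cohorts of 2,205
(the two-subdistrict screening scale) and 50,000 (to pin the calibration
within ±0.6 points); 10,000 for the binomial-interval calibration
property; 5,000 per arm for trial-effect recovery; 1,000 random records
for the alert-engine oracle comparison.

## Known limitations

* The classifier's A-staging uses the latest UACR only; confirmed
  A-staging (persistence of the category itself) is not implemented.
* Visit ages are treated as fixed over a record's span when computing
  eGFR (screening records span about a year; the error is < 1%).
* The generator's calibration constants were set under the default noise
  CV and visit schedule; configurations far from the defaults (very high
  noise, two tightly spaced visits) will recover targets with more bias.
* The Markov model is a cohort model: no individual-level heterogeneity,
  no microsimulation, no age-indexed background mortality in the packaged
  matrices.
* Alert rule wordings with genuinely ambiguous denominators ("per
  period", "albuminuria mg/day" read against mg/g measurements) follow
  the documented readings above rather than attempting reconciliation.
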