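"""Generate a synthetic rural screening cohort and summarise its CKD burden.

Builds 2,205 adult participants (the scale of a two-subdistrict screening
campaign), classifies each against the KDIGO definition, and prints the
prevalence summary.  The percentages are what a screening program would
report: overall CKD prevalence, the share of unknown-etiology CKD (CKDu),
and the comorbidity profile of the CKD group.
"""

from ckdcare import GeneratorConfig, classify, generate_cohort, prevalence_summary

config = GeneratorConfig(n_participants=2205, seed=20170512)
cohort = generate_cohort(config)
summary = prevalence_summary([classify(p) for p in cohort])

for key, value in summary.as_dict().items():
    print(f"{key:>28}: {value}")

print(
    "\nRead: of the screened adults, "
    f"{summary.as_dict()['ckd_prevalence_pct']}% have CKD; "
    f"{summary.as_dict()['ckdu_given_ckd_pct']}% of those have no known cause "
    f"({summary.as_dict()['ckdu_overall_pct']}% of everyone screened)."
)
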