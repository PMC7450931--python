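"""Two-arm comprehensive-care trial: nurse-led multidisciplinary support
versus conventional care.

The generator encodes the trial's 12-month effects as distributional
shifts: +3.34 ml/min/1.73 m^2 mean eGFR and -6.2/-7.5 mmHg blood pressure
in the intervention arm.  At a large synthetic sample the arm summaries
recover those shifts almost exactly.
"""

from ckdcare import GeneratorConfig, arm_summary, generate_trial_arms

config = GeneratorConfig(n_participants=2, seed=11)
arms = generate_trial_arms(config, n_per_arm=5000)

for label, arm in (("intervention", arms.intervention), ("control", arms.control)):
    s = arm_summary(arm)
    print(
        f"{label:>12}: n={s['n']}  mean eGFR(12 m)={s['mean_egfr_12m']:.2f}  "
        f"BP={s['mean_sbp_12m']:.1f}/{s['mean_dbp_12m']:.1f} mmHg"
    )

si, sc = arm_summary(arms.intervention), arm_summary(arms.control)
print(
    f"\nbetween-arm eGFR difference: {si['mean_egfr_12m'] - sc['mean_egfr_12m']:.2f} "
    "ml/min/1.73 m^2 (configured effect: 3.34)"
)
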