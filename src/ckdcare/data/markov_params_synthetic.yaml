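# SYNTHETIC Markov parameter set for the CKD progression model.
#
# This is NOT a transcription of any published cost/utility table: the
# supplementary assumptions behind the published lifetime cost and QALY
# totals are not publicly deposited, so this file provides an internally
# consistent, clearly synthetic parameterization in the same structure
# (annual transition probabilities among CKD stages 3-5/dialysis,
# post-complication states and death; Baht costs per state-year and per
# incident complication; EQ-5D-style utility weights; 3%/yr discounting).
# Magnitudes are chosen to be plausible for Thai CKD care, and the engine's
# correctness is established by its property suite, not by this file.
# Replace this file with a transcribed table to replicate a published model.

states: [CKD3, CKD4, CKD5, post_stroke, post_ami, chf, dead]
event_states: [post_stroke, post_ami, chf]
dead_state: dead
stage_edges:
  stage3_to_4: [CKD3, CKD4]
  stage4_to_5: [CKD4, CKD5]

# Per-cycle (annual) transition probabilities; the stay-in-state
# probability is the residual of each row.  The CKD5 state is end-stage
# disease under a rural-care mix of dialysis and conservative management,
# hence its blended annual cost and high mortality.
transitions:
  CKD3: {CKD4: 0.10, post_stroke: 0.008, post_ami: 0.008, chf: 0.010, dead: 0.020}
  CKD4: {CKD5: 0.12, post_stroke: 0.012, post_ami: 0.012, chf: 0.015, dead: 0.060}
  CKD5: {post_stroke: 0.015, post_ami: 0.015, chf: 0.020, dead: 0.350}
  post_stroke: {dead: 0.080}
  post_ami: {chf: 0.020, dead: 0.060}
  chf: {dead: 0.090}
  dead: {dead: 1.0}

costs:
  # Baht per year of state occupancy (outpatient + inpatient)
  state:
    CKD3: 15000
    CKD4: 32000
    CKD5: 95000
    post_stroke: 60000
    post_ami: 45000
    chf: 55000
    dead: 0
  # one-off Baht cost at incident entry into a complication state
  event:
    post_stroke: 80000
    post_ami: 90000
    chf: 60000

utilities:
  CKD3: 0.85
  CKD4: 0.77
  CKD5: 0.60
  post_stroke: 0.55
  post_ami: 0.68
  chf: 0.62
  dead: 0.0

start_distribution:
  CKD3: 1.0

settings:
  discount_rate: 0.03
  cycle_length: 1.0
  start_age: 60
  horizon: lifetime
  half_cycle_correction: false

strategy:
  name: comprehensive-care
  annual_program_cost: 1000
  rr_stage3_to_4: 0.8
  rr_stage4_to_5: 0.75
  rr_complications: 0.8
  effect_duration: 5
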