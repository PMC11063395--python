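# CohortSpec for `cchrbayes generate --spec examples/cohort_spec.yaml`:
# two equal groups of CCHR-met patients with a 6% vs 6% bleeding rate
# (a null cohort for false-difference checks).
group_sizes:
  doac: 300
  none: 300
met_counts:
  doac: 300
  none: 300
bleed_rate_met: 0.06
bleed_rate_unmet: 0.0
age_profile:
  doac: [83, 0.7]
  none: [59, 0.45]
inr_category_counts: [0, 0, 0]
seed: 0
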