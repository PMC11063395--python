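"""Margin-of-error sample-size arithmetic for the study design.

At an assumed 5% bleeding incidence among CCHR-met patients, estimating
the proportion to an absolute 2% margin with 95% confidence requires 457
patients per group, hence a planned enrolment of at least 914 across the
treated and untreated groups.
"""

from cchrbayes import SampleSizeSpec, planned_recruitment, sample_size_proportion

spec = SampleSizeSpec(p0=0.05, margin=0.02, confidence=0.95)
per_group = sample_size_proportion(spec)
print(f"assumed incidence {spec.p0:.0%}, margin {spec.margin:.0%}, confidence {spec.confidence:.0%}")
print(f"per-group sample size : {per_group}")
print(f"planned recruitment   : {planned_recruitment(per_group, 2)} (two groups)")
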