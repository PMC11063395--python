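"""Apply the Canadian CT Head Rule to individual patients.

Builds three GCS-15 mTBI presentations and prints the rule verdict, the
triggered criteria and the risk tier for each.  A 'met' verdict means the
rule indicates a head CT; 'high' tier criteria predict need for
neurosurgery, 'medium' tier predict clinically important brain injury.
"""

from cchrbayes import (
    InjuryMechanism,
    PatientRecord,
    Sex,
    TherapyClass,
    TherapyIndication,
    apply_cchr,
)


def patient(pid, **overrides):
    base = dict(
        patient_id=pid,
        age=40,
        sex=Sex.FEMALE,
        therapy_class=TherapyClass.NONE,
        therapy_indication=TherapyIndication.NOT_APPLICABLE,
        injury_mechanism=InjuryMechanism.FALL_WALKING,
        gcs_2h=15,
        amnesia_before_impact_min=0,
        vomiting_count=0,
        suspected_open_or_depressed_fracture=False,
        basal_skull_fracture_sign=False,
        dangerous_mechanism=False,
        inr=None,
        ct_bleed=False,
        neurosurgery=False,
        death_30d=False,
        complication_30d=False,
        followup_reached=True,
    )
    base.update(overrides)
    return PatientRecord(**base)


cases = [
    ("74-year-old, low fall, otherwise unremarkable", patient("a", age=74)),
    ("30-year-old, 45 min amnesia before impact", patient("b", age=30, amnesia_before_impact_min=45)),
    ("50-year-old, no criteria", patient("c", age=50)),
]

for label, p in cases:
    a = apply_cchr(p)
    crits = ", ".join(sorted(c.value for c in a.triggered_criteria)) or "-"
    print(f"{label}:")
    print(f"  met={a.met}  tier={a.risk_tier.value}  criteria: {crits}")
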