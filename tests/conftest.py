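import pytest

from cchrbayes import (
    InjuryMechanism,
    PatientRecord,
    Sex,
    TherapyClass,
    TherapyIndication,
    reference_cohort,
)


def make_patient(**overrides) -> PatientRecord:
    """A baseline eligible patient with every CCHR predictor negative."""
    base = dict(
        patient_id="p0",
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


@pytest.fixture(scope="session")
def fixture_cohort():
    return reference_cohort()
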