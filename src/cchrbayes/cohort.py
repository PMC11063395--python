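"""Patient records and the Canadian CT Head Rule (CCHR).

The CCHR indicates a head CT after mild traumatic brain injury when any of
seven criteria holds.  Five are *high risk* (predict need for neurosurgical
intervention): GCS < 15 at 2 h after injury, suspected open or depressed
skull fracture, any sign of basal skull fracture, vomiting two or more
times, age 65 or older.  Two are *medium risk* (predict clinically
important brain injury on CT): amnesia before impact of 30 min or more,
and a dangerous mechanism of injury (pedestrian struck, occupant ejected,
fall from elevation).

This module provides the patient-level record type, the deterministic rule
engine, INR categorisation for vitamin-K-antagonist patients, the study
inclusion filter, and the cohort CSV dialect.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "Sex",
    "TherapyClass",
    "TherapyIndication",
    "InjuryMechanism",
    "Criterion",
    "RiskTier",
    "INRCategory",
    "PatientRecord",
    "CCHRAssessment",
    "IncompleteRecordError",
    "ANTICOAGULANTS",
    "ANTIPLATELETS",
    "apply_cchr",
    "categorize_inr",
    "inclusion_filter",
    "read_cohort_csv",
    "write_cohort_csv",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class TherapyClass(str, enum.Enum):
    NONE = "none"
    VKA = "vka"
    DOAC = "doac"
    HEPARIN = "heparin"
    ASPIRIN = "aspirin"
    P2Y12 = "p2y12"


#: Anticoagulant therapy classes (act on the coagulation cascade).
ANTICOAGULANTS = frozenset({TherapyClass.VKA, TherapyClass.DOAC, TherapyClass.HEPARIN})
#: Anti-platelet therapy classes (inhibit platelet aggregation).
ANTIPLATELETS = frozenset({TherapyClass.ASPIRIN, TherapyClass.P2Y12})


class TherapyIndication(str, enum.Enum):
    AFIB_FLUTTER = "afib_flutter"
    PE = "pe"
    DVT = "dvt"
    IHD = "ihd"
    PRIMARY_PREVENTION = "primary_prevention"
    OTHER_UNKNOWN = "other_unknown"
    NOT_APPLICABLE = "not_applicable"


class InjuryMechanism(str, enum.Enum):
    FALL_WALKING = "fall_walking"
    FALL_GT3M = "fall_gt3m"
    ROAD_ACCIDENT = "road_accident"
    AGGRESSION = "aggression"
    OTHER = "other"


class Criterion(str, enum.Enum):
    """The seven CCHR criteria."""

    GCS_LT15_AT_2H = "gcs_lt15_at_2h"
    OPEN_DEPRESSED_FRACTURE = "open_depressed_fracture"
    BASAL_SKULL_SIGN = "basal_skull_sign"
    VOMITING_GE2 = "vomiting_ge2"
    AGE_GE65 = "age_ge65"
    AMNESIA_GE30MIN = "amnesia_ge30min"
    DANGEROUS_MECHANISM = "dangerous_mechanism"


HIGH_RISK_CRITERIA = frozenset(
    {
        Criterion.GCS_LT15_AT_2H,
        Criterion.OPEN_DEPRESSED_FRACTURE,
        Criterion.BASAL_SKULL_SIGN,
        Criterion.VOMITING_GE2,
        Criterion.AGE_GE65,
    }
)
MEDIUM_RISK_CRITERIA = frozenset(
    {Criterion.AMNESIA_GE30MIN, Criterion.DANGEROUS_MECHANISM}
)


class RiskTier(str, enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    NONE = "none"


class INRCategory(str, enum.Enum):
    """INR bands for VKA patients: subtherapeutic <= 1.5 < therapeutic < 2.5 <= overtherapeutic."""

    SUBTHERAPEUTIC = "subtherapeutic"
    THERAPEUTIC = "therapeutic"
    OVERTHERAPEUTIC = "overtherapeutic"


class IncompleteRecordError(ValueError):
    """A CCHR predictor field is missing; it is never imputed as negative."""


#: Fields the rule engine needs populated.
_PREDICTOR_FIELDS = (
    "age",
    "gcs_2h",
    "amnesia_before_impact_min",
    "vomiting_count",
    "suspected_open_or_depressed_fracture",
    "basal_skull_fracture_sign",
    "dangerous_mechanism",
)


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled patient: demographics, therapy, CCHR predictors, outcomes.

    ``cchr_met_recorded`` is the rule verdict recorded at enrolment.  It is
    normally ``None`` (stratify by the rule engine); it differs from the
    engine's verdict only for a patient whose GCS was assessed too early,
    so the enrolment chart disagrees with a retrospective application of
    the rule.
    """

    patient_id: str
    age: int
    sex: Sex
    therapy_class: TherapyClass
    therapy_indication: TherapyIndication
    injury_mechanism: InjuryMechanism
    gcs_2h: int
    amnesia_before_impact_min: int
    vomiting_count: int
    suspected_open_or_depressed_fracture: bool
    basal_skull_fracture_sign: bool
    dangerous_mechanism: bool
    inr: Optional[float]
    ct_bleed: bool
    neurosurgery: bool
    death_30d: bool
    complication_30d: bool
    followup_reached: bool
    cchr_met_recorded: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 18:
            raise ValueError(f"adults only: age must be >= 18, got {self.age}")
        if self.gcs_2h is not None and not (3 <= self.gcs_2h <= 15):
            raise ValueError(f"gcs_2h must be in 3..15, got {self.gcs_2h}")
        if self.inr is not None and self.therapy_class is not TherapyClass.VKA:
            raise ValueError(
                "inr may only be recorded for VKA patients "
                f"(therapy_class={self.therapy_class.value})"
            )
        if self.inr is not None and not (math.isfinite(self.inr) and self.inr > 0):
            raise ValueError(f"inr must be a positive finite number, got {self.inr}")
        if self.amnesia_before_impact_min is not None and self.amnesia_before_impact_min < 0:
            raise ValueError("amnesia_before_impact_min must be non-negative")
        if self.vomiting_count is not None and self.vomiting_count < 0:
            raise ValueError("vomiting_count must be non-negative")
        if self.neurosurgery and not self.ct_bleed:
            raise ValueError("neurosurgery implies a positive CT (ct_bleed)")

    @property
    def on_therapy(self) -> bool:
        return self.therapy_class is not TherapyClass.NONE

    @property
    def on_anticoagulant(self) -> bool:
        return self.therapy_class in ANTICOAGULANTS

    @property
    def on_antiplatelet(self) -> bool:
        return self.therapy_class in ANTIPLATELETS


@dataclass(frozen=True)
class CCHRAssessment:
    """Rule verdict: met iff at least one criterion triggered."""

    met: bool
    triggered_criteria: frozenset
    risk_tier: RiskTier

    def __post_init__(self) -> None:
        assert self.met == bool(self.triggered_criteria)


def apply_cchr(patient: PatientRecord) -> CCHRAssessment:
    """Evaluate the Canadian CT Head Rule on one patient.

    The rule is met iff at least one of the seven criteria holds.  The risk
    tier is ``high`` if any high-risk criterion triggered, ``medium`` if
    only medium-risk criteria triggered, ``none`` otherwise.

    Raises
    ------
    IncompleteRecordError
        If any predictor field is ``None``.  Missing predictors are hard
        errors, never silently treated as negative.
    """
    for name in _PREDICTOR_FIELDS:
        if getattr(patient, name) is None:
            raise IncompleteRecordError(
                f"incomplete record {patient.patient_id!r}: predictor field "
                f"{name!r} is missing"
            )

    triggered = set()
    if patient.gcs_2h < 15:
        triggered.add(Criterion.GCS_LT15_AT_2H)
    if patient.suspected_open_or_depressed_fracture:
        triggered.add(Criterion.OPEN_DEPRESSED_FRACTURE)
    if patient.basal_skull_fracture_sign:
        triggered.add(Criterion.BASAL_SKULL_SIGN)
    if patient.vomiting_count >= 2:
        triggered.add(Criterion.VOMITING_GE2)
    if patient.age >= 65:
        triggered.add(Criterion.AGE_GE65)
    if patient.amnesia_before_impact_min >= 30:
        triggered.add(Criterion.AMNESIA_GE30MIN)
    if patient.dangerous_mechanism:
        triggered.add(Criterion.DANGEROUS_MECHANISM)

    if triggered & HIGH_RISK_CRITERIA:
        tier = RiskTier.HIGH
    elif triggered:
        tier = RiskTier.MEDIUM
    else:
        tier = RiskTier.NONE
    return CCHRAssessment(met=bool(triggered), triggered_criteria=frozenset(triggered), risk_tier=tier)


def cchr_met(patient: PatientRecord) -> bool:
    """Met status used for stratification: the enrolment-recorded verdict if
    present, otherwise the rule engine's."""
    if patient.cchr_met_recorded is not None:
        return patient.cchr_met_recorded
    return apply_cchr(patient).met


def categorize_inr(inr: float) -> INRCategory:
    """Band an INR value: <=1.5 subtherapeutic, strictly between 1.5 and 2.5
    therapeutic, >=2.5 overtherapeutic.  The bands partition (0, inf)."""
    if not isinstance(inr, (int, float)) or isinstance(inr, bool):
        raise ValueError(f"inr must be a number, got {type(inr).__name__}")
    if not math.isfinite(inr) or inr <= 0:
        raise ValueError(f"inr must be a positive finite number, got {inr}")
    if inr <= 1.5:
        return INRCategory.SUBTHERAPEUTIC
    if inr < 2.5:
        return INRCategory.THERAPEUTIC
    return INRCategory.OVERTHERAPEUTIC


def inclusion_filter(
    patient: PatientRecord,
    hours_since_trauma: float,
    medical_cause: bool,
    seizure: bool,
    pregnant: bool,
    therapy_adherent: bool,
) -> bool:
    """Study inclusion predicate.

    Included iff: GCS 15 at 2 h, presentation within 24 h, no medical cause
    of the trauma, no post-traumatic seizure, not pregnant, and — for
    patients on therapy — regular therapy intake.  Patients on neither
    therapy are included only when they meet the CCHR (they would otherwise
    not undergo CT, so their bleeding status would be unobservable).
    """
    if patient.gcs_2h != 15:
        return False
    if hours_since_trauma > 24:
        return False
    if medical_cause or seizure or pregnant:
        return False
    if patient.on_therapy and not therapy_adherent:
        return False
    if not patient.on_therapy and not apply_cchr(patient).met:
        return False
    return True


# ---------------------------------------------------------------------------
# Cohort CSV dialect: one row per patient, header row, booleans as 0/1,
# missing INR / missing recorded verdict as empty string.

_BOOL_FIELDS = {
    "suspected_open_or_depressed_fracture",
    "basal_skull_fracture_sign",
    "dangerous_mechanism",
    "ct_bleed",
    "neurosurgery",
    "death_30d",
    "complication_30d",
    "followup_reached",
}
_ENUM_FIELDS = {
    "sex": Sex,
    "therapy_class": TherapyClass,
    "therapy_indication": TherapyIndication,
    "injury_mechanism": InjuryMechanism,
}
COHORT_COLUMNS = [f.name for f in fields(PatientRecord)]


def _to_cell(name: str, value):
    if value is None:
        return ""
    if name in _BOOL_FIELDS or name == "cchr_met_recorded":
        return int(value)
    if name in _ENUM_FIELDS:
        return value.value
    return value


def write_cohort_csv(records: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write patient records as delimited text (comma-separated, UTF-8)."""
    rows = [
        {name: _to_cell(name, getattr(r, name)) for name in COHORT_COLUMNS}
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: Union[str, Path]) -> list:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "cchr_met_recorded"]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for name in COHORT_COLUMNS:
            if name not in df.columns:
                kwargs[name] = None
                continue
            raw = getattr(row, name)
            if name in ("inr", "cchr_met_recorded"):
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    kwargs[name] = None
                else:
                    kwargs[name] = bool(int(raw)) if name == "cchr_met_recorded" else float(raw)
            elif name in _BOOL_FIELDS:
                kwargs[name] = bool(int(raw))
            elif name in _ENUM_FIELDS:
                kwargs[name] = _ENUM_FIELDS[name](raw)
            elif name == "patient_id":
                kwargs[name] = str(raw)
            else:
                kwargs[name] = int(raw)
        records.append(PatientRecord(**kwargs))
    return records


def with_recorded_verdict(patient: PatientRecord, met: Optional[bool]) -> PatientRecord:
    """Return a copy of ``patient`` with the enrolment-recorded rule verdict set."""
    return replace(patient, cchr_met_recorded=met)
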