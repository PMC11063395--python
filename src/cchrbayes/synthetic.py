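"""Synthetic GCS-15 mTBI cohorts.

Two entry points:

* :func:`generate_cohort` — a seeded stochastic generator producing cohorts
  with a prescribed stratum structure (group sizes, CCHR-met counts,
  per-stratum bleeding rates), for calibration and replicate studies.
* :func:`reference_cohort` — a fully deterministic 1,015-patient cohort
  reproducing, margin by margin, the published prospective emergency
  department study this package models: 509 patients on anticoagulant or
  anti-platelet therapy (52 VKA / 189 DOAC / 4 heparin / 227 aspirin /
  37 P2Y12 inhibitors) and 506 on neither, 60 CT-positive haemorrhages,
  one neurosurgical intervention, no deaths.

The generator constructs CCHR predictor fields consistently with the rule
engine: every record meant to meet the rule receives at least one triggered
criterion, every record meant not to meet it has all criteria negative
(which forces age < 65).  Bleeds are Bernoulli draws per stratum; nothing
else in the record influences bleeding risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .cohort import (
    ANTICOAGULANTS,
    ANTIPLATELETS,
    Criterion,
    InjuryMechanism,
    PatientRecord,
    Sex,
    TherapyClass,
    TherapyIndication,
)

__all__ = ["CohortSpec", "InfeasibleSpecError", "generate_cohort", "reference_cohort"]


class InfeasibleSpecError(ValueError):
    """The requested margins cannot be realised by any rule-consistent cohort."""


RateLike = Union[float, Mapping[TherapyClass, float]]

#: Study margins: (group size, CCHR-met count) per therapy class.
STUDY_GROUP_SIZES: Dict[TherapyClass, int] = {
    TherapyClass.VKA: 52,
    TherapyClass.DOAC: 189,
    TherapyClass.HEPARIN: 4,
    TherapyClass.ASPIRIN: 227,
    TherapyClass.P2Y12: 37,
    TherapyClass.NONE: 506,
}
STUDY_MET_COUNTS: Dict[TherapyClass, int] = {
    TherapyClass.VKA: 40,
    TherapyClass.DOAC: 135,
    TherapyClass.HEPARIN: 3,
    TherapyClass.ASPIRIN: 174,
    TherapyClass.P2Y12: 35,
    TherapyClass.NONE: 506,
}

# Observed per-category bleeding rates: 14/178 anticoagulated met,
# 9/209 anti-platelet met, 1/67 anti-platelet unmet, 36/506 no-therapy met.
_AC_MET_RATE = 14 / 178
_AP_MET_RATE = 9 / 209
_AP_UNMET_RATE = 1 / 67
_NONE_MET_RATE = 36 / 506

STUDY_BLEED_RATE_MET: Dict[TherapyClass, float] = {
    TherapyClass.VKA: _AC_MET_RATE,
    TherapyClass.DOAC: _AC_MET_RATE,
    TherapyClass.HEPARIN: _AC_MET_RATE,
    TherapyClass.ASPIRIN: _AP_MET_RATE,
    TherapyClass.P2Y12: _AP_MET_RATE,
    TherapyClass.NONE: _NONE_MET_RATE,
}
STUDY_BLEED_RATE_UNMET: Dict[TherapyClass, float] = {
    TherapyClass.VKA: 0.0,
    TherapyClass.DOAC: 0.0,
    TherapyClass.HEPARIN: 0.0,
    TherapyClass.ASPIRIN: _AP_UNMET_RATE,
    TherapyClass.P2Y12: _AP_UNMET_RATE,
    TherapyClass.NONE: 0.0,
}

#: (median age, fraction aged >64 *within the CCHR-met stratum*) per group,
#: as observed.  Used by the deterministic reference cohort.
STUDY_AGE_PROFILE: Dict[TherapyClass, Tuple[int, float]] = {
    TherapyClass.VKA: (83, 0.92),
    TherapyClass.DOAC: (83, 0.95),
    TherapyClass.HEPARIN: (83, 0.95),
    TherapyClass.ASPIRIN: (82, 0.90),
    TherapyClass.P2Y12: (84, 1.00),
    TherapyClass.NONE: (59, 0.45),
}


def _relaxed_group_age_profile() -> Dict[TherapyClass, Tuple[int, float]]:
    """Group-level age profile consistent with the rule engine.

    Anyone aged >= 65 is CCHR-met, so the fraction over 64 in a whole group
    cannot exceed its met fraction.  The observed within-met fractions are
    therefore rescaled to the group level: over-64 count =
    round(within-met fraction x met count)."""
    out: Dict[TherapyClass, Tuple[int, float]] = {}
    for g, n in STUDY_GROUP_SIZES.items():
        median, frac_met = STUDY_AGE_PROFILE[g]
        m = STUDY_MET_COUNTS[g]
        n_over = min(m, round(frac_met * m))
        out[g] = (median, n_over / n if n else 0.0)
    return out

STUDY_MECHANISM_MIX: Dict[InjuryMechanism, float] = {
    InjuryMechanism.FALL_WALKING: 0.761,
    InjuryMechanism.FALL_GT3M: 0.061,
    InjuryMechanism.ROAD_ACCIDENT: 0.096,
    InjuryMechanism.AGGRESSION: 0.034,
    InjuryMechanism.OTHER: 0.048,
}

# How met records that are not already met by age acquire a criterion.
# GCS < 15 is excluded: the study enrols GCS-15 patients only.
DEFAULT_CRITERION_MIX: Dict[Criterion, float] = {
    Criterion.DANGEROUS_MECHANISM: 0.40,
    Criterion.AMNESIA_GE30MIN: 0.30,
    Criterion.VOMITING_GE2: 0.20,
    Criterion.BASAL_SKULL_SIGN: 0.05,
    Criterion.OPEN_DEPRESSED_FRACTURE: 0.05,
}


@dataclass
class CohortSpec:
    """Margins and rates a generated cohort must realise.

    Defaults reproduce the modelled study's structure.  ``bleed_rate_met``
    and ``bleed_rate_unmet`` accept a single float (applied to every group)
    or a per-group mapping.
    """

    group_sizes: Dict[TherapyClass, int] = field(
        default_factory=lambda: dict(STUDY_GROUP_SIZES)
    )
    met_counts: Dict[TherapyClass, int] = field(
        default_factory=lambda: dict(STUDY_MET_COUNTS)
    )
    bleed_rate_met: RateLike = field(
        default_factory=lambda: dict(STUDY_BLEED_RATE_MET)
    )
    bleed_rate_unmet: RateLike = field(
        default_factory=lambda: dict(STUDY_BLEED_RATE_UNMET)
    )
    age_profile: Dict[TherapyClass, Tuple[int, float]] = field(
        default_factory=_relaxed_group_age_profile
    )
    mechanism_mix: Dict[InjuryMechanism, float] = field(
        default_factory=lambda: dict(STUDY_MECHANISM_MIX)
    )
    criterion_mix: Dict[Criterion, float] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_MIX)
    )
    inr_category_counts: Tuple[int, int, int] = (3, 18, 16)
    seed: int = 0

    def rate_for(self, which: str, group: TherapyClass) -> float:
        rates = self.bleed_rate_met if which == "met" else self.bleed_rate_unmet
        if isinstance(rates, Mapping):
            return float(rates.get(group, 0.0))
        return float(rates)

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise InfeasibleSpecError(f"negative group size for {g.value}")
            m = self.met_counts.get(g, 0)
            if not 0 <= m <= n:
                raise InfeasibleSpecError(
                    f"met count {m} outside [0, {n}] for group {g.value}"
                )
            for which in ("met", "unmet"):
                r = self.rate_for(which, g)
                if not 0.0 <= r <= 1.0:
                    raise InfeasibleSpecError(
                        f"bleed rate {r} outside [0, 1] for {which} {g.value}"
                    )
            median, frac = self.age_profile.get(g, (70, 0.5))
            if not 0.0 <= frac <= 1.0:
                raise InfeasibleSpecError(f"age fraction {frac} outside [0, 1]")
            n_over = round(frac * n)
            if n_over > m:
                # anyone aged >= 65 is rule-met, so over-64 records cannot
                # outnumber the met stratum
                raise InfeasibleSpecError(
                    f"group {g.value}: age profile demands {n_over} records "
                    f"aged >= 65 (fraction >64 = {frac}) but only {m} may meet "
                    f"the rule; the {n - m} unmet records require age < 65"
                )
        if any(c < 0 for c in self.inr_category_counts):
            raise InfeasibleSpecError("negative INR category count")
        n_vka = self.group_sizes.get(TherapyClass.VKA, 0)
        if sum(self.inr_category_counts) > n_vka:
            raise InfeasibleSpecError(
                f"{sum(self.inr_category_counts)} INR values requested but only "
                f"{n_vka} VKA records"
            )


_AGES_OVER = (66, 70, 74, 79, 83, 85, 88, 92, 96)
_AGES_UNDER = (22, 28, 34, 41, 47, 52, 58, 63)
_INR_REPRESENTATIVE = {
    "sub": (1.2, 1.3, 1.4),
    "ther": (1.8, 2.0, 2.2),
    "over": (6.6, 2.8, 3.0, 3.4),
}


def _indication_for(group: TherapyClass, j: int) -> TherapyIndication:
    if group in ANTICOAGULANTS:
        # atrial fibrillation/flutter 71%, PE 2.8%, DVT 5.3%, other 20.8%
        cyc = (
            [TherapyIndication.AFIB_FLUTTER] * 71
            + [TherapyIndication.PE] * 3
            + [TherapyIndication.DVT] * 5
            + [TherapyIndication.OTHER_UNKNOWN] * 21
        )
        return cyc[j % len(cyc)]
    if group in ANTIPLATELETS:
        # ischemic heart disease 68.9%, primary prevention 22.7%, other 8.3%
        cyc = (
            [TherapyIndication.IHD] * 69
            + [TherapyIndication.PRIMARY_PREVENTION] * 23
            + [TherapyIndication.OTHER_UNKNOWN] * 8
        )
        return cyc[j % len(cyc)]
    return TherapyIndication.NOT_APPLICABLE


def _mechanism_cycle(mix: Mapping[InjuryMechanism, float]) -> List[InjuryMechanism]:
    cyc: List[InjuryMechanism] = []
    for mech, frac in mix.items():
        cyc.extend([mech] * max(1, round(frac * 100)))
    return cyc


def _build_record(
    *,
    patient_id: str,
    group: TherapyClass,
    j: int,
    met: bool,
    age: int,
    sex: Sex,
    mechanism: InjuryMechanism,
    extra_criterion: Optional[Criterion],
    bleed: bool,
    inr: Optional[float] = None,
    neurosurgery: bool = False,
    followup_reached: bool = True,
    cchr_met_recorded: Optional[bool] = None,
) -> PatientRecord:
    amnesia = 0
    vomiting = 0
    open_fx = False
    basal = False
    dangerous = False
    if extra_criterion is Criterion.AMNESIA_GE30MIN:
        amnesia = 45
    elif extra_criterion is Criterion.VOMITING_GE2:
        vomiting = 2
    elif extra_criterion is Criterion.DANGEROUS_MECHANISM:
        dangerous = True
    elif extra_criterion is Criterion.BASAL_SKULL_SIGN:
        basal = True
    elif extra_criterion is Criterion.OPEN_DEPRESSED_FRACTURE:
        open_fx = True
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        therapy_class=group,
        therapy_indication=_indication_for(group, j),
        injury_mechanism=mechanism,
        gcs_2h=15,
        amnesia_before_impact_min=amnesia,
        vomiting_count=vomiting,
        suspected_open_or_depressed_fracture=open_fx,
        basal_skull_fracture_sign=basal,
        dangerous_mechanism=dangerous,
        inr=inr,
        ct_bleed=bleed,
        neurosurgery=neurosurgery,
        death_30d=False,
        complication_30d=False,
        followup_reached=followup_reached,
        cchr_met_recorded=cchr_met_recorded,
    )


def generate_cohort(spec: CohortSpec) -> List[PatientRecord]:
    """Generate a seeded cohort realising the margins in ``spec``.

    Per group ``g`` exactly ``met_counts[g]`` records meet the CCHR (the
    predictor fields are constructed so the rule engine agrees), the rest
    have every criterion negative.  Ages in the met stratum are >= 65 with
    the group's configured probability; met records aged under 65 draw one
    criterion from ``criterion_mix``.  Bleeds are independent Bernoulli
    draws at the stratum's rate.  Identical spec (including seed) gives an
    identical cohort.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: List[PatientRecord] = []
    criteria = list(spec.criterion_mix)
    crit_p = np.asarray([spec.criterion_mix[c] for c in criteria], dtype=float)
    crit_p = crit_p / crit_p.sum()
    mechs = list(spec.mechanism_mix)
    mech_p = np.asarray([spec.mechanism_mix[m] for m in mechs], dtype=float)
    mech_p = mech_p / mech_p.sum()

    i = 0
    for group in sorted(spec.group_sizes, key=lambda g: g.value):
        n = spec.group_sizes[group]
        m = spec.met_counts.get(group, 0)
        _, frac_over = spec.age_profile.get(group, (70, 0.5))
        n_over = min(m, round(frac_over * n))
        n_inr = sum(spec.inr_category_counts) if group is TherapyClass.VKA else 0
        inr_values: List[Optional[float]] = []
        if n_inr:
            for key, count in zip(("sub", "ther", "over"), spec.inr_category_counts):
                reps = _INR_REPRESENTATIVE[key]
                inr_values.extend(reps[k % len(reps)] for k in range(count))
        inr_values.extend([None] * (n - len(inr_values)))

        for j in range(n):
            met = j < m
            if met:
                over_64 = j < n_over
                age = int(rng.integers(65, 98)) if over_64 else int(rng.integers(18, 65))
                extra = None
                if age < 65:
                    extra = criteria[int(rng.choice(len(criteria), p=crit_p))]
                rate = spec.rate_for("met", group)
            else:
                age = int(rng.integers(18, 65))
                extra = None
                rate = spec.rate_for("unmet", group)
            mech = mechs[int(rng.choice(len(mechs), p=mech_p))]
            if extra is Criterion.DANGEROUS_MECHANISM and mech is InjuryMechanism.FALL_WALKING:
                mech = InjuryMechanism.FALL_GT3M
            bleed = bool(rng.random() < rate)
            records.append(
                _build_record(
                    patient_id=f"S{i:05d}",
                    group=group,
                    j=j,
                    met=met,
                    age=age,
                    sex=Sex.FEMALE if rng.random() < 0.505 else Sex.MALE,
                    mechanism=mech,
                    extra_criterion=extra,
                    bleed=bleed,
                    inr=inr_values[j],
                )
            )
            i += 1
    return records


# Deterministic per-class bleed split in the reference cohort.  Only the
# category totals (14 anticoagulated met, 9 anti-platelet met, 1 anti-platelet
# unmet, 36 no-therapy) are published; the within-category split is a
# documented convention.
_FIXTURE_BLEEDS_MET = {
    TherapyClass.VKA: 4,
    TherapyClass.DOAC: 9,
    TherapyClass.HEPARIN: 1,
    TherapyClass.ASPIRIN: 8,
    TherapyClass.P2Y12: 1,
    TherapyClass.NONE: 36,
}


def reference_cohort() -> List[PatientRecord]:
    """Deterministic 1,015-patient cohort with the modelled study's margins.

    Margins reproduced exactly: group sizes and CCHR-met counts per therapy
    class; 60 haemorrhages (14 anticoagulated, all met; 10 anti-platelet,
    9 met and 1 not met; 36 on neither therapy); 37 VKA records carrying an
    INR, 3 subtherapeutic / 18 therapeutic / 16 overtherapeutic, including
    the observed extremes 1.2 and 6.6; one neurosurgical intervention (the
    not-met aspirin bleeder, aged 74 — recorded as not meeting the rule at
    enrolment because her GCS was assessed on arrival rather than at 2 h);
    no deaths; 20 patients unreached at the one-month follow-up call.

    Everything beyond the published margins (individual ages, sexes,
    mechanisms, indications) is filled by a deterministic round-robin
    scheme, so the cohort is bit-identical across runs and platforms.
    """
    records: List[PatientRecord] = []
    mech_cycle = _mechanism_cycle(STUDY_MECHANISM_MIX)
    # medium/high criterion rotation for met records aged under 65
    extra_cycle = (
        Criterion.DANGEROUS_MECHANISM,
        Criterion.AMNESIA_GE30MIN,
        Criterion.VOMITING_GE2,
        Criterion.DANGEROUS_MECHANISM,
        Criterion.AMNESIA_GE30MIN,
        Criterion.BASAL_SKULL_SIGN,
    )
    group_order = (
        TherapyClass.VKA,
        TherapyClass.DOAC,
        TherapyClass.HEPARIN,
        TherapyClass.ASPIRIN,
        TherapyClass.P2Y12,
        TherapyClass.NONE,
    )
    i = 0
    for group in group_order:
        n = STUDY_GROUP_SIZES[group]
        m = STUDY_MET_COUNTS[group]
        _, frac_over = STUDY_AGE_PROFILE[group]
        n_over = min(m, round(frac_over * m))
        bleeds_met = _FIXTURE_BLEEDS_MET[group]
        inr_values: List[Optional[float]] = []
        if group is TherapyClass.VKA:
            for key, count in zip(("sub", "ther", "over"), (3, 18, 16)):
                reps = _INR_REPRESENTATIVE[key]
                inr_values.extend(reps[k % len(reps)] for k in range(count))
        inr_values.extend([None] * (n - len(inr_values)))

        for j in range(n):
            met = j < m
            if met:
                over_64 = j < n_over
                age = _AGES_OVER[j % len(_AGES_OVER)] if over_64 else _AGES_UNDER[j % len(_AGES_UNDER)]
                if age < 65:  # _AGES_UNDER guarantees this
                    extra = extra_cycle[j % len(extra_cycle)]
                else:
                    extra = None
                bleed = j < bleeds_met
            else:
                age = _AGES_UNDER[j % len(_AGES_UNDER)]
                extra = None
                bleed = False
            mech = mech_cycle[i % len(mech_cycle)]
            if extra is Criterion.DANGEROUS_MECHANISM and mech is InjuryMechanism.FALL_WALKING:
                mech = InjuryMechanism.FALL_GT3M
            records.append(
                _build_record(
                    patient_id=f"R{i:04d}",
                    group=group,
                    j=j,
                    met=met,
                    age=age,
                    sex=Sex.FEMALE if i % 2 == 0 else Sex.MALE,
                    mechanism=mech,
                    extra_criterion=extra,
                    bleed=bleed,
                    inr=inr_values[j],
                )
            )
            i += 1

    # The single not-met bleeder: an aspirin patient aged 74, low fall,
    # recorded at enrolment as not meeting the rule (early GCS assessment),
    # positive CT (subdural haematoma) and neurosurgical evacuation.
    idx = next(
        k
        for k, r in enumerate(records)
        if r.therapy_class is TherapyClass.ASPIRIN
        and r.cchr_met_recorded is None
        and not _is_met_by_construction(r)
    )
    r = records[idx]
    records[idx] = PatientRecord(
        patient_id=r.patient_id,
        age=74,
        sex=Sex.FEMALE,
        therapy_class=TherapyClass.ASPIRIN,
        therapy_indication=TherapyIndication.PRIMARY_PREVENTION,
        injury_mechanism=InjuryMechanism.FALL_WALKING,
        gcs_2h=15,
        amnesia_before_impact_min=0,
        vomiting_count=0,
        suspected_open_or_depressed_fracture=False,
        basal_skull_fracture_sign=False,
        dangerous_mechanism=False,
        inr=None,
        ct_bleed=True,
        neurosurgery=True,
        death_30d=False,
        complication_30d=False,
        followup_reached=True,
        cchr_met_recorded=False,
    )

    # 20 patients unreached at 30-day follow-up, taken deterministically
    # from the tail of the no-therapy non-bleeders.
    unreached = 0
    for k in range(len(records) - 1, -1, -1):
        if unreached == 20:
            break
        r = records[k]
        if r.therapy_class is TherapyClass.NONE and not r.ct_bleed:
            records[k] = PatientRecord(
                **{**_as_kwargs(r), "followup_reached": False}
            )
            unreached += 1
    return records


def _as_kwargs(r: PatientRecord) -> dict:
    from dataclasses import asdict

    return asdict(r)


def _is_met_by_construction(r: PatientRecord) -> bool:
    return (
        r.age >= 65
        or r.vomiting_count >= 2
        or r.amnesia_before_impact_min >= 30
        or r.suspected_open_or_depressed_fracture
        or r.basal_skull_fracture_sign
        or r.dangerous_mechanism
        or r.gcs_2h < 15
    )


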