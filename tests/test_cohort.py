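"""Rule engine, INR banding, inclusion filter and the cohort CSV dialect."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cchrbayes import (
    Criterion,
    INRCategory,
    IncompleteRecordError,
    RiskTier,
    TherapyClass,
    apply_cchr,
    categorize_inr,
    inclusion_filter,
    read_cohort_csv,
    write_cohort_csv,
)
from conftest import make_patient


class TestApplyCCHR:
    @pytest.mark.parametrize(
        "overrides, expected_criteria, tier",
        [
            ({"age": 74}, {Criterion.AGE_GE65}, RiskTier.HIGH),
            ({"vomiting_count": 2}, {Criterion.VOMITING_GE2}, RiskTier.HIGH),
            ({"gcs_2h": 14}, {Criterion.GCS_LT15_AT_2H}, RiskTier.HIGH),
            (
                {"suspected_open_or_depressed_fracture": True},
                {Criterion.OPEN_DEPRESSED_FRACTURE},
                RiskTier.HIGH,
            ),
            ({"basal_skull_fracture_sign": True}, {Criterion.BASAL_SKULL_SIGN}, RiskTier.HIGH),
            ({"amnesia_before_impact_min": 30}, {Criterion.AMNESIA_GE30MIN}, RiskTier.MEDIUM),
            ({"dangerous_mechanism": True}, {Criterion.DANGEROUS_MECHANISM}, RiskTier.MEDIUM),
            (
                {"age": 80, "dangerous_mechanism": True},
                {Criterion.AGE_GE65, Criterion.DANGEROUS_MECHANISM},
                RiskTier.HIGH,
            ),
        ],
    )
    def test_single_criteria_and_tiers(self, overrides, expected_criteria, tier):
        a = apply_cchr(make_patient(**overrides))
        assert a.met
        assert set(a.triggered_criteria) == expected_criteria
        assert a.risk_tier == tier

    def test_all_negative_is_not_met(self):
        a = apply_cchr(make_patient(age=30, amnesia_before_impact_min=10))
        assert not a.met
        assert a.risk_tier is RiskTier.NONE
        assert not a.triggered_criteria

    @pytest.mark.parametrize(
        "age, amnesia, expected_met",
        [(64, 29, False), (65, 0, True), (40, 29, False), (40, 30, True)],
    )
    def test_threshold_boundaries(self, age, amnesia, expected_met):
        a = apply_cchr(make_patient(age=age, amnesia_before_impact_min=amnesia))
        assert a.met == expected_met

    @pytest.mark.parametrize("missing", ["age", "vomiting_count", "dangerous_mechanism"])
    def test_missing_predictor_is_hard_error_naming_field(self, missing):
        p = make_patient()
        p = dataclasses.replace(p, **{missing: None})
        with pytest.raises(IncompleteRecordError, match=missing):
            apply_cchr(p)

    @settings(max_examples=200, deadline=None)
    @given(
        age=st.integers(18, 100),
        vomiting=st.integers(0, 5),
        amnesia=st.integers(0, 120),
        open_fx=st.booleans(),
        basal=st.booleans(),
        dangerous=st.booleans(),
        gcs=st.integers(13, 15),
    )
    def test_monotonicity_worsening_never_unmets(
        self, age, vomiting, amnesia, open_fx, basal, dangerous, gcs
    ):
        """Making any single predictor worse never flips met True -> False."""
        p = make_patient(
            age=age,
            vomiting_count=vomiting,
            amnesia_before_impact_min=amnesia,
            suspected_open_or_depressed_fracture=open_fx,
            basal_skull_fracture_sign=basal,
            dangerous_mechanism=dangerous,
            gcs_2h=gcs,
        )
        before = apply_cchr(p).met
        worse_variants = [
            dataclasses.replace(p, age=age + 10),
            dataclasses.replace(p, vomiting_count=vomiting + 1),
            dataclasses.replace(p, amnesia_before_impact_min=amnesia + 30),
            dataclasses.replace(p, suspected_open_or_depressed_fracture=True),
            dataclasses.replace(p, basal_skull_fracture_sign=True),
            dataclasses.replace(p, dangerous_mechanism=True),
            dataclasses.replace(p, gcs_2h=max(3, gcs - 1)),
        ]
        for worse in worse_variants:
            if before:
                assert apply_cchr(worse).met


class TestCategorizeINR:
    @pytest.mark.parametrize(
        "inr, expected",
        [
            (1.2, INRCategory.SUBTHERAPEUTIC),
            (1.5, INRCategory.SUBTHERAPEUTIC),
            (1.51, INRCategory.THERAPEUTIC),
            (1.78, INRCategory.THERAPEUTIC),
            (2.49, INRCategory.THERAPEUTIC),
            (2.5, INRCategory.OVERTHERAPEUTIC),
            (6.6, INRCategory.OVERTHERAPEUTIC),
        ],
    )
    def test_bands(self, inr, expected):
        assert categorize_inr(inr) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            categorize_inr(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=50.0, allow_nan=False))
    def test_partition_of_positive_reals(self, inr):
        """Every positive INR lands in exactly one category."""
        cat = categorize_inr(inr)
        assert cat in INRCategory
        if inr <= 1.5:
            assert cat is INRCategory.SUBTHERAPEUTIC
        elif inr < 2.5:
            assert cat is INRCategory.THERAPEUTIC
        else:
            assert cat is INRCategory.OVERTHERAPEUTIC


class TestInclusionFilter:
    def kwargs(self, **over):
        base = dict(
            hours_since_trauma=2.0,
            medical_cause=False,
            seizure=False,
            pregnant=False,
            therapy_adherent=True,
        )
        base.update(over)
        return base

    def test_on_therapy_eligible(self):
        p = make_patient(therapy_class=TherapyClass.DOAC)
        assert inclusion_filter(p, **self.kwargs())

    def test_no_therapy_requires_cchr_met(self):
        unmet = make_patient()  # no criteria, no therapy
        met = make_patient(age=70)
        assert not inclusion_filter(unmet, **self.kwargs())
        assert inclusion_filter(met, **self.kwargs())

    def test_delayed_presentation_excluded(self):
        p = make_patient(therapy_class=TherapyClass.ASPIRIN)
        assert not inclusion_filter(p, **self.kwargs(hours_since_trauma=30.0))

    @pytest.mark.parametrize("flag", ["medical_cause", "seizure", "pregnant"])
    def test_exclusion_flags(self, flag):
        p = make_patient(therapy_class=TherapyClass.VKA)
        assert not inclusion_filter(p, **self.kwargs(**{flag: True}))

    def test_gcs_below_15_excluded(self):
        p = make_patient(therapy_class=TherapyClass.DOAC, gcs_2h=14)
        assert not inclusion_filter(p, **self.kwargs())

    def test_non_adherent_therapy_excluded(self):
        p = make_patient(therapy_class=TherapyClass.DOAC)
        assert not inclusion_filter(p, **self.kwargs(therapy_adherent=False))


class TestRecordValidation:
    def test_minor_rejected(self):
        with pytest.raises(ValueError, match="18"):
            make_patient(age=17)

    def test_inr_only_for_vka(self):
        with pytest.raises(ValueError, match="VKA"):
            make_patient(therapy_class=TherapyClass.DOAC, inr=2.0)
        make_patient(therapy_class=TherapyClass.VKA, inr=2.0)  # ok

    def test_neurosurgery_implies_bleed(self):
        with pytest.raises(ValueError, match="ct_bleed"):
            make_patient(neurosurgery=True, ct_bleed=False)


class TestCohortCSV:
    def test_roundtrip(self, tmp_path, fixture_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(fixture_cohort, path)
        back = read_cohort_csv(path)
        assert back == fixture_cohort

    def test_booleans_and_missing_inr_serialization(self, tmp_path):
        p = make_patient(therapy_class=TherapyClass.VKA, inr=2.5)
        q = make_patient(patient_id="p1", therapy_class=TherapyClass.DOAC)
        path = tmp_path / "two.csv"
        write_cohort_csv([p, q], path)
        text = path.read_text()
        header = text.splitlines()[0]
        assert header.startswith("patient_id,age,sex,therapy_class")
        rows = text.splitlines()[1:]
        assert rows[0].split(",")[12] == "2.5"
        assert rows[1].split(",")[12] == ""  # missing INR is empty

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,age\np0,40\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort_csv(path)
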