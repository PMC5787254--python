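"""Unit and property tests of the Frail-VIG scoring rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from frailvig.instrument import (
    BAND_LABELS,
    BINARY_ITEMS,
    DISEASE_ITEMS,
    N_DEFICITS,
    CognitiveLevel,
    DepressiveStatus,
    DiseaseStatus,
    ScoringError,
    ValidationError,
    categorize,
    cognitive_from_gds,
    is_frail,
    map_barthel,
    map_cognitive,
    score_assessment,
)

from conftest import make_record, random_record


def oracle_points(record) -> int:
    """Independent point total: a literal restatement of the scoring table."""
    points = sum(int(bool(getattr(record, item))) for item in BINARY_ITEMS)
    b = record.barthel
    points += 0 if b >= 95 else 1 if b >= 65 else 2 if b >= 25 else 3
    points += {"none": 0, "mild_moderate": 1, "severe": 2}[record.cognitive.value]
    points += int(record.depressive == DepressiveStatus.YES)
    points += sum(int(getattr(record, item)) for item in DISEASE_ITEMS)
    return points


class TestMapBarthel:
    @pytest.mark.parametrize(
        "barthel,points",
        [(100, 0), (95, 0), (90, 1), (65, 1), (60, 2), (45, 2), (25, 2), (20, 3), (0, 3)],
    )
    def test_dependency_bands(self, barthel, points):
        assert map_barthel(barthel) == points

    @pytest.mark.parametrize("bad", [-5, 105, 47, 12.5])
    def test_rejects_off_scale_values(self, bad):
        with pytest.raises(ValidationError):
            map_barthel(bad)

    def test_optional_rounding_to_five(self):
        assert map_barthel(47, round_to_five=True) == map_barthel(45)
        assert map_barthel(93, round_to_five=True) == map_barthel(95)

    def test_error_names_patient(self):
        with pytest.raises(ValidationError, match="p17"):
            map_barthel(47, patient_id="p17")


class TestMapCognitive:
    @pytest.mark.parametrize(
        "level,points",
        [(CognitiveLevel.NONE, 0), ("mild_moderate", 1), (CognitiveLevel.SEVERE, 2)],
    )
    def test_levels(self, level, points):
        assert map_cognitive(level) == points

    def test_unknown_level(self):
        with pytest.raises(ValidationError):
            map_cognitive("profound")

    @pytest.mark.parametrize(
        "gds,level",
        [
            (1, CognitiveLevel.NONE),
            (2, CognitiveLevel.MILD_MODERATE),
            (5, CognitiveLevel.MILD_MODERATE),
            (6, CognitiveLevel.SEVERE),
            (7, CognitiveLevel.SEVERE),
        ],
    )
    def test_gds_equivalence(self, gds, level):
        assert cognitive_from_gds(gds) is level

    @pytest.mark.parametrize("bad", [0, 8, 3.5])
    def test_gds_range(self, bad):
        with pytest.raises(ValidationError):
            cognitive_from_gds(bad)


class TestScoreAssessment:
    def test_no_deficits(self):
        result = score_assessment(make_record())
        assert result.total_points == 0
        assert result.score == 0.0
        assert not result.frail
        assert result.category == BAND_LABELS[0]

    def test_saturation_without_advanced(self):
        record = make_record(
            barthel=0,
            cognitive=CognitiveLevel.SEVERE,
            depressive=DepressiveStatus.YES,
            **{item: True for item in BINARY_ITEMS},
            **{item: DiseaseStatus.PRESENT for item in DISEASE_ITEMS},
        )
        result = score_assessment(record)
        assert result.total_points == 25
        assert result.score == 1.0

    def test_worked_seven_point_example(self, worked_record):
        result = score_assessment(worked_record)
        assert result.total_points == 7
        assert result.score == pytest.approx(0.28)
        assert result.category == "0.3 (0.26–0.35)"
        assert result.frail

    def test_advanced_disease_adds_one_point(self, worked_record):
        worked_record.disease_cardiac = DiseaseStatus.ADVANCED
        result = score_assessment(worked_record)
        assert result.total_points == 8
        assert result.score == pytest.approx(0.32)

    def test_score_capped_at_one_with_advanced(self):
        record = make_record(
            barthel=0,
            cognitive=CognitiveLevel.SEVERE,
            depressive=DepressiveStatus.YES,
            **{item: True for item in BINARY_ITEMS},
            **{item: DiseaseStatus.ADVANCED for item in DISEASE_ITEMS},
        )
        result = score_assessment(record)
        assert result.total_points == 31
        assert result.score == 1.0

    def test_per_patient_advanced_mode_single_bonus(self):
        record = make_record(
            disease_cardiac=DiseaseStatus.ADVANCED,
            disease_renal=DiseaseStatus.ADVANCED,
        )
        per_disease = score_assessment(record)
        per_patient = score_assessment(record, advanced_mode="per_patient")
        assert per_disease.total_points == 4
        assert per_patient.total_points == 3

    def test_domain_points_sum_to_total(self):
        rng = np.random.default_rng(5)
        for i in range(50):
            result = score_assessment(random_record(rng, patient_id=f"d{i}"))
            assert sum(result.domain_points.values()) == result.total_points
            assert sum(result.item_points.values()) == result.total_points

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            record = random_record(rng, patient_id=f"o{i}")
            assert score_assessment(record).total_points == oracle_points(record)

    def test_missing_item_strict_error(self):
        record = make_record(falls=None)
        with pytest.raises(ScoringError, match="falls"):
            score_assessment(record)

    def test_missing_item_rescales_denominator(self):
        record = make_record(falls=None, delirium=True)
        result = score_assessment(record, missing_policy="rescale")
        assert result.denominator == 24
        assert result.score == pytest.approx(1 / 24)

    def test_rescale_refuses_above_five_percent_missing(self):
        record = make_record(barthel=None)  # 3 of 25 potential deficits
        with pytest.raises(ScoringError, match="5%"):
            score_assessment(record, missing_policy="rescale")

    def test_depressive_not_evaluable_scores_zero_with_warning(self):
        record = make_record(depressive=DepressiveStatus.NOT_EVALUABLE)
        result = score_assessment(record)
        assert result.total_points == 0
        assert result.warnings
        with pytest.raises(ScoringError):
            score_assessment(record, not_evaluable_policy="error")


class TestCategorize:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.0, "0.1 (0–0.15)"),
            (0.16, "0.2 (0.16–0.25)"),
            (0.28, "0.3 (0.26–0.35)"),
            (0.44, "0.4 (0.36–0.45)"),
            (0.46, "0.5 (0.46–0.55)"),
            (0.56, "0.6 (0.56–0.65)"),
            (1.0, "0.7 (0.66–1)"),
        ],
    )
    def test_printed_intervals(self, score, label):
        assert categorize(score) == label

    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            categorize(bad)

    @pytest.mark.parametrize("score,frail", [(0.25, False), (0.28, True), (0.0, False)])
    def test_frailty_threshold_is_strict(self, score, frail):
        assert is_frail(score) is frail

    @given(st.integers(min_value=0, max_value=25))
    def test_frail_iff_band_above_second(self, k):
        score = k / 25
        assert is_frail(score) == (categorize(score) in BAND_LABELS[2:])


@st.composite
def record_strategy(draw):
    return make_record(
        patient_id="h",
        barthel=draw(st.integers(0, 20)) * 5,
        cognitive=draw(st.sampled_from(list(CognitiveLevel))),
        depressive=draw(st.sampled_from([DepressiveStatus.NO, DepressiveStatus.YES])),
        **{item: draw(st.booleans()) for item in BINARY_ITEMS},
        **{item: draw(st.sampled_from(list(DiseaseStatus))) for item in DISEASE_ITEMS},
    )


class TestScoreProperties:
    @given(record_strategy())
    def test_score_on_25th_lattice_without_advanced(self, record):
        for item in DISEASE_ITEMS:
            if getattr(record, item) is DiseaseStatus.ADVANCED:
                setattr(record, item, DiseaseStatus.PRESENT)
        result = score_assessment(record)
        assert result.total_points <= N_DEFICITS
        assert result.score == pytest.approx(result.total_points / 25)

    @given(record_strategy())
    def test_adding_any_deficit_never_decreases_score(self, record):
        base = score_assessment(record).score
        for item in BINARY_ITEMS:
            if not getattr(record, item):
                worse = make_record(**{**record.__dict__, item: True})
                assert score_assessment(worse).score >= base
        for item in DISEASE_ITEMS:
            status = getattr(record, item)
            if status is not DiseaseStatus.ADVANCED:
                worse = make_record(**{**record.__dict__, item: DiseaseStatus(status + 1)})
                assert score_assessment(worse).score >= base
        if record.barthel > 0:
            worse = make_record(**{**record.__dict__, "barthel": record.barthel - 5})
            assert score_assessment(worse).score >= base
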