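"""Testing pathways: schedules, screens, referral and diagnosis."""
import numpy as np
import pytest

from amblyosim import HealthState, StrategyName, reference_draw
from amblyosim import TestResult as ScreenResult
from amblyosim.strategies import (
    adherence_probability,
    optometrist_diagnose,
    prob_positive_given_conclusive,
    prob_tested,
    refer_and_attend,
    referral_probability,
    screen_child,
    screening_branch_probabilities,
)
from amblyosim.strategies import testing_schedule as schedule_for

PC, SCHOOL, OPT = StrategyName.PRIMARY_CARE, StrategyName.SCHOOL, StrategyName.OPTOMETRIC


class TestSchedule:
    @pytest.mark.parametrize(
        "strategy,age,expected",
        [
            (PC, 3, True),
            (PC, 4, True),
            (PC, 5, True),
            (PC, 6, False),
            (SCHOOL, 3, False),
            (SCHOOL, 5, True),
            (SCHOOL, 6, False),
            (OPT, 3, True),
            (OPT, 4, False),
        ],
    )
    def test_eligibility(self, strategy, age, expected):
        assert schedule_for(strategy, age) is expected

    def test_once_only_optometric(self):
        assert schedule_for(OPT, 3, already_examined=True) is False

    def test_no_testing_after_age_five_any_strategy(self):
        for s in StrategyName:
            for age in range(6, 18):
                assert schedule_for(s, age) is False

    def test_configurable_exam_age(self):
        assert schedule_for(OPT, 4, exam_age=4) is True
        assert schedule_for(OPT, 3, exam_age=4) is False


class TestProbabilities:
    def test_tested_probability(self, ref_draw):
        assert prob_tested(PC, 4, ref_draw) == pytest.approx(0.84 * 0.61)
        assert prob_tested(SCHOOL, 5, ref_draw) == 0.81
        assert prob_tested(SCHOOL, 4, ref_draw) == 0.0
        assert prob_tested(OPT, 3, ref_draw) == 0.88

    def test_operating_characteristics(self, ref_draw):
        assert prob_positive_given_conclusive(PC, HealthState.UNTREATED_AMBLYOPIA, ref_draw) == 0.659
        assert prob_positive_given_conclusive(PC, HealthState.UNTREATED_RISK_FACTOR, ref_draw) == 0.586
        assert prob_positive_given_conclusive(PC, HealthState.HEALTHY, ref_draw) == pytest.approx(1 - 0.398)
        assert prob_positive_given_conclusive(SCHOOL, HealthState.HEALTHY, ref_draw) == pytest.approx(1 - 0.121)
        # a treated child screens like a healthy one
        assert prob_positive_given_conclusive(SCHOOL, HealthState.TREATED_AMBLYOPIA, ref_draw) == pytest.approx(1 - 0.121)

    def test_referral_and_adherence_tables(self, ref_draw):
        assert referral_probability(PC, 3, ScreenResult.POSITIVE, ref_draw) == 0.66
        assert referral_probability(PC, 5, ScreenResult.INCONCLUSIVE, ref_draw) == 0.50
        assert adherence_probability(PC, 5, ScreenResult.POSITIVE, ref_draw) == 0.42
        assert referral_probability(SCHOOL, 5, ScreenResult.INCONCLUSIVE, ref_draw) == 1.00
        assert adherence_probability(SCHOOL, 5, ScreenResult.POSITIVE, ref_draw) == 0.66


class TestScreenChild:
    def test_sensitivity_frequency(self, ref_draw, rng):
        # force testing and conclusive results; positives should track the
        # published sensitivity for untreated amblyopia (0.659)
        d = reference_draw()
        d.p_well_child_visit = 1.0
        d.p_primary_care_screen = 1.0
        d.p_inconclusive_pc = {k: 0.0 for k in d.p_inconclusive_pc}
        n = 20_000
        pos = sum(
            screen_child(PC, 4, HealthState.UNTREATED_AMBLYOPIA, d, rng).result
            == ScreenResult.POSITIVE
            for _ in range(n)
        )
        se = np.sqrt(0.659 * (1 - 0.659) / n)
        assert abs(pos / n - 0.659) < 3 * se

    def test_false_positive_frequency_school(self, rng):
        d = reference_draw()
        d.p_school_screen = 1.0
        d.p_inconclusive_school = {k: 0.0 for k in d.p_inconclusive_school}
        n = 20_000
        pos = sum(
            screen_child(SCHOOL, 5, HealthState.HEALTHY, d, rng).result == ScreenResult.POSITIVE
            for _ in range(n)
        )
        p = 1 - 0.121
        se = np.sqrt(p * (1 - p) / n)
        assert abs(pos / n - p) < 3 * se

    def test_zero_uptake_never_tests(self, rng):
        d = reference_draw()
        d.p_well_child_visit = 0.0
        d.p_school_screen = 0.0
        d.p_optometric_exam_uptake = 0.0
        for s, age in [(PC, 4), (SCHOOL, 5), (OPT, 3)]:
            for _ in range(50):
                ev = screen_child(s, age, HealthState.HEALTHY, d, rng)
                assert not ev.tested
                assert ev.result == ScreenResult.NOT_TESTED

    def test_optometric_bypasses_screening(self, rng):
        d = reference_draw()
        d.p_optometric_exam_uptake = 1.0
        ev = screen_child(OPT, 3, HealthState.UNTREATED_AMBLYOPIA, d, rng)
        assert ev.attended_optometrist
        assert ev.result == ScreenResult.NOT_TESTED

    def test_dead_child_rejected(self, ref_draw, rng):
        with pytest.raises(ValueError):
            screen_child(PC, 4, HealthState.DEAD, ref_draw, rng)


class TestReferAndAttend:
    def test_attendance_frequency_pc_positive_age3(self, ref_draw, rng):
        n = 20_000
        att = sum(
            refer_and_attend(PC, 3, ScreenResult.POSITIVE, ref_draw, rng) for _ in range(n)
        )
        p = 0.66 * 0.63
        se = np.sqrt(p * (1 - p) / n)
        assert abs(att / n - p) < 3 * se

    def test_school_inconclusive(self, ref_draw, rng):
        n = 20_000
        att = sum(
            refer_and_attend(SCHOOL, 5, ScreenResult.INCONCLUSIVE, ref_draw, rng)
            for _ in range(n)
        )
        p = 1.00 * 0.66
        se = np.sqrt(p * (1 - p) / n)
        assert abs(att / n - p) < 3 * se

    def test_negative_never_attends(self, ref_draw, rng):
        for result in (ScreenResult.NEGATIVE, ScreenResult.NOT_TESTED):
            assert refer_and_attend(PC, 4, result, ref_draw, rng) is False


class TestOptometristDiagnosis:
    def test_forced_accuracy(self, rng):
        d = reference_draw()
        d.accuracy_optometrist = 1.0
        assert optometrist_diagnose(HealthState.UNTREATED_AMBLYOPIA, d, rng) == "amblyopia"
        assert optometrist_diagnose(HealthState.UNTREATED_RISK_FACTOR, d, rng) == "risk_factor"
        assert optometrist_diagnose(HealthState.HEALTHY, d, rng) is None

    def test_diagnosis_frequency(self, ref_draw, rng):
        n = 20_000
        hits = sum(
            optometrist_diagnose(HealthState.UNTREATED_AMBLYOPIA, ref_draw, rng)
            == "amblyopia"
            for _ in range(n)
        )
        se = np.sqrt(0.95 * 0.05 / n)
        assert abs(hits / n - 0.95) < 3 * se

    def test_healthy_never_treated(self, ref_draw, rng):
        # misclassification of a healthy child still returns "no condition"
        assert all(
            optometrist_diagnose(HealthState.HEALTHY, ref_draw, rng) is None
            for _ in range(2000)
        )


class TestBranchAudit:
    def test_screening_branches_sum_to_one(self, ref_draw):
        for strategy in StrategyName:
            for state in (s for s in HealthState if s != HealthState.DEAD):
                for age in range(3, 18):
                    probs = screening_branch_probabilities(strategy, state, age, ref_draw)
                    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_testing_cost_after_five(self, ref_draw):
        for strategy in StrategyName:
            for age in range(6, 18):
                probs = screening_branch_probabilities(
                    strategy, HealthState.UNTREATED_AMBLYOPIA, age, ref_draw
                )
                assert probs["not_tested"] == 1.0
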