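"""The three vision-testing pathways.

* ``PRIMARY_CARE`` (reference): screening during well-child visits, annually
  at ages 3-5. A screen happens only if the child attends a visit (p=0.84)
  and the physician screens (p=0.61 given a visit). Positive or inconclusive
  results may be referred to an optometrist; referral and adherence depend on
  age and on the result type.
* ``SCHOOL``: a single screen by contract screeners in senior kindergarten
  (age 5, p=0.81), with certain referral and 0.66 adherence.
* ``OPTOMETRIC``: one mandated comprehensive optometric examination (uptake
  0.88), placed at age 3 by default; no screening step — attendance implies
  direct diagnosis.

Screens first resolve "inconclusive" with a condition-specific probability;
the conclusive remainder is positive with the condition-specific sensitivity
(diseased states) or one minus specificity (healthy/treated states). The
optometrist classifies the true state correctly with 95% accuracy;
misclassification returns "no condition" — there is no false-treatment
pathway. Every attendee incurs the diagnostic-exam cost regardless of truth.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterDraw
from .states import CONDITION_CLASS, HealthState

__all__ = [
    "StrategyName",
    "TestResult",
    "ScreeningEvent",
    "REFERENCE_STRATEGY",
    "testing_schedule",
    "prob_tested",
    "prob_inconclusive",
    "prob_positive_given_conclusive",
    "referral_probability",
    "adherence_probability",
    "screen_child",
    "refer_and_attend",
    "optometrist_diagnose",
    "screening_branch_probabilities",
]


class StrategyName(str, enum.Enum):
    PRIMARY_CARE = "primary_care"
    SCHOOL = "school"
    OPTOMETRIC = "optometric"


REFERENCE_STRATEGY = StrategyName.PRIMARY_CARE


class TestResult(str, enum.Enum):
    POSITIVE = "positive"
    INCONCLUSIVE = "inconclusive"
    NEGATIVE = "negative"
    NOT_TESTED = "not_tested"


@dataclass
class ScreeningEvent:
    """Record of one cycle's testing chain for one child."""

    visited: bool = False  # well-child visit (primary care only)
    tested: bool = False
    result: TestResult = TestResult.NOT_TESTED
    referred: bool = False
    attended_optometrist: bool = False
    diagnosed_condition: str | None = None
    treated: bool = False


def testing_schedule(
    strategy: StrategyName,
    age: int,
    already_examined: bool = False,
    exam_age: int = 3,
) -> bool:
    """Is a child of this age eligible for testing under the strategy?

    Primary care: ages 3-5 annually. School: age 5 only. Optometric: the
    single mandated exam age only (and never if already examined). No
    strategy tests after age 5.
    """
    if age > 5:
        return False
    if strategy == StrategyName.PRIMARY_CARE:
        return 3 <= age <= 5
    if strategy == StrategyName.SCHOOL:
        return age == 5
    if strategy == StrategyName.OPTOMETRIC:
        return age == exam_age and not already_examined
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# pure probability helpers (shared by the scalar ops and the array engine)


def prob_tested(strategy: StrategyName, age: int, draw: ParameterDraw) -> float:
    """Marginal probability of actually being tested in an eligible cycle."""
    if not testing_schedule(strategy, age, exam_age=draw.optometric_exam_age):
        return 0.0
    if strategy == StrategyName.PRIMARY_CARE:
        return draw.p_well_child_visit * draw.p_primary_care_screen
    if strategy == StrategyName.SCHOOL:
        return draw.p_school_screen
    return draw.p_optometric_exam_uptake


def prob_inconclusive(
    strategy: StrategyName, state: HealthState, draw: ParameterDraw
) -> float:
    cls = CONDITION_CLASS[state]
    if strategy == StrategyName.PRIMARY_CARE:
        return draw.p_inconclusive_pc[cls]
    if strategy == StrategyName.SCHOOL:
        return draw.p_inconclusive_school[cls]
    return 0.0  # the optometric exam has no inconclusive branch


def prob_positive_given_conclusive(
    strategy: StrategyName, state: HealthState, draw: ParameterDraw
) -> float:
    cls = CONDITION_CLASS[state]
    if strategy == StrategyName.PRIMARY_CARE:
        sens_amb, sens_arf, spec = (
            draw.sens_pc_amblyopia,
            draw.sens_pc_risk_factor,
            draw.spec_pc,
        )
    elif strategy == StrategyName.SCHOOL:
        sens_amb, sens_arf, spec = (
            draw.sens_school_amblyopia,
            draw.sens_school_risk_factor,
            draw.spec_school,
        )
    else:
        raise ValueError("the optometric exam is not a screen")
    if cls == "amblyopia":
        return sens_amb
    if cls == "risk_factor":
        return sens_arf
    return 1.0 - spec


def referral_probability(
    strategy: StrategyName, age: int, result: TestResult, draw: ParameterDraw
) -> float:
    if result not in (TestResult.POSITIVE, TestResult.INCONCLUSIVE):
        return 0.0
    if strategy == StrategyName.PRIMARY_CARE:
        table = (
            draw.referral_after_positive_pc
            if result == TestResult.POSITIVE
            else draw.referral_after_inconclusive_pc
        )
        return table[age]
    if strategy == StrategyName.SCHOOL:
        return (
            draw.referral_school_positive
            if result == TestResult.POSITIVE
            else draw.referral_school_inconclusive
        )
    raise ValueError("the optometric strategy has no referral step")


def adherence_probability(
    strategy: StrategyName, age: int, result: TestResult, draw: ParameterDraw
) -> float:
    if result not in (TestResult.POSITIVE, TestResult.INCONCLUSIVE):
        return 0.0
    if strategy == StrategyName.PRIMARY_CARE:
        table = (
            draw.adherence_after_positive_pc
            if result == TestResult.POSITIVE
            else draw.adherence_after_inconclusive_pc
        )
        return table[age]
    if strategy == StrategyName.SCHOOL:
        return draw.adherence_school
    raise ValueError("the optometric strategy has no referral step")


# ---------------------------------------------------------------------------
# scalar operations


def screen_child(
    strategy: StrategyName,
    age: int,
    true_state: HealthState,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> ScreeningEvent:
    """Run one cycle's test-uptake and result generation for one child."""
    if true_state == HealthState.DEAD:
        raise ValueError("cannot screen a dead child")
    ev = ScreeningEvent()
    if strategy == StrategyName.OPTOMETRIC:
        attended = rng.random() < prob_tested(strategy, age, draw)
        ev.tested = ev.attended_optometrist = attended
        return ev
    if strategy == StrategyName.PRIMARY_CARE:
        ev.visited = rng.random() < draw.p_well_child_visit
        ev.tested = ev.visited and rng.random() < draw.p_primary_care_screen
    else:
        ev.tested = rng.random() < prob_tested(strategy, age, draw)
    if not ev.tested:
        return ev
    if rng.random() < prob_inconclusive(strategy, true_state, draw):
        ev.result = TestResult.INCONCLUSIVE
    elif rng.random() < prob_positive_given_conclusive(strategy, true_state, draw):
        ev.result = TestResult.POSITIVE
    else:
        ev.result = TestResult.NEGATIVE
    return ev


def refer_and_attend(
    strategy: StrategyName,
    age: int,
    result: TestResult,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> bool:
    """Did the child reach an optometrist after this screen result?"""
    if result not in (TestResult.POSITIVE, TestResult.INCONCLUSIVE):
        return False
    if rng.random() >= referral_probability(strategy, age, result, draw):
        return False
    return rng.random() < adherence_probability(strategy, age, result, draw)


def optometrist_diagnose(
    true_state: HealthState,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> str | None:
    """Optometrist classification of an attendee's true state.

    Correct with probability ``accuracy_optometrist``; any misclassification
    is returned as "no condition" (``None``) — a healthy child is never
    falsely started on treatment.
    """
    correct = rng.random() < draw.accuracy_optometrist
    if not correct:
        return None
    if true_state == HealthState.UNTREATED_AMBLYOPIA:
        return "amblyopia"
    if true_state == HealthState.UNTREATED_RISK_FACTOR:
        return "risk_factor"
    if true_state == HealthState.TREATED_AMBLYOPIA:
        return "treated_amblyopia"
    return None


def screening_branch_probabilities(
    strategy: StrategyName, state: HealthState, age: int, draw: ParameterDraw
) -> dict[str, float]:
    """Exhaustive outcome probabilities of one testing cycle (branch audit).

    Outcomes partition into not_tested / negative / flagged-not-attended /
    attended and must sum to 1.
    """
    p_t = prob_tested(strategy, age, draw)
    out = {"not_tested": 1.0 - p_t}
    if p_t == 0.0:
        out.update(negative=0.0, attended=0.0, flagged_not_attended=0.0)
        return out
    if strategy == StrategyName.OPTOMETRIC:
        out["attended"] = p_t
        out["negative"] = 0.0
        out["flagged_not_attended"] = 0.0
        return out
    p_inc = prob_inconclusive(strategy, state, draw)
    p_pos = (1.0 - p_inc) * prob_positive_given_conclusive(strategy, state, draw)
    p_neg = (1.0 - p_inc) * (1.0 - prob_positive_given_conclusive(strategy, state, draw))
    attend_pos = referral_probability(
        strategy, age, TestResult.POSITIVE, draw
    ) * adherence_probability(strategy, age, TestResult.POSITIVE, draw)
    attend_inc = referral_probability(
        strategy, age, TestResult.INCONCLUSIVE, draw
    ) * adherence_probability(strategy, age, TestResult.INCONCLUSIVE, draw)
    out["negative"] = p_t * p_neg
    out["attended"] = p_t * (p_pos * attend_pos + p_inc * attend_inc)
    out["flagged_not_attended"] = p_t * (
        p_pos * (1 - attend_pos) + p_inc * (1 - attend_inc)
    )
    return out
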