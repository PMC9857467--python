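"""Annual disease progression, treatment outcome and mortality.

Incidence (healthy -> risk factor, risk factor -> amblyopia) operates only at
ages 3-5; thereafter untreated states persist, except for a small annual
hazard of vision loss in the nonamblyopic eye while amblyopia remains
untreated (irreversible impairment is assumed absent a diagnosis). Treated
amblyopia is absorbing — no relapse is modelled. Background mortality applies
identically in every living state, after progression, from national life
tables.
"""
from __future__ import annotations

import numpy as np

from .parameters import ParameterDraw
from .states import HealthState

__all__ = [
    "mortality_probability",
    "vision_loss_probability",
    "incidence_active",
    "progress_state",
    "treatment_outcome",
    "transition_probabilities",
]


def mortality_probability(age: int, draw: ParameterDraw) -> float:
    """Annual probability of death at ``age`` (any living state)."""
    try:
        return draw.p_death_by_age[int(age)]
    except KeyError:
        raise ValueError(f"no mortality entry for age {age}") from None


def vision_loss_probability(age: int, draw: ParameterDraw) -> float:
    """Annual hazard of vision loss in the nonamblyopic eye while amblyopia
    is untreated. Zero before age 5."""
    if 5 <= age <= 15:
        return draw.p_vision_loss_5_15
    if 16 <= age <= 18:
        return draw.p_vision_loss_16_18
    return 0.0


def incidence_active(age: int) -> bool:
    """Incidence transitions operate only at ages 3-5."""
    return 3 <= age <= 5


def progress_state(
    state: HealthState,
    age: int,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> HealthState:
    """One cycle of natural history for an untreated child: progression,
    then mortality. ``DEAD`` input is a contract violation."""
    if state == HealthState.DEAD:
        raise ValueError("progress_state called on a dead child")
    new = state
    if incidence_active(age):
        if state == HealthState.HEALTHY:
            if rng.random() < draw.p_healthy_to_risk_factor:
                new = HealthState.UNTREATED_RISK_FACTOR
        elif state == HealthState.UNTREATED_RISK_FACTOR:
            if rng.random() < draw.p_risk_factor_to_amblyopia:
                new = HealthState.UNTREATED_AMBLYOPIA
    if state == HealthState.UNTREATED_AMBLYOPIA:
        if rng.random() < vision_loss_probability(age, draw):
            new = HealthState.VISION_LOSS_NONAMBLYOPIC
    if rng.random() < mortality_probability(age, draw):
        return HealthState.DEAD
    return new


def treatment_outcome(
    state: HealthState,
    age: int,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> HealthState:
    """Resolve one course of treatment for a diagnosed, adherent child.

    A risk factor resolves to healthy vision with certainty. Untreated
    amblyopia succeeds with the age-at-treatment probability; success splits
    into full recovery (VA >= 20/25) versus a residual treated-amblyopia
    deficit, failure leaves the child untreated-amblyopic.
    """
    if state == HealthState.UNTREATED_RISK_FACTOR:
        return HealthState.HEALTHY
    if state != HealthState.UNTREATED_AMBLYOPIA:
        raise ValueError(f"treatment_outcome undefined for state {state!r}")
    try:
        p_success = draw.p_treatment_success_by_age[int(age)]
    except KeyError:
        raise ValueError(f"no treatment-success entry for age {age}") from None
    if rng.random() < p_success:
        if rng.random() < draw.p_success_to_healthy:
            return HealthState.HEALTHY
        return HealthState.TREATED_AMBLYOPIA
    return HealthState.UNTREATED_AMBLYOPIA


def transition_probabilities(
    state: HealthState, age: int, draw: ParameterDraw
) -> dict[HealthState, float]:
    """One-cycle transition kernel (progression then mortality) for an
    untreated child. Used for branch audits and cohort-matrix checks."""
    if state == HealthState.DEAD:
        return {HealthState.DEAD: 1.0}
    branches: dict[HealthState, float] = {}
    if state == HealthState.HEALTHY and incidence_active(age):
        p = draw.p_healthy_to_risk_factor
        branches = {HealthState.UNTREATED_RISK_FACTOR: p, HealthState.HEALTHY: 1 - p}
    elif state == HealthState.UNTREATED_RISK_FACTOR and incidence_active(age):
        p = draw.p_risk_factor_to_amblyopia
        branches = {HealthState.UNTREATED_AMBLYOPIA: p, HealthState.UNTREATED_RISK_FACTOR: 1 - p}
    elif state == HealthState.UNTREATED_AMBLYOPIA:
        p = vision_loss_probability(age, draw)
        branches = {HealthState.VISION_LOSS_NONAMBLYOPIC: p, HealthState.UNTREATED_AMBLYOPIA: 1 - p}
    else:
        branches = {state: 1.0}
    p_d = mortality_probability(age, draw)
    out = {s: p * (1 - p_d) for s, p in branches.items() if p > 0}
    out[HealthState.DEAD] = out.get(HealthState.DEAD, 0.0) + p_d
    return out
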