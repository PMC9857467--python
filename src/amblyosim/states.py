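"""Health states of the amblyopia natural-history model.

A child occupies exactly one state per annual cycle. ``DEAD`` and
``VISION_LOSS_NONAMBLYOPIC`` are absorbing; ``TREATED_AMBLYOPIA`` is an
absorbing *living* state (no relapse is modelled).
"""
from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    HEALTHY = 0
    UNTREATED_AMBLYOPIA = 1
    UNTREATED_RISK_FACTOR = 2
    TREATED_AMBLYOPIA = 3
    VISION_LOSS_NONAMBLYOPIC = 4
    DEAD = 5


#: states a child may hold at model entry (age 3)
ENTRY_STATES = (
    HealthState.HEALTHY,
    HealthState.UNTREATED_AMBLYOPIA,
    HealthState.UNTREATED_RISK_FACTOR,
)

LIVING_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)

#: living states that never transition out (except to death)
ABSORBING_LIVING_STATES = (
    HealthState.TREATED_AMBLYOPIA,
    HealthState.VISION_LOSS_NONAMBLYOPIC,
)

#: key into the ``utilities`` parameter map for each state
UTILITY_KEY = {
    HealthState.HEALTHY: "healthy",
    HealthState.UNTREATED_AMBLYOPIA: "untreated_amblyopia",
    HealthState.UNTREATED_RISK_FACTOR: "untreated_risk_factor",
    HealthState.TREATED_AMBLYOPIA: "treated_amblyopia",
    HealthState.VISION_LOSS_NONAMBLYOPIC: "vision_loss",
    HealthState.DEAD: "dead",
}

#: condition class a screening test "sees".  Vision loss in the nonamblyopic
#: eye only arises after age 5, i.e. after all testing, but is mapped to the
#: amblyopia class for completeness.
CONDITION_CLASS = {
    HealthState.HEALTHY: "healthy_or_treated",
    HealthState.UNTREATED_AMBLYOPIA: "amblyopia",
    HealthState.UNTREATED_RISK_FACTOR: "risk_factor",
    HealthState.TREATED_AMBLYOPIA: "healthy_or_treated",
    HealthState.VISION_LOSS_NONAMBLYOPIC: "amblyopia",
}
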