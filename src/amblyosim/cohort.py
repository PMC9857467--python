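"""Synthesis of the hypothetical entry cohort.

Children enter at age 3 in one of three states — healthy vision, untreated
amblyopia, or an untreated amblyopia risk factor — drawn from the entry
prevalences, and carry a fixed social-assistance flag (which gates coverage
of prescription glasses).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterDraw, ParameterError
from .states import HealthState

__all__ = ["Child", "Cohort", "initial_state_distribution", "generate_cohort"]


@dataclass(frozen=True)
class Child:
    id: int
    initial_state: HealthState
    on_social_assistance: bool
    age: int = 3


@dataclass
class Cohort:
    """Column-oriented cohort: one entry per child."""

    initial_state: np.ndarray  # int8 HealthState codes
    on_social_assistance: np.ndarray  # bool
    entry_age: int = 3

    def __len__(self) -> int:
        return self.initial_state.shape[0]

    def child(self, i: int) -> Child:
        return Child(
            id=i,
            initial_state=HealthState(int(self.initial_state[i])),
            on_social_assistance=bool(self.on_social_assistance[i]),
            age=self.entry_age,
        )

    def __iter__(self):
        return (self.child(i) for i in range(len(self)))

    def state_fractions(self) -> dict[HealthState, float]:
        n = len(self)
        return {
            s: float(np.mean(self.initial_state == int(s)))
            for s in (
                HealthState.UNTREATED_AMBLYOPIA,
                HealthState.UNTREATED_RISK_FACTOR,
                HealthState.HEALTHY,
            )
        }


def initial_state_distribution(draw: ParameterDraw) -> tuple[float, float, float]:
    """Probabilities of (untreated amblyopia, untreated risk factor, healthy).

    Raises :class:`ParameterError` if the prevalences overflow the simplex.
    """
    p_amb = draw.prevalence_amblyopia
    p_arf = draw.prevalence_risk_factor
    if p_amb + p_arf > 1.0:
        raise ParameterError(
            f"entry prevalences sum to {p_amb + p_arf:.3f} > 1"
        )
    return p_amb, p_arf, 1.0 - p_amb - p_arf


def generate_cohort(
    n: int, draw: ParameterDraw, rng: np.random.Generator
) -> Cohort:
    """Sample ``n`` children at entry age.

    Initial states are drawn from :func:`initial_state_distribution`;
    social-assistance status with probability ``draw.p_social_assistance``.
    Reproducible for a fixed generator state.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    p_amb, p_arf, _ = initial_state_distribution(draw)
    u = rng.random(n)
    state = np.full(n, int(HealthState.HEALTHY), dtype=np.int8)
    state[u < p_amb + p_arf] = int(HealthState.UNTREATED_RISK_FACTOR)
    state[u < p_amb] = int(HealthState.UNTREATED_AMBLYOPIA)
    social = rng.random(n) < draw.p_social_assistance
    return Cohort(initial_state=state, on_social_assistance=social, entry_age=draw.entry_age)
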