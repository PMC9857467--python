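"""Simulation engine: per-child cycles, discounted accrual, and the PSA loop.

Each child is simulated over 15 annual cycles (ages 3-17). Within a cycle the
event order is: testing -> referral -> optometrist diagnosis -> treatment
adherence -> treatment outcome, then quality-adjusted life-year (QALY)
accrual for the state occupied during the year, then disease progression
(skipped in a treatment cycle), then mortality. Costs and QALYs are
discounted at 1.5% per year beyond the first.

Two equivalent simulation paths are provided:

* :func:`simulate_individual` — a readable scalar reference implementation
  returning a full per-cycle trajectory; used for inspection and testing.
* :func:`simulate_cohort` — a vectorised implementation over the whole
  cohort, consuming a pre-drawn block of uniform variates. The same block is
  reused across strategies within a PSA iteration (common random numbers), so
  a child untouched by testing has *identical* outcomes under every strategy
  and incremental differences isolate strategy effects.

:func:`run_psa` wraps the outer probabilistic loop: one parameter draw and
one shared cohort per iteration, each strategy simulated on the shared
uniforms, with per-iteration means and pooled per-child paired differences
accumulated for the cost-effectiveness statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea
from .cohort import Child, Cohort, generate_cohort
from .natural_history import (
    mortality_probability,
    progress_state,
    treatment_outcome,
    vision_loss_probability,
)
from .parameters import ParameterDraw, ParameterSet, reference_draw, sample_draw
from .states import UTILITY_KEY, HealthState
from .strategies import (
    REFERENCE_STRATEGY,
    ScreeningEvent,
    StrategyName,
    TestResult,
    adherence_probability,
    optometrist_diagnose,
    prob_inconclusive,
    prob_positive_given_conclusive,
    refer_and_attend,
    referral_probability,
    screen_child,
    testing_schedule,
)

__all__ = [
    "discount_factor",
    "discount_sum",
    "accrue_cycle_costs",
    "accrue_cycle_qaly",
    "CycleRecord",
    "IndividualTrajectory",
    "simulate_individual",
    "draw_uniform_block",
    "simulate_cohort",
    "StrategyResult",
    "PSAResult",
    "run_psa",
]

# slot indices into the shared uniform block (one variate per child, cycle
# and decision point)
U_TEST, U_SCREEN, U_INC, U_RES, U_REF, U_ATT, U_DX, U_ADH, U_SUCC, U_SPLIT, \
    U_PROG, U_ARF, U_VL, U_DEATH = range(14)
N_SLOTS = 14

_STATE_DEAD = int(HealthState.DEAD)


def discount_factor(years_from_entry: int, rate: float) -> float:
    """Discount weight for a cycle: 1 in year 0, ``(1+rate)^-t`` after."""
    if years_from_entry < 0:
        raise ValueError("years_from_entry must be >= 0")
    if years_from_entry == 0:
        return 1.0
    return float((1.0 + rate) ** (-years_from_entry))


def discount_sum(horizon_years: int, rate: float) -> float:
    """Sum of discount factors over the horizon — the per-child QALY ceiling."""
    return sum(discount_factor(t, rate) for t in range(horizon_years))


def _utility_vector(draw: ParameterDraw) -> np.ndarray:
    return np.array([draw.utilities[UTILITY_KEY[s]] for s in HealthState])


def accrue_cycle_qaly(state: HealthState, years_from_entry: int, draw: ParameterDraw) -> float:
    """Discounted QALY increment for one year spent in ``state``."""
    u = draw.utilities[UTILITY_KEY[state]]
    return u * discount_factor(years_from_entry, draw.discount_rate)


def accrue_cycle_costs(
    strategy: StrategyName,
    event: ScreeningEvent,
    child: Child,
    age: int,
    draw: ParameterDraw,
    glasses_due: bool = False,
) -> float:
    """Undiscounted cost of one cycle's events (discounting is the caller's).

    Primary care charges the well-child visit whenever a visit occurs and
    the screening fee when a screen occurs; school charges the screen plus
    per-child screener training; the optometric exam, and any attended
    referral, charges the diagnostic-exam fee. A treatment cycle adds one
    follow-up visit, and prescription glasses for social-assistance
    recipients when a set is due.
    """
    total = 0.0
    if strategy == StrategyName.PRIMARY_CARE:
        if event.visited:
            total += draw.cost_well_child_visit
        if event.tested:
            total += draw.cost_pc_screen
    elif strategy == StrategyName.SCHOOL:
        if event.tested:
            total += draw.cost_school_screen + draw.cost_nurse_training_per_child
    if event.attended_optometrist:
        total += draw.cost_opto_diagnostic
    if event.treated:
        total += draw.cost_opto_followup
    if glasses_due and child.on_social_assistance:
        total += draw.cost_glasses
    if total < 0:  # pragma: no cover - defensive
        raise RuntimeError("negative cycle cost")
    return total


@dataclass
class CycleRecord:
    age: int
    state: HealthState  # state occupied during the year (post-treatment)
    event: ScreeningEvent | None
    cost_increment: float  # discounted CAD
    qaly_increment: float  # discounted QALYs


@dataclass
class IndividualTrajectory:
    child_id: int
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return sum(r.cost_increment for r in self.records)

    @property
    def total_qaly(self) -> float:
        return sum(r.qaly_increment for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            ev = r.event or ScreeningEvent()
            rows.append(
                {
                    "age": r.age,
                    "state": r.state.name,
                    "tested": ev.tested,
                    "result": ev.result.value,
                    "attended": ev.attended_optometrist,
                    "diagnosed": ev.diagnosed_condition,
                    "treated": ev.treated,
                    "cost": r.cost_increment,
                    "qaly": r.qaly_increment,
                }
            )
        return pd.DataFrame(rows)


_IMPAIRED = (
    HealthState.UNTREATED_AMBLYOPIA,
    HealthState.TREATED_AMBLYOPIA,
    HealthState.VISION_LOSS_NONAMBLYOPIC,
)


def simulate_individual(
    strategy: StrategyName,
    child: Child,
    draw: ParameterDraw,
    rng: np.random.Generator,
) -> IndividualTrajectory:
    """Simulate one child's full trajectory (scalar reference path)."""
    traj = IndividualTrajectory(child_id=child.id)
    state = child.initial_state
    glasses_age: int | None = None  # age at last glasses purchase
    examined = False
    for t in range(draw.horizon_years):
        age = draw.entry_age + t
        if state == HealthState.DEAD:
            break
        disc = discount_factor(t, draw.discount_rate)
        event: ScreeningEvent | None = None
        treated_now = False
        glasses_due = False
        if testing_schedule(strategy, age, examined, draw.optometric_exam_age):
            event = screen_child(strategy, age, state, draw, rng)
            if strategy == StrategyName.OPTOMETRIC and event.tested:
                examined = True
            if not event.attended_optometrist and event.result in (
                TestResult.POSITIVE,
                TestResult.INCONCLUSIVE,
            ):
                event.referred = True  # referral folded into refer_and_attend
                event.attended_optometrist = refer_and_attend(
                    strategy, age, event.result, draw, rng
                )
            if event.attended_optometrist:
                event.diagnosed_condition = optometrist_diagnose(state, draw, rng)
                if event.diagnosed_condition in ("amblyopia", "risk_factor") and (
                    rng.random() < draw.p_treatment_adherence
                ):
                    state = treatment_outcome(state, age, draw, rng)
                    event.treated = True
                    treated_now = True
                    if child.on_social_assistance and (
                        glasses_age is None
                        or age - glasses_age >= draw.glasses_interval_years
                    ):
                        glasses_due = True
                        glasses_age = age
        # replacement glasses while impaired, outside treatment cycles
        if (
            not glasses_due
            and glasses_age is not None
            and child.on_social_assistance
            and state in _IMPAIRED
            and age - glasses_age >= draw.glasses_interval_years
        ):
            glasses_due = True
            glasses_age = age
        cost = accrue_cycle_costs(
            strategy, event or ScreeningEvent(), child, age, draw, glasses_due
        )
        qaly = accrue_cycle_qaly(state, t, draw)
        traj.records.append(
            CycleRecord(age, state, event, cost * disc, qaly)
        )
        if treated_now:
            # progression skipped in a treatment cycle; mortality still applies
            if rng.random() < mortality_probability(age, draw):
                state = HealthState.DEAD
        else:
            state = progress_state(state, age, draw, rng)
    return traj


# ---------------------------------------------------------------------------
# vectorised path


def draw_uniform_block(rng: np.random.Generator, n: int, horizon: int) -> np.ndarray:
    """Pre-draw every uniform variate the cohort simulation can consume:
    shape ``(N_SLOTS, n, horizon)``."""
    return rng.random((N_SLOTS, n, horizon))


def simulate_cohort(
    strategy: StrategyName,
    cohort: Cohort,
    draw: ParameterDraw,
    uniforms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised trajectory simulation of a whole cohort.

    Returns per-child discounted ``(cost, qaly)`` arrays. Passing the same
    uniform block for every strategy implements common random numbers.
    """
    n = len(cohort)
    horizon = draw.horizon_years
    if uniforms.shape != (N_SLOTS, n, horizon):
        raise ValueError("uniform block has wrong shape")
    state = cohort.initial_state.astype(np.int16).copy()
    social = cohort.on_social_assistance
    util = _utility_vector(draw)
    cost_total = np.zeros(n)
    qaly_total = np.zeros(n)
    # years since last glasses purchase; negative = never bought
    glasses_timer = np.full(n, -1, dtype=np.int16)
    is_pc = strategy == StrategyName.PRIMARY_CARE
    is_school = strategy == StrategyName.SCHOOL
    is_opt = strategy == StrategyName.OPTOMETRIC

    # per-state lookup vectors (recomputed cheaply; stable within a draw)
    def _state_vec(fn) -> np.ndarray:
        return np.array([fn(HealthState(s)) for s in range(6)])

    p_inc_vec = _state_vec(
        lambda s: prob_inconclusive(strategy, s, draw) if s != HealthState.DEAD else 0.0
    ) if not is_opt else None
    p_pos_vec = _state_vec(
        lambda s: prob_positive_given_conclusive(strategy, s, draw)
        if s != HealthState.DEAD
        else 0.0
    ) if not is_opt else None

    for t in range(horizon):
        age = draw.entry_age + t
        disc = discount_factor(t, draw.discount_rate)
        alive = state != _STATE_DEAD
        cyc_cost = np.zeros(n)
        treated_now = np.zeros(n, dtype=bool)
        attended = np.zeros(n, dtype=bool)

        eligible = testing_schedule(strategy, age, False, draw.optometric_exam_age)
        if eligible and is_pc:
            visited = alive & (uniforms[U_TEST, :, t] < draw.p_well_child_visit)
            cyc_cost[visited] += draw.cost_well_child_visit
            tested = visited & (uniforms[U_SCREEN, :, t] < draw.p_primary_care_screen)
            cyc_cost[tested] += draw.cost_pc_screen
        elif eligible and is_school:
            tested = alive & (uniforms[U_TEST, :, t] < draw.p_school_screen)
            cyc_cost[tested] += draw.cost_school_screen + draw.cost_nurse_training_per_child
        elif eligible and is_opt:
            attended = alive & (uniforms[U_TEST, :, t] < draw.p_optometric_exam_uptake)
            tested = attended
        else:
            tested = np.zeros(n, dtype=bool)

        if eligible and not is_opt and tested.any():
            inconclusive = tested & (uniforms[U_INC, :, t] < p_inc_vec[state])
            conclusive = tested & ~inconclusive
            positive = conclusive & (uniforms[U_RES, :, t] < p_pos_vec[state])
            flagged = positive | inconclusive
            if flagged.any():
                p_ref = np.where(
                    positive,
                    referral_probability(strategy, age, TestResult.POSITIVE, draw),
                    referral_probability(strategy, age, TestResult.INCONCLUSIVE, draw),
                )
                p_att = np.where(
                    positive,
                    adherence_probability(strategy, age, TestResult.POSITIVE, draw),
                    adherence_probability(strategy, age, TestResult.INCONCLUSIVE, draw),
                )
                referred = flagged & (uniforms[U_REF, :, t] < p_ref)
                attended = referred & (uniforms[U_ATT, :, t] < p_att)

        if attended.any():
            cyc_cost[attended] += draw.cost_opto_diagnostic
            correct = attended & (uniforms[U_DX, :, t] < draw.accuracy_optometrist)
            diagnosed = correct & (
                (state == int(HealthState.UNTREATED_AMBLYOPIA))
                | (state == int(HealthState.UNTREATED_RISK_FACTOR))
            )
            adhere = diagnosed & (uniforms[U_ADH, :, t] < draw.p_treatment_adherence)
            if adhere.any():
                arf = adhere & (state == int(HealthState.UNTREATED_RISK_FACTOR))
                amb = adhere & (state == int(HealthState.UNTREATED_AMBLYOPIA))
                state[arf] = int(HealthState.HEALTHY)
                if amb.any():
                    succ = amb & (
                        uniforms[U_SUCC, :, t] < draw.p_treatment_success_by_age[age]
                    )
                    to_healthy = succ & (
                        uniforms[U_SPLIT, :, t] < draw.p_success_to_healthy
                    )
                    state[to_healthy] = int(HealthState.HEALTHY)
                    state[succ & ~to_healthy] = int(HealthState.TREATED_AMBLYOPIA)
                cyc_cost[adhere] += draw.cost_opto_followup
                treated_now = adhere
                buy = adhere & social & (
                    (glasses_timer < 0)
                    | (glasses_timer >= draw.glasses_interval_years)
                )
                cyc_cost[buy] += draw.cost_glasses
                glasses_timer[buy] = 0

        # replacement glasses while impaired
        impaired = (
            (state == int(HealthState.UNTREATED_AMBLYOPIA))
            | (state == int(HealthState.TREATED_AMBLYOPIA))
            | (state == int(HealthState.VISION_LOSS_NONAMBLYOPIC))
        )
        replace = (
            alive
            & ~treated_now
            & social
            & impaired
            & (glasses_timer >= draw.glasses_interval_years)
        )
        cyc_cost[replace] += draw.cost_glasses
        glasses_timer[replace] = 0

        # accrual: state occupied during the year, post-treatment
        qaly_total += np.where(alive, util[state] * disc, 0.0)
        cost_total += cyc_cost * disc

        # progression (skipped in treatment cycles)
        prog = alive & ~treated_now
        healthy = prog & (state == int(HealthState.HEALTHY))
        arf_s = prog & (state == int(HealthState.UNTREATED_RISK_FACTOR))
        amb_s = prog & (state == int(HealthState.UNTREATED_AMBLYOPIA))
        if age <= 5:
            to_arf = healthy & (uniforms[U_PROG, :, t] < draw.p_healthy_to_risk_factor)
            to_amb = arf_s & (uniforms[U_ARF, :, t] < draw.p_risk_factor_to_amblyopia)
            state[to_arf] = int(HealthState.UNTREATED_RISK_FACTOR)
            state[to_amb] = int(HealthState.UNTREATED_AMBLYOPIA)
        p_vl = vision_loss_probability(age, draw)
        if p_vl > 0.0:
            to_vl = amb_s & (uniforms[U_VL, :, t] < p_vl)
            state[to_vl] = int(HealthState.VISION_LOSS_NONAMBLYOPIC)

        # mortality
        dies = alive & (uniforms[U_DEATH, :, t] < mortality_probability(age, draw))
        state[dies] = _STATE_DEAD
        glasses_timer[glasses_timer >= 0] += 1

    return cost_total, qaly_total


# ---------------------------------------------------------------------------
# PSA driver


@dataclass
class StrategyResult:
    """Monte-Carlo summary for one strategy."""

    strategy: StrategyName
    n_iterations: int
    n_children: int
    mean_cost: float
    mean_qaly: float
    ci_cost: tuple[float, float]  # normal CI over pooled children
    ci_qaly: tuple[float, float]
    iteration_costs: np.ndarray  # per-iteration cohort means
    iteration_qalys: np.ndarray

    def iteration_ci(self, which: str = "cost", level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of the per-iteration cohort means."""
        arr = self.iteration_costs if which == "cost" else self.iteration_qalys
        lo, hi = np.percentile(arr, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
        return float(lo), float(hi)


@dataclass
class PSAResult:
    seed: int
    n_iterations: int
    n_children: int
    wtp_threshold: float
    strategies: dict[StrategyName, StrategyResult]
    incrementals: dict[StrategyName, cea.IncrementalSummary]
    reference: StrategyName = REFERENCE_STRATEGY


def _pooled(mean_sum: float, sq_sum: float, n: int) -> tuple[float, tuple[float, float]]:
    mean = mean_sum / n
    var = max(sq_sum / n - mean * mean, 0.0)
    half = 1.959963984540054 * np.sqrt(var / n)
    return mean, (mean - half, mean + half)


def run_psa(
    params: ParameterSet,
    n_iterations: int,
    seed: int,
    strategies: tuple[StrategyName, ...] = tuple(StrategyName),
    n_children: int | None = None,
    wtp_grid: np.ndarray | None = None,
    correction: bool = True,
    probabilistic: bool = True,
) -> PSAResult:
    """Run the full probabilistic analysis.

    Per iteration: one parameter draw (or the reference draw when
    ``probabilistic=False``), one shared cohort, one shared uniform block,
    one trajectory per child per strategy. Incremental statistics versus the
    reference strategy are accumulated over per-child paired differences.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n = n_children if n_children is not None else params.n_individuals
    grid = wtp_grid if wtp_grid is not None else cea.default_wtp_grid()
    ss = np.random.SeedSequence(seed)
    param_ss, sim_ss = ss.spawn(2)
    param_rng = np.random.default_rng(param_ss)
    iter_seeds = sim_ss.spawn(n_iterations)

    strategies = tuple(strategies)
    comparators = [s for s in strategies if s != REFERENCE_STRATEGY]
    has_ref = REFERENCE_STRATEGY in strategies

    it_cost = {s: np.zeros(n_iterations) for s in strategies}
    it_qaly = {s: np.zeros(n_iterations) for s in strategies}
    sums = {s: np.zeros(4) for s in strategies}  # sum c, sum c^2, sum q, sum q^2
    accs = {
        c: cea.PairAccumulator(grid, correction=correction) for c in comparators
    } if has_ref else {}
    it_dc = {c: np.zeros(n_iterations) for c in accs}
    it_dq = {c: np.zeros(n_iterations) for c in accs}

    for i in range(n_iterations):
        draw = (
            sample_draw(params, i, param_rng) if probabilistic else reference_draw(params)
        )
        rng_i = np.random.default_rng(iter_seeds[i])
        cohort = generate_cohort(n, draw, rng_i)
        uniforms = draw_uniform_block(rng_i, n, draw.horizon_years)
        out: dict[StrategyName, tuple[np.ndarray, np.ndarray]] = {}
        for s in strategies:
            cost, qaly = simulate_cohort(s, cohort, draw, uniforms)
            out[s] = (cost, qaly)
            it_cost[s][i] = cost.mean()
            it_qaly[s][i] = qaly.mean()
            sums[s] += (cost.sum(), (cost**2).sum(), qaly.sum(), (qaly**2).sum())
        if has_ref:
            ref_cost, ref_qaly = out[REFERENCE_STRATEGY]
            for c in comparators:
                dc = out[c][0] - ref_cost
                dq = out[c][1] - ref_qaly
                accs[c].update(dc, dq)
                it_dc[c][i] = dc.mean()
                it_dq[c][i] = dq.mean()

    results: dict[StrategyName, StrategyResult] = {}
    n_pool = n * n_iterations
    for s in strategies:
        sc, sc2, sq, sq2 = sums[s]
        mc, cic = _pooled(sc, sc2, n_pool)
        mq, ciq = _pooled(sq, sq2, n_pool)
        results[s] = StrategyResult(
            strategy=s,
            n_iterations=n_iterations,
            n_children=n,
            mean_cost=mc,
            mean_qaly=mq,
            ci_cost=cic,
            ci_qaly=ciq,
            iteration_costs=it_cost[s],
            iteration_qalys=it_qaly[s],
        )
    incrementals = {
        c: accs[c].summary(
            comparator=c.value,
            reference=REFERENCE_STRATEGY.value,
            wtp_threshold=params.wtp_threshold,
            iteration_delta_costs=it_dc[c],
            iteration_delta_qalys=it_dq[c],
        )
        for c in accs
    }
    return PSAResult(
        seed=seed,
        n_iterations=n_iterations,
        n_children=n,
        wtp_threshold=params.wtp_threshold,
        strategies=results,
        incrementals=incrementals,
    )
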