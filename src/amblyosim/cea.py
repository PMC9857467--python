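"""Incremental cost-effectiveness statistics.

Each comparator strategy is evaluated against the reference (primary-care
screening) on paired differences ``(delta cost, delta QALY)``. To prevent
ties from favouring the comparator, a correction of +0.0001 CAD is added to
each incremental cost and -0.0001 to each incremental QALY before
classification, so a pair with no difference at all lands in the northwest
quadrant (more costly, no more effective) and is counted against the
comparator.

Quadrants of the cost-effectiveness plane (after correction):

* NE — more QALYs, cost >= 0 (cost-effective if the ICER is below the
  willingness-to-pay threshold)
* NW — no QALY gain, cost >= 0
* SW — no QALY gain, cost < 0 (savings, but not counted cost-effective)
* SE — more QALYs at a saving ("dominant"; always cost-effective)

The acceptability curve for a comparator reports, per willingness-to-pay
value, the proportion of pairs that are cost-effective under this quadrant
rule (the reference takes the complement). A multiway net-monetary-benefit
variant (:func:`ceac_nmb`) is also provided.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Quadrant",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "CORRECTION_COST",
    "CORRECTION_QALY",
    "apply_correction",
    "classify_quadrant",
    "icer_or_dominance",
    "default_wtp_grid",
    "CEACCurve",
    "IncrementalSummary",
    "PairAccumulator",
    "ceac_nmb",
]

CORRECTION_COST = 1e-4
CORRECTION_QALY = -1e-4

DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"
UNDEFINED = "UNDEFINED"


class Quadrant(str, enum.Enum):
    NE = "NE"
    NW = "NW"
    SW = "SW"
    SE = "SE"


def apply_correction(delta_cost, delta_qaly, enabled: bool = True):
    """Shift paired differences in the reference strategy's favour."""
    if not enabled:
        return delta_cost, delta_qaly
    return delta_cost + CORRECTION_COST, delta_qaly + CORRECTION_QALY


def classify_quadrant(delta_cost, delta_qaly):
    """Quadrant of the cost-effectiveness plane (correction already applied).

    Scalars return a :class:`Quadrant`; arrays return an object array of
    :class:`Quadrant`.
    """
    dc = np.asarray(delta_cost)
    dq = np.asarray(delta_qaly)
    codes = np.where(dq > 0, np.where(dc >= 0, 0, 3), np.where(dc >= 0, 1, 2))
    lut = np.array([Quadrant.NE, Quadrant.NW, Quadrant.SW, Quadrant.SE], dtype=object)
    out = lut[codes]
    if np.isscalar(out) or getattr(out, "ndim", 1) == 0:
        return out if isinstance(out, Quadrant) else Quadrant(out.item())
    return out


def icer_or_dominance(mean_delta_cost: float, mean_delta_qaly: float):
    """ICER, or a dominance label when a ratio would mislead.

    Less costly *and* more effective -> ``DOMINANT``; more costly and less
    effective -> ``DOMINATED``; zero QALY difference -> ``UNDEFINED`` (never
    silently divided); otherwise the ratio in CAD per QALY.
    """
    dc, dq = float(mean_delta_cost), float(mean_delta_qaly)
    if dq == 0.0:
        return UNDEFINED
    if dc < 0 and dq > 0:
        return DOMINANT
    if dc > 0 and dq < 0:
        return DOMINATED
    return dc / dq


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid, CAD 0-100 000 per QALY in 1 000 steps."""
    return np.arange(0.0, 100_001.0, 1_000.0)


@dataclass
class CEACCurve:
    """Probability of being cost-effective per willingness-to-pay value."""

    wtp_grid: np.ndarray
    probabilities: dict[str, np.ndarray]  # strategy name -> prob per grid point

    def at(self, wtp: float, strategy: str) -> float:
        j = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.probabilities[strategy][j])


@dataclass
class IncrementalSummary:
    """Comparator-versus-reference summary of the paired analysis."""

    comparator: str
    reference: str
    n_pairs: int
    mean_delta_cost: float
    ci_delta_cost: tuple[float, float]
    mean_delta_qaly: float
    ci_delta_qaly: tuple[float, float]
    icer_label: float | str
    quadrant_fractions: dict[Quadrant, float]
    yaxis_fraction: float  # pairs with exactly zero QALY difference (pre-correction)
    prob_cost_effective_at_wtp: float
    ceac: CEACCurve
    iteration_delta_costs: np.ndarray | None = None
    iteration_delta_qalys: np.ndarray | None = None


@dataclass
class PairAccumulator:
    """Streaming accumulator over per-child paired differences.

    ``update`` may be called once per PSA iteration with that iteration's
    pooled pairs; statistics are exact over everything seen.
    """

    wtp_grid: np.ndarray
    correction: bool = True
    scatter_max: int = 20_000
    n: int = 0
    sum_dc: float = 0.0
    sum_dq: float = 0.0
    sq_dc: float = 0.0
    sq_dq: float = 0.0
    quad_counts: dict[Quadrant, int] = field(
        default_factory=lambda: {q: 0 for q in Quadrant}
    )
    yaxis_count: int = 0
    ce_counts: np.ndarray | None = None
    scatter: np.ndarray | None = None  # first pairs kept for CE-plane plots

    def update(self, delta_cost: np.ndarray, delta_qaly: np.ndarray) -> None:
        dc = np.asarray(delta_cost, dtype=float)
        dq = np.asarray(delta_qaly, dtype=float)
        if self.ce_counts is None:
            self.ce_counts = np.zeros(self.wtp_grid.shape[0])
        self.n += dc.size
        self.sum_dc += dc.sum()
        self.sum_dq += dq.sum()
        self.sq_dc += (dc**2).sum()
        self.sq_dq += (dq**2).sum()
        self.yaxis_count += int((dq == 0.0).sum())
        dcc, dqc = apply_correction(dc, dq, self.correction)
        pos_q = dqc > 0
        neg_c = dcc < 0
        se = pos_q & neg_c
        ne = pos_q & ~neg_c
        self.quad_counts[Quadrant.SE] += int(se.sum())
        self.quad_counts[Quadrant.NE] += int(ne.sum())
        self.quad_counts[Quadrant.SW] += int((~pos_q & neg_c).sum())
        self.quad_counts[Quadrant.NW] += int((~pos_q & ~neg_c).sum())
        # cost-effective pairs per wtp: all of SE, plus NE with ICER below wtp
        self.ce_counts += int(se.sum())
        if ne.any():
            icers = np.sort(dcc[ne] / dqc[ne])
            self.ce_counts += np.searchsorted(icers, self.wtp_grid, side="left")
        if self.scatter is None or self.scatter.shape[0] < self.scatter_max:
            keep = self.scatter_max - (0 if self.scatter is None else self.scatter.shape[0])
            block = np.column_stack([dc[:keep], dq[:keep]])
            self.scatter = (
                block if self.scatter is None else np.vstack([self.scatter, block])
            )

    def summary(
        self,
        comparator: str,
        reference: str,
        wtp_threshold: float,
        iteration_delta_costs: np.ndarray | None = None,
        iteration_delta_qalys: np.ndarray | None = None,
    ) -> IncrementalSummary:
        if self.n == 0:
            raise ValueError("no pairs accumulated")
        z = 1.959963984540054
        m_dc = self.sum_dc / self.n
        m_dq = self.sum_dq / self.n
        sd_dc = np.sqrt(max(self.sq_dc / self.n - m_dc**2, 0.0))
        sd_dq = np.sqrt(max(self.sq_dq / self.n - m_dq**2, 0.0))
        h_dc = z * sd_dc / np.sqrt(self.n)
        h_dq = z * sd_dq / np.sqrt(self.n)
        probs = self.ce_counts / self.n
        curve = CEACCurve(
            wtp_grid=self.wtp_grid.copy(),
            probabilities={
                str(comparator): probs,
                str(reference): 1.0 - probs,
            },
        )
        return IncrementalSummary(
            comparator=str(comparator),
            reference=str(reference),
            n_pairs=self.n,
            mean_delta_cost=m_dc,
            ci_delta_cost=(m_dc - h_dc, m_dc + h_dc),
            mean_delta_qaly=m_dq,
            ci_delta_qaly=(m_dq - h_dq, m_dq + h_dq),
            icer_label=icer_or_dominance(m_dc, m_dq),
            quadrant_fractions={q: c / self.n for q, c in self.quad_counts.items()},
            yaxis_fraction=self.yaxis_count / self.n,
            prob_cost_effective_at_wtp=curve.at(wtp_threshold, str(comparator)),
            ceac=curve,
            iteration_delta_costs=iteration_delta_costs,
            iteration_delta_qalys=iteration_delta_qalys,
        )


def ceac_nmb(
    costs: dict[str, np.ndarray],
    qalys: dict[str, np.ndarray],
    wtp_grid: np.ndarray,
    reference: str,
) -> CEACCurve:
    """Multiway acceptability curve by net monetary benefit.

    At each willingness-to-pay value the strategy with the strictly greatest
    ``wtp * QALY - cost`` wins an iteration; ties go to the reference.
    """
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    names = list(costs)
    if reference not in names:
        raise ValueError("reference strategy missing from inputs")
    c = np.stack([np.asarray(costs[s], dtype=float) for s in names])  # (S, n)
    q = np.stack([np.asarray(qalys[s], dtype=float) for s in names])
    probs = {s: np.zeros(wtp_grid.shape[0]) for s in names}
    ref_idx = names.index(reference)
    n = c.shape[1]
    for j, lam in enumerate(wtp_grid):
        nmb = lam * q - c  # (S, n)
        best = nmb.max(axis=0)
        ref_ties = nmb[ref_idx] >= best  # reference wins any tie
        winner = np.where(ref_ties, ref_idx, nmb.argmax(axis=0))
        for k, s in enumerate(names):
            probs[s][j] = float((winner == k).sum()) / n
    return CEACCurve(wtp_grid=np.asarray(wtp_grid, dtype=float), probabilities=probs)
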