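"""Publication-style outputs: summary table, CE plane and acceptability curves.

Costs are carried in 2019 CAD throughout the model; US dollars appear only
here, converted at the 2019 mean exchange rate (1.3268 CAD per USD).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import __version__  # noqa: E402
from .cea import IncrementalSummary  # noqa: E402
from .engine import PSAResult  # noqa: E402
from .parameters import ParameterSet  # noqa: E402
from .strategies import StrategyName  # noqa: E402

__all__ = [
    "RunManifest",
    "cad_to_usd",
    "report_table3",
    "summary_dict",
    "plot_outputs",
]

_LABELS = {
    StrategyName.PRIMARY_CARE: "Primary care screening",
    StrategyName.SCHOOL: "School screening",
    StrategyName.OPTOMETRIC: "Optometric examination",
}


@dataclass
class RunManifest:
    """Provenance record written alongside every results directory."""

    config_digest: str
    seed: int
    n_iterations: int
    n_children: int
    version: str
    created: str

    @classmethod
    def create(cls, params: ParameterSet, seed: int, n_iterations: int, n_children: int) -> "RunManifest":
        digest = hashlib.sha256(params.to_yaml().encode()).hexdigest()[:16]
        return cls(
            config_digest=digest,
            seed=seed,
            n_iterations=n_iterations,
            n_children=n_children,
            version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def cad_to_usd(cad: float, cad_per_usd: float = 1.3268) -> float:
    return cad / cad_per_usd


def _fmt_ci(lo: float, hi: float, nd: int) -> str:
    return f"({lo:.{nd}f} to {hi:.{nd}f})"


def _icer_str(label) -> str:
    if isinstance(label, str):
        return label.capitalize() if label in ("DOMINANT", "DOMINATED") else label
    return f"{label:,.2f}"


def report_table3(result: PSAResult, cad_per_usd: float = 1.3268) -> pd.DataFrame:
    """Mean and incremental cost/QALY table, one row per strategy.

    Incremental columns compare each alternative with the reference
    (primary-care) strategy; the reference row carries no incrementals.
    """
    if StrategyName.PRIMARY_CARE not in result.strategies:
        raise ValueError("reference strategy missing from results")
    rows = []
    for s, res in result.strategies.items():
        inc: IncrementalSummary | None = result.incrementals.get(s)
        row = {
            "strategy": _LABELS.get(s, str(s)),
            "mean_cost_cad": res.mean_cost,
            "mean_cost_ci": _fmt_ci(*res.ci_cost, 2),
            "mean_cost_usd": cad_to_usd(res.mean_cost, cad_per_usd),
            "mean_qaly": res.mean_qaly,
            "mean_qaly_ci": _fmt_ci(*res.ci_qaly, 4),
            "incr_cost_cad": inc.mean_delta_cost if inc else np.nan,
            "incr_cost_ci": _fmt_ci(*inc.ci_delta_cost, 2) if inc else "NA",
            "incr_cost_usd": cad_to_usd(inc.mean_delta_cost, cad_per_usd) if inc else np.nan,
            "incr_qaly": inc.mean_delta_qaly if inc else np.nan,
            "incr_qaly_ci": _fmt_ci(*inc.ci_delta_qaly, 4) if inc else "NA",
            "icer": _icer_str(inc.icer_label) if inc else "NA",
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")


def summary_dict(result: PSAResult) -> dict:
    """JSON-serialisable summary of a PSA run."""
    out: dict = {
        "seed": result.seed,
        "n_iterations": result.n_iterations,
        "n_children": result.n_children,
        "wtp_threshold": result.wtp_threshold,
        "strategies": {},
        "incrementals": {},
    }
    for s, res in result.strategies.items():
        out["strategies"][s.value] = {
            "mean_cost_cad": res.mean_cost,
            "ci_cost_cad": list(res.ci_cost),
            "mean_qaly": res.mean_qaly,
            "ci_qaly": list(res.ci_qaly),
        }
    for s, inc in result.incrementals.items():
        out["incrementals"][s.value] = {
            "mean_delta_cost_cad": inc.mean_delta_cost,
            "ci_delta_cost_cad": list(inc.ci_delta_cost),
            "mean_delta_qaly": inc.mean_delta_qaly,
            "ci_delta_qaly": list(inc.ci_delta_qaly),
            "icer": inc.icer_label if isinstance(inc.icer_label, str) else float(inc.icer_label),
            "quadrant_fractions": {q.value: f for q, f in inc.quadrant_fractions.items()},
            "yaxis_fraction": inc.yaxis_fraction,
            "prob_cost_effective_at_wtp": inc.prob_cost_effective_at_wtp,
        }
    return out


def plot_outputs(result: PSAResult, out_dir: Path, scatter_pairs=None) -> list[Path]:
    """Write CE-plane and acceptability-curve figures plus their data files.

    ``scatter_pairs`` maps comparator -> (n, 2) array of per-child
    (delta cost, delta QALY) pairs; when omitted only the CEAC is plotted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    wtp = result.wtp_threshold

    if scatter_pairs:
        fig, axes = plt.subplots(
            1, len(scatter_pairs), figsize=(6 * len(scatter_pairs), 5), squeeze=False
        )
        for ax, (comp, pairs) in zip(axes[0], scatter_pairs.items()):
            dq, dc = pairs[:, 1], pairs[:, 0]
            ax.scatter(dq, dc, s=4, alpha=0.3, edgecolors="none")
            qspan = max(abs(dq).max(), 1e-4) * 1.1
            qs = np.linspace(-qspan, qspan, 3)
            ax.plot(qs, wtp * qs, "b--", lw=1, label=f"WTP {wtp:,.0f} CAD/QALY")
            ax.axhline(0, color="k", lw=0.5)
            ax.axvline(0, color="k", lw=0.5)
            ax.set_xlabel("Incremental QALYs per child")
            ax.set_ylabel("Incremental cost per child (CAD)")
            ax.set_title(f"{_LABELS.get(comp, comp)} vs primary care")
            ax.legend(loc="upper left", fontsize=8)
            df = pd.DataFrame({"delta_cost_cad": dc, "delta_qaly": dq})
            p = out_dir / f"ce_plane_{getattr(comp, 'value', comp)}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        fig.tight_layout()
        p = out_dir / "ce_plane.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    if result.incrementals:
        fig, axes = plt.subplots(
            1, len(result.incrementals), figsize=(6 * len(result.incrementals), 4.5), squeeze=False
        )
        for ax, (comp, inc) in zip(axes[0], result.incrementals.items()):
            grid = inc.ceac.wtp_grid
            for name, prob in inc.ceac.probabilities.items():
                ax.plot(grid, prob, marker=".", ms=3, lw=1, label=_LABELS.get(StrategyName(name), name))
            ax.axvline(wtp, color="grey", ls=":", lw=1)
            ax.set_ylim(-0.02, 1.02)
            ax.set_xlabel("Willingness to pay (CAD per QALY)")
            ax.set_ylabel("Probability cost-effective")
            ax.set_title(f"{_LABELS.get(comp, comp)} vs primary care")
            ax.legend(fontsize=8)
            df = pd.DataFrame({"wtp_cad": grid, **{n: p for n, p in inc.ceac.probabilities.items()}})
            p = out_dir / f"ceac_{comp.value}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        fig.tight_layout()
        p = out_dir / "ceac.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
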