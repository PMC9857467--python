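"""One-way probabilistic sensitivity analysis.

A single parameter is pinned to each of a set of values (its PSA
distribution collapsed to a point mass) while every other parameter keeps
its reference-case distribution, and the full probabilistic analysis is
re-run per value. The same seed is used for every value, so differences
between scenario values are not confounded by Monte-Carlo noise.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import engine
from .parameters import ParameterSet, set_path
from .strategies import StrategyName

__all__ = ["SensitivityScenario", "one_way", "valid_parameter_keys"]


def valid_parameter_keys(params: ParameterSet) -> list[str]:
    """Dotted keys accepted by :func:`one_way`."""
    keys: list[str] = []
    for name, value in params.to_dict().items():
        if name == "dispersion":
            continue
        if isinstance(value, dict):
            keys.extend(f"{name}.{sub}" for sub in value)
        elif isinstance(value, (int, float)):
            keys.append(name)
    return keys


@dataclass
class SensitivityScenario:
    parameter_key: str
    values: list[float]
    results: list[engine.PSAResult]

    def incremental(self, comparator: StrategyName):
        """Per-value incremental summaries for one comparator."""
        return [r.incrementals[comparator] for r in self.results]


def one_way(
    parameter_key: str,
    values,
    params: ParameterSet,
    n_iterations: int,
    seed: int,
    n_children: int | None = None,
    strategies: tuple[StrategyName, ...] = tuple(StrategyName),
) -> SensitivityScenario:
    """Vary ``parameter_key`` over ``values``, resampling all other inputs."""
    valid = valid_parameter_keys(params)
    if parameter_key not in valid:
        raise KeyError(
            f"unknown parameter key {parameter_key!r}; valid keys: {', '.join(valid)}"
        )
    results = []
    for v in values:
        p = params.copy()
        set_path(p, parameter_key, float(v))
        # collapse the key's PSA distribution so the pin holds in every draw
        p.dispersion.per_key[parameter_key] = {"family": "point"}
        results.append(
            engine.run_psa(
                p,
                n_iterations=n_iterations,
                seed=seed,
                strategies=strategies,
                n_children=n_children,
            )
        )
    return SensitivityScenario(
        parameter_key=parameter_key, values=[float(v) for v in values], results=results
    )
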