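"""Model parameters: reference-case values, distributions, and PSA draws.

The reference case bundles every epidemiological probability, test operating
characteristic, utility weight and unit cost of the model, together with a
distribution family for each quantity that is sampled in the probabilistic
sensitivity analysis (PSA):

* ``beta`` — probabilities with published uncertainty; parameterised by the
  method of moments from the reference mean and an effective sample size
  (pseudo-observation count, default 100), so the sampling mean is exact.
* ``log_normal`` — treatment-success and vision-loss probabilities;
  parameterised on the log scale so the *median* equals the reference value
  and the 97.5th percentile is ``ratio`` (default 1.2) times the median.
  Probability samples are truncated at 1.
* ``normal`` — receipt of social assistance; SD = ``cv`` (default 10%) of the
  mean, truncated to [0, 1].
* ``point`` — everything else is carried at its reference value in every draw.

The packaged default configuration lives in ``data/reference_case.yaml``;
:func:`load_parameters` reads it and applies user overrides.
"""
from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "DispersionConfig",
    "ParameterSet",
    "ParameterDraw",
    "load_parameters",
    "beta_hyperparameters",
    "sample_draw",
    "reference_draw",
    "iter_distributions",
    "get_path",
    "set_path",
]

_Z975 = 1.959963984540054


class ParameterError(ValueError):
    """A parameter value or configuration document failed validation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution assigned to one scalar parameter.

    ``dispersion`` is interpreted per family: effective sample size for
    ``beta``, the 97.5th-percentile/median ratio for ``log_normal``, the
    coefficient of variation for ``normal``, and ignored for ``point``.
    """

    family: str  # point | beta | log_normal | normal
    mean: float
    dispersion: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "beta", "log_normal", "normal"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            # degenerate beta means are treated as point masses upstream
            raise ParameterError("beta mean must lie in (0, 1)")
        if self.lower is not None and self.mean < self.lower:
            raise ParameterError("mean below lower truncation bound")
        if self.upper is not None and self.mean > self.upper:
            raise ParameterError("mean above upper truncation bound")


@dataclass
class DispersionConfig:
    """Default spreads for the PSA families, with optional per-key overrides.

    ``per_key`` maps a dotted parameter key (e.g. ``"sens_pc_amblyopia"`` or
    ``"p_treatment_success_by_age.4"``) to a dict that may set ``family``
    (``"point"`` pins the key) or the family's dispersion knob (``ess``,
    ``ratio`` or ``cv``).
    """

    beta_ess: float = 100.0
    lognormal_p975_ratio: float = 1.2
    normal_cv: float = 0.10
    per_key: dict[str, dict[str, Any]] = field(default_factory=dict)


def _age_map(d: Mapping[int, float]) -> dict[int, float]:
    return {int(k): float(v) for k, v in d.items()}


@dataclass
class ParameterSet:
    """Full reference-case parameter catalogue.

    Probabilities are annual unless noted; costs are 2019 CAD.
    """

    # epidemiology at entry (age 3)
    prevalence_amblyopia: float = 0.058
    prevalence_risk_factor: float = 0.202

    # uptake of testing / care
    p_optometric_exam_uptake: float = 0.880
    p_primary_care_screen: float = 0.610  # conditional on a well-child visit
    p_school_screen: float = 0.810
    p_well_child_visit: float = 0.840
    p_treatment_adherence: float = 0.75
    p_social_assistance: float = 0.04

    # treatment success, by age at treatment
    p_treatment_success_by_age: dict[int, float] = field(
        default_factory=lambda: {3: 0.89, 4: 0.76, 5: 0.65}
    )

    # primary-care referral pathway, by age and screen result
    referral_after_positive_pc: dict[int, float] = field(
        default_factory=lambda: {3: 0.66, 4: 0.91, 5: 0.86}
    )
    referral_after_inconclusive_pc: dict[int, float] = field(
        default_factory=lambda: {3: 0.59, 4: 0.59, 5: 0.50}
    )
    adherence_after_positive_pc: dict[int, float] = field(
        default_factory=lambda: {3: 0.63, 4: 0.62, 5: 0.42}
    )
    adherence_after_inconclusive_pc: dict[int, float] = field(
        default_factory=lambda: {3: 0.34, 4: 0.33, 5: 0.56}
    )

    # school referral pathway (age 5)
    referral_school_positive: float = 1.00
    referral_school_inconclusive: float = 1.00
    adherence_school: float = 0.66

    # inconclusive-result probabilities by true condition class
    p_inconclusive_pc: dict[str, float] = field(
        default_factory=lambda: {
            "amblyopia": 0.05,
            "risk_factor": 0.03,
            "healthy_or_treated": 0.02,
        }
    )
    p_inconclusive_school: dict[str, float] = field(
        default_factory=lambda: {
            "amblyopia": 0.30,
            "risk_factor": 0.12,
            "healthy_or_treated": 0.05,
        }
    )

    # operating characteristics of the screens / exam
    sens_pc_amblyopia: float = 0.659
    sens_pc_risk_factor: float = 0.586
    spec_pc: float = 0.398
    sens_school_amblyopia: float = 0.867
    sens_school_risk_factor: float = 0.882
    spec_school: float = 0.121
    accuracy_optometrist: float = 0.95

    # annual transition probabilities
    p_death_by_age: dict[int, float] = field(
        default_factory=lambda: _age_map(
            {
                3: 0.00014,
                4: 0.00011,
                5: 0.00009,
                6: 0.00008,
                7: 0.00008,
                8: 0.00007,
                9: 0.00008,
                10: 0.00008,
                11: 0.00009,
                12: 0.0001,
                13: 0.00013,
                14: 0.00016,
                15: 0.00021,
                16: 0.00027,
                17: 0.00033,
                18: 0.00039,
            }
        )
    )
    p_healthy_to_risk_factor: float = 0.033  # ages 3-5 only
    p_risk_factor_to_amblyopia: float = 0.32  # ages 3-5 only
    p_success_to_healthy: float = 0.472  # VA >= 20/25 after successful treatment
    p_success_to_treated: float = 0.528  # residual deficit, treated-amblyopia state
    p_vision_loss_5_15: float = 0.00004
    p_vision_loss_16_18: float = 0.00005

    # health-state utility weights
    utilities: dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 1.00,
            "untreated_amblyopia": 0.96,
            "untreated_risk_factor": 0.96,
            "treated_amblyopia": 0.99,
            "vision_loss": 0.93,
            "dead": 0.0,
        }
    )

    # unit costs, 2019 CAD
    cost_well_child_visit: float = 41.34
    cost_pc_screen: float = 11.50
    cost_school_screen: float = 10.00
    cost_nurse_training_per_child: float = 0.01
    cost_opto_diagnostic: float = 42.50
    cost_opto_followup: float = 25.15
    cost_glasses: float = 120.70
    glasses_interval_years: int = 3

    # analysis settings
    discount_rate: float = 0.015
    wtp_threshold: float = 50_000.0
    n_individuals: int = 25_000
    horizon_years: int = 15
    entry_age: int = 3
    exit_age: int = 17
    optometric_exam_age: int = 3  # single mandated exam, placed at entry
    cad_per_usd: float = 1.3268

    dispersion: DispersionConfig = field(default_factory=DispersionConfig)

    def __post_init__(self) -> None:
        validate(self)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


@dataclass
class ParameterDraw(ParameterSet):
    """One PSA realisation of :class:`ParameterSet`.

    Point-mass parameters equal their reference values; distributed
    parameters carry sampled values, truncated to their legal range.
    """

    draw_index: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# validation

_PROBABILITY_SCALARS = (
    "prevalence_amblyopia",
    "prevalence_risk_factor",
    "p_optometric_exam_uptake",
    "p_primary_care_screen",
    "p_school_screen",
    "p_well_child_visit",
    "p_treatment_adherence",
    "p_social_assistance",
    "referral_school_positive",
    "referral_school_inconclusive",
    "adherence_school",
    "sens_pc_amblyopia",
    "sens_pc_risk_factor",
    "spec_pc",
    "sens_school_amblyopia",
    "sens_school_risk_factor",
    "spec_school",
    "accuracy_optometrist",
    "p_healthy_to_risk_factor",
    "p_risk_factor_to_amblyopia",
    "p_success_to_healthy",
    "p_success_to_treated",
    "p_vision_loss_5_15",
    "p_vision_loss_16_18",
)

_PROBABILITY_MAPS = (
    "p_treatment_success_by_age",
    "referral_after_positive_pc",
    "referral_after_inconclusive_pc",
    "adherence_after_positive_pc",
    "adherence_after_inconclusive_pc",
    "p_inconclusive_pc",
    "p_inconclusive_school",
    "p_death_by_age",
)

_COST_SCALARS = (
    "cost_well_child_visit",
    "cost_pc_screen",
    "cost_school_screen",
    "cost_nurse_training_per_child",
    "cost_opto_diagnostic",
    "cost_opto_followup",
    "cost_glasses",
)


def validate(params: ParameterSet) -> None:
    """Raise :class:`ParameterError` naming the offending key, if any."""
    for key in _PROBABILITY_SCALARS:
        v = getattr(params, key)
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{key}={v} outside [0, 1]")
    for key in _PROBABILITY_MAPS:
        for sub, v in getattr(params, key).items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{key}.{sub}={v} outside [0, 1]")
    for key in _COST_SCALARS:
        v = getattr(params, key)
        if v < 0:
            raise ParameterError(f"{key}={v} negative")
    for sub, v in params.utilities.items():
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"utilities.{sub}={v} outside [0, 1]")
    if abs(params.p_success_to_healthy + params.p_success_to_treated - 1.0) > 1e-9:
        raise ParameterError(
            "p_success_to_healthy + p_success_to_treated must equal 1"
        )
    if params.horizon_years != params.exit_age - params.entry_age + 1:
        raise ParameterError("horizon_years must equal exit_age - entry_age + 1")
    if not params.entry_age <= params.optometric_exam_age <= 5:
        raise ParameterError("optometric_exam_age must lie in [entry_age, 5]")
    if params.discount_rate < 0:
        raise ParameterError("discount_rate negative")
    if params.n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")


# ---------------------------------------------------------------------------
# dotted-path access (used by sampling and one-way sensitivity analysis)


def get_path(params: ParameterSet, key: str) -> float:
    obj: Any = params
    for part in key.split("."):
        if isinstance(obj, Mapping):
            k: Any = int(part) if part.lstrip("-").isdigit() else part
            obj = obj[k]
        else:
            obj = getattr(obj, part)
    return obj


def set_path(params: ParameterSet, key: str, value: float) -> None:
    parts = key.split(".")
    obj: Any = params
    for part in parts[:-1]:
        if isinstance(obj, Mapping):
            k: Any = int(part) if part.lstrip("-").isdigit() else part
            obj = obj[k]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, Mapping):
        k = int(last) if last.lstrip("-").isdigit() else last
        if k not in obj:
            raise KeyError(key)
        obj[k] = value
    else:
        if not hasattr(obj, last):
            raise KeyError(key)
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# distribution registry

_BETA_SCALARS = (
    "prevalence_amblyopia",
    "prevalence_risk_factor",
    "p_primary_care_screen",
    "p_school_screen",
    "p_well_child_visit",
    "p_treatment_adherence",
    "adherence_school",
    "p_risk_factor_to_amblyopia",
    "sens_pc_amblyopia",
    "sens_pc_risk_factor",
    "spec_pc",
    "sens_school_amblyopia",
    "sens_school_risk_factor",
    "spec_school",
)
_BETA_MAPS = (
    "referral_after_positive_pc",
    "referral_after_inconclusive_pc",
    "adherence_after_positive_pc",
    "adherence_after_inconclusive_pc",
    "p_inconclusive_pc",
    "p_inconclusive_school",
)
_BETA_ENTRIES = ("utilities.vision_loss",)
_LOGNORMAL_SCALARS = ("p_vision_loss_5_15", "p_vision_loss_16_18")
_LOGNORMAL_MAPS = ("p_treatment_success_by_age",)
_NORMAL_SCALARS = ("p_social_assistance",)


def _distributed_keys(params: ParameterSet) -> list[tuple[str, str]]:
    """Ordered (dotted key, family) pairs for every non-point parameter."""
    keys: list[tuple[str, str]] = []
    for k in _BETA_SCALARS:
        keys.append((k, "beta"))
    for m in _BETA_MAPS:
        for sub in getattr(params, m):
            keys.append((f"{m}.{sub}", "beta"))
    for k in _BETA_ENTRIES:
        keys.append((k, "beta"))
    for k in _LOGNORMAL_SCALARS:
        keys.append((k, "log_normal"))
    for m in _LOGNORMAL_MAPS:
        for sub in getattr(params, m):
            keys.append((f"{m}.{sub}", "log_normal"))
    for k in _NORMAL_SCALARS:
        keys.append((k, "normal"))
    return keys


def _spec_for(params: ParameterSet, key: str, family: str) -> DistributionSpec:
    mean = float(get_path(params, key))
    disp = params.dispersion
    override = disp.per_key.get(key, {})
    family = override.get("family", family)
    if family == "point" or mean in (0.0, 1.0):
        return DistributionSpec("point", mean)
    if family == "beta":
        d = float(override.get("ess", disp.beta_ess))
    elif family == "log_normal":
        d = float(override.get("ratio", disp.lognormal_p975_ratio))
    elif family == "normal":
        d = float(override.get("cv", disp.normal_cv))
    else:  # pragma: no cover - registry only emits known families
        raise ParameterError(f"unknown family {family!r}")
    return DistributionSpec(family, mean, d, lower=0.0, upper=1.0)


def iter_distributions(params: ParameterSet) -> Iterator[tuple[str, DistributionSpec]]:
    """Yield (dotted key, :class:`DistributionSpec`) for every PSA-sampled key."""
    for key, family in _distributed_keys(params):
        yield key, _spec_for(params, key, family)


# ---------------------------------------------------------------------------
# sampling


def beta_hyperparameters(mean: float, effective_sample_size: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a Beta with the requested mean.

    ``alpha = mean * n`` and ``beta = (1 - mean) * n`` where ``n`` is the
    effective sample size in pseudo-observations.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError("beta mean must lie strictly in (0, 1)")
    if effective_sample_size <= 0:
        raise ParameterError("effective sample size must be positive")
    return mean * effective_sample_size, (1.0 - mean) * effective_sample_size


def _sample_one(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "point" or spec.dispersion == 0.0:
        return spec.mean
    if spec.family == "beta":
        a, b = beta_hyperparameters(spec.mean, spec.dispersion)
        v = float(rng.beta(a, b))
    elif spec.family == "log_normal":
        sigma = math.log(spec.dispersion) / _Z975
        v = spec.mean * math.exp(float(rng.normal(0.0, sigma)))
    else:  # normal
        v = float(rng.normal(spec.mean, spec.dispersion * spec.mean))
    lo = spec.lower if spec.lower is not None else -math.inf
    hi = spec.upper if spec.upper is not None else math.inf
    return min(max(v, lo), hi)


def sample_draw(
    params: ParameterSet,
    draw_index: int,
    rng: np.random.Generator,
) -> ParameterDraw:
    """Draw one PSA realisation of the parameter catalogue.

    Point-mass parameters are copied verbatim; distributed parameters are
    sampled from their family in a fixed key order, so a given generator
    state maps deterministically to a draw.
    """
    draw = ParameterDraw(
        **{f.name: copy.deepcopy(getattr(params, f.name)) for f in dataclasses.fields(ParameterSet)},
        draw_index=draw_index,
        seed=0,
    )
    for key, spec in iter_distributions(params):
        set_path(draw, key, _sample_one(spec, rng))
    # the success split is a point pair; re-normalise defensively
    validate_draw(draw)
    return draw


def validate_draw(draw: ParameterDraw) -> None:
    validate(draw)
    if draw.prevalence_amblyopia + draw.prevalence_risk_factor > 1.0:
        raise ParameterError("entry prevalences exceed 1 in combination")


def reference_draw(params: ParameterSet | None = None) -> ParameterDraw:
    """The degenerate draw in which every parameter sits at its reference value."""
    params = params if params is not None else load_parameters()
    return ParameterDraw(
        **{f.name: copy.deepcopy(getattr(params, f.name)) for f in dataclasses.fields(ParameterSet)}
    )


# ---------------------------------------------------------------------------
# configuration documents


def _deep_merge(base: dict, override: Mapping, prefix: str = "") -> dict:
    out = dict(base)
    free_form = prefix.startswith("dispersion.per_key")
    for k, v in override.items():
        dotted = f"{prefix}{k}"
        if k not in base and not free_form:
            raise ParameterError(f"unknown parameter key {dotted!r}")
        if free_form:
            out[k] = v if not isinstance(v, Mapping) else dict(v)
            continue
        if isinstance(base[k], dict) and isinstance(v, Mapping):
            out[k] = _deep_merge(base[k], v, prefix=f"{dotted}.")
        else:
            out[k] = v
    return out


def _default_document() -> dict[str, Any]:
    text = resources.files("amblyosim.data").joinpath("reference_case.yaml").read_text()
    doc = yaml.safe_load(text)
    return doc


def load_parameters(
    source: str | Path | Mapping | None = None,
    overrides: Mapping | None = None,
) -> ParameterSet:
    """Build a :class:`ParameterSet` from the packaged reference case.

    ``source`` may be a YAML path or a mapping; keys not in the catalogue are
    rejected. ``overrides`` is applied last (same rules).
    """
    doc = _default_document()
    for layer in (source, overrides):
        if layer is None:
            continue
        if isinstance(layer, (str, Path)):
            try:
                layer = yaml.safe_load(Path(layer).read_text())
            except yaml.YAMLError as exc:
                raise ParameterError(f"malformed configuration document: {exc}") from exc
        if not isinstance(layer, Mapping):
            raise ParameterError("configuration document must be a mapping")
        doc = _deep_merge(doc, layer)
    disp = doc.pop("dispersion", {})
    kwargs = dict(doc)
    kwargs["p_death_by_age"] = _age_map(kwargs["p_death_by_age"])
    for m in ("p_treatment_success_by_age", *(_BETA_MAPS[:4])):
        kwargs[m] = _age_map(kwargs[m])
    try:
        return ParameterSet(dispersion=DispersionConfig(**disp), **kwargs)
    except TypeError as exc:
        raise ParameterError(str(exc)) from exc
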