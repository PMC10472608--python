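"""One-way (tornado) and probabilistic sensitivity analysis.

Both analyses re-run the full deterministic costing chain with perturbed
parameters and track the cost per additionally vaccinated child. The
one-way analysis moves one parameter at a time between its low and high
value, ranking parameters by the output range they induce (the tornado
ordering). The probabilistic analysis (PSA) draws all parameters jointly
and independently from their distributions and summarizes the resulting
output distribution.

The PSA always evaluates the chain in ``exact`` mode: the printed-figure
rounding steps are a presentation convention, and leaving them inside a
Monte Carlo would inject artificial discreteness into the output
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from pydantic import ValidationError
from scipy import stats

from .config import AnalysisConfig
from .pipeline import run_pipeline


class SensitivityError(ValueError):
    """Raised on an unknown parameter or invalid distribution."""


@dataclass(frozen=True)
class ParamSpec:
    """Range (and optionally distribution) for one chain parameter.

    ``name`` is a dotted config path such as ``impact.stockout_after``,
    ``population.coverage`` or ``total_cost_override``. ``distribution``
    is required for the PSA: ``{"kind": "uniform"}`` (bounds low/high),
    ``{"kind": "triangular"}`` (mode defaults to base), or
    ``{"kind": "normal"}`` (mean defaults to base, ``sd`` required,
    truncated to [low, high]).
    """

    name: str
    base: float
    low: float
    high: float
    distribution: Optional[Mapping[str, Any]] = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise SensitivityError(
                f"{self.name}: require low <= base <= high, got "
                f"{self.low}, {self.base}, {self.high}"
            )


class OneWayRow(NamedTuple):
    """Cost per child at a parameter's low, base and high value."""

    at_low: float
    at_base: float
    at_high: float

    @property
    def range(self) -> float:
        return max(self.at_low, self.at_high) - min(self.at_low, self.at_high)


@dataclass(frozen=True)
class PsaSummary:
    """Monte Carlo summary of the cost-per-child distribution."""

    mean: float
    p2_5: float
    p97_5: float


@dataclass(frozen=True)
class SensitivityResult:
    """Output of a one-way or probabilistic sensitivity run."""

    base_value: float
    per_parameter: Mapping[str, OneWayRow] = field(default_factory=dict)
    psa_summary: Optional[PsaSummary] = None
    n_draws: int = 0
    seed: Optional[int] = None

    def tornado_order(self) -> list[str]:
        """Parameter names by descending induced output range."""
        return sorted(
            self.per_parameter,
            key=lambda name: self.per_parameter[name].range,
            reverse=True,
        )


def _evaluate(base: AnalysisConfig, overrides: Mapping[str, float], *, exact: bool = False) -> float:
    """Cost per child with ``overrides`` applied to a copy of ``base``."""
    cfg = base.model_copy(deep=True)
    if exact:
        cfg.mode = "exact"
    for name, value in overrides.items():
        try:
            current = cfg.get_param(name)
        except KeyError as exc:
            raise SensitivityError(str(exc)) from None
        if isinstance(current, int) and not isinstance(current, bool):
            value = int(round(value))
        try:
            cfg.set_param(name, value)
        except (KeyError, ValidationError) as exc:
            raise SensitivityError(f"cannot set {name!r} to {value!r}: {exc}") from None
    return run_pipeline(cfg).incremental.cost_per_child


def one_way(base_config: AnalysisConfig, specs: Sequence[ParamSpec]) -> SensitivityResult:
    """One-way sensitivity: each parameter to its low and high in turn.

    All other parameters stay at base. Results are independent of spec
    order; unknown parameter names are rejected by name.
    """
    base_value = _evaluate(base_config, {})
    rows: dict[str, OneWayRow] = {}
    for spec in specs:
        rows[spec.name] = OneWayRow(
            at_low=_evaluate(base_config, {spec.name: spec.low}),
            at_base=base_value,
            at_high=_evaluate(base_config, {spec.name: spec.high}),
        )
    return SensitivityResult(base_value=base_value, per_parameter=rows)


def _sample(spec: ParamSpec, rng: np.random.Generator) -> float:
    if spec.distribution is None:
        raise SensitivityError(f"{spec.name}: PSA requires a distribution")
    dist = dict(spec.distribution)
    kind = dist.pop("kind", None)
    if kind == "uniform":
        if spec.low == spec.high:
            return spec.low
        return float(rng.uniform(spec.low, spec.high))
    if kind == "triangular":
        mode = float(dist.pop("mode", spec.base))
        if not spec.low <= mode <= spec.high:
            raise SensitivityError(f"{spec.name}: triangular mode outside [low, high]")
        if spec.low == spec.high:
            return spec.low
        return float(rng.triangular(spec.low, mode, spec.high))
    if kind == "normal":
        mean = float(dist.pop("mean", spec.base))
        sd = dist.pop("sd", None)
        if sd is None or not float(sd) > 0:
            raise SensitivityError(f"{spec.name}: truncated normal requires sd > 0")
        sd = float(sd)
        a, b = (spec.low - mean) / sd, (spec.high - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    raise SensitivityError(
        f"{spec.name}: unknown distribution kind {kind!r}; "
        "expected uniform, triangular or normal"
    )


def probabilistic(
    base_config: AnalysisConfig,
    specs: Sequence[ParamSpec],
    n_draws: int = 10_000,
    seed: int = 0,
) -> SensitivityResult:
    """Probabilistic sensitivity analysis with joint independent draws.

    Each draw samples every spec's distribution, evaluates the chain in
    ``exact`` mode, and the cost-per-child sample is summarized by its
    mean and 2.5th/97.5th percentiles. Identical seeds give identical
    summaries.
    """
    if n_draws < 1:
        raise SensitivityError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    values = np.empty(n_draws)
    for i in range(n_draws):
        overrides = {spec.name: _sample(spec, rng) for spec in specs}
        values[i] = _evaluate(base_config, overrides, exact=True)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return SensitivityResult(
        base_value=_evaluate(base_config, {}, exact=True),
        psa_summary=PsaSummary(mean=float(values.mean()), p2_5=float(lo), p97_5=float(hi)),
        n_draws=n_draws,
        seed=seed,
    )
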