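"""Validated configuration for the full costing chain.

Defaults are the study parameters of the Bauchi vaccine direct-delivery
costing: the 2019 reference monthly cost by category, the Jul 2015 -
Dec 2018 operational period, Nigerian CPI inflation rates, the stockout
effect and dose-loss translation parameters, and the state population
inputs. ``AnalysisConfig()`` with no arguments is therefore the complete
study fixture; YAML files override any subset of keys.
"""

from __future__ import annotations

from typing import IO, Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Model(BaseModel):
    model_config = ConfigDict(validate_assignment=True)


class PeriodConfig(_Model):
    start: str = "2015-07"
    end: str = "2018-12"


class InflationConfig(_Model):
    # Annual CPI fractions; 2019 is the reference (expense-report) year.
    rates: dict[int, float] = Field(
        default_factory=lambda: {2015: 0.09, 2016: 0.157, 2017: 0.165, 2018: 0.121, 2019: 0.114}
    )
    convention: Literal[
        "none", "own_year", "compound_to_end", "compound_to_reference", "deflate_from_reference"
    ] = "own_year"
    reference_year: int = 2019


class ImpactConfig(_Model):
    weekly_dose_loss: int = 77
    weeks_per_month: int = 4
    national_monthly_doses: int = 508_052
    n_lgas: int = 774
    stockout_before: float = 0.389
    stockout_after: float = 0.172


class PopulationConfig(_Model):
    # frac_under_two: half of the 8% of the population under four years old.
    total: int = 8_000_000
    frac_under_two: float = 0.04
    coverage: float = 0.808


class BudgetConfig(_Model):
    monthly_usd: float = 39_930.0


class ReferenceCostsConfig(_Model):
    """Development and capital costs, echoed as reference fields only.

    Excluded from the implementation total unless ``include_capital`` is
    set (they are shared with the implementer's other programs).
    """

    development_usd: float = 101_552.0
    capital_usd: float = 134_622.0


class AnalysisConfig(_Model):
    """Complete parameter set of the costing chain."""

    mode: Literal["paper", "exact"] = "paper"
    fx_naira_per_usd: float = 360.0
    n_projects: int = 14
    # 2019 reference monthly implementation cost by category, USD.
    monthly_category_costs_usd: dict[str, float] = Field(
        default_factory=lambda: {
            "personnel": 4891.0,
            "vaccine_transportation": 1628.0,
            "software_support": 2244.0,
            "other": 1792.0,
        }
    )
    # Printed headline total consumed as a pass-through input (its exact
    # inflation arithmetic is under-determined); None falls back to the
    # convention-computed total.
    total_cost_override: Optional[float] = 542_132.0
    include_capital: bool = False
    period: PeriodConfig = Field(default_factory=PeriodConfig)
    inflation: InflationConfig = Field(default_factory=InflationConfig)
    impact: ImpactConfig = Field(default_factory=ImpactConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    budget: BudgetConfig = Field(default_factory=BudgetConfig)
    reference_costs: ReferenceCostsConfig = Field(default_factory=ReferenceCostsConfig)
    # Optional sensitivity block: dotted parameter name -> {base?, low,
    # high, distribution?}; base defaults to the configured value.
    sensitivity: dict[str, dict[str, Any]] = Field(default_factory=dict)

    @field_validator("fx_naira_per_usd")
    @classmethod
    def _fx_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("fx_naira_per_usd must be positive")
        return v

    @property
    def monthly_cost_usd(self) -> float:
        """Reference monthly implementation cost (sum over categories)."""
        return sum(self.monthly_category_costs_usd.values())

    # -- dotted-path access (used by the sensitivity layer) ---------------

    def get_param(self, name: str) -> Any:
        """Look up a parameter by dotted path, e.g. ``impact.stockout_after``."""
        obj: Any = self
        for part in name.split("."):
            if isinstance(obj, dict):
                key: Any = part
                if key not in obj and part.isdigit():
                    key = int(part)
                if key not in obj:
                    raise KeyError(f"unknown parameter {name!r}")
                obj = obj[key]
            elif isinstance(obj, BaseModel) and part in type(obj).model_fields:
                obj = getattr(obj, part)
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return obj

    def set_param(self, name: str, value: Any) -> None:
        """Assign a parameter by dotted path (validated by the model)."""
        parts = name.split(".")
        obj: Any = self
        for part in parts[:-1]:
            if isinstance(obj, dict):
                if part not in obj:
                    raise KeyError(f"unknown parameter {name!r}")
                obj = obj[part]
            elif isinstance(obj, BaseModel) and part in type(obj).model_fields:
                obj = getattr(obj, part)
            else:
                raise KeyError(f"unknown parameter {name!r}")
        leaf = parts[-1]
        if isinstance(obj, dict):
            key: Any = leaf
            if key not in obj and leaf.isdigit():
                key = int(leaf)
            if key not in obj:
                raise KeyError(f"unknown parameter {name!r}")
            obj[key] = value
        elif isinstance(obj, BaseModel) and leaf in type(obj).model_fields:
            setattr(obj, leaf, value)
        else:
            raise KeyError(f"unknown parameter {name!r}")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, target: str | IO[str] | None = None) -> str:
        """Serialize to YAML; optionally also write to ``target``."""
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if target is not None:
            if hasattr(target, "write"):
                target.write(text)  # type: ignore[union-attr]
            else:
                with open(target, "w") as fh:
                    fh.write(text)
        return text


def load_config(source: str | IO[str] | None = None) -> AnalysisConfig:
    """Build a config from a YAML file (or stream), filling gaps with defaults."""
    if source is None:
        return AnalysisConfig()
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())  # type: ignore[union-attr]
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    return AnalysisConfig(**(data or {}))
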