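"""Head-count step and incremental cost per additionally vaccinated child.

The uptake increase from the impact chain is applied to the state's
vaccinated-child population: total population x fraction under two years
old gives the vaccine-eligible children; times baseline coverage gives
the children actually vaccinated; times the uptake increase gives the
additional children vaccinated because of the program. Dividing the
total program cost by that head count yields the incremental cost per
additional child — the study's headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rounding import round_half_up


class IncrementalError(ValueError):
    """Raised on degenerate head-count or budget inputs."""


@dataclass(frozen=True)
class PopulationParams:
    """State population, under-two fraction, and baseline coverage."""

    total_population: int = 8_000_000
    frac_under_two: float = 0.04
    coverage: float = 0.808

    def __post_init__(self) -> None:
        if self.total_population < 0:
            raise IncrementalError("population must be non-negative")
        for name in ("frac_under_two", "coverage"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise IncrementalError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class IncrementalCostResult:
    """Head counts and unit costs of the incremental chain."""

    eligible_children: int
    vaccinated_children: int
    additional_children: int
    total_cost: float
    cost_per_child: float
    cost_per_stockout_point: float

    def __post_init__(self) -> None:
        if not (
            self.additional_children
            <= self.vaccinated_children
            <= self.eligible_children
        ):
            raise IncrementalError("head counts must be nested: additional <= vaccinated <= eligible")


def eligible_children(params: PopulationParams) -> int:
    """Vaccine-eligible (under-two) children: population x fraction, rounded."""
    return int(round_half_up(params.total_population * params.frac_under_two))


def vaccinated_children(eligible: int, coverage: float) -> int:
    """Children receiving at least one vaccine: eligible x coverage, rounded."""
    if not 0.0 <= coverage <= 1.0:
        raise IncrementalError(f"coverage must lie in [0, 1], got {coverage}")
    return int(round_half_up(eligible * coverage))


def additional_children(vaccinated: int, uptake_increase: float) -> int:
    """Additional children vaccinated due to the program, rounded to nearest."""
    if not 0.0 <= uptake_increase <= 1.0:
        raise IncrementalError(f"uptake increase must lie in [0, 1], got {uptake_increase}")
    return int(round_half_up(vaccinated * uptake_increase))


def cost_per_child(total_cost: float, additional: int) -> float:
    """Incremental cost per additional vaccinated child (full precision).

    Displayed to 2 decimals (542,132 / 26,373 -> 20.56).
    """
    if additional < 1:
        raise IncrementalError("program produced no additional vaccinations")
    return total_cost / additional


def budget_share(monthly_cost: float, monthly_budget: float) -> float:
    """Program monthly cost as a fraction of the routine-immunization budget."""
    if not monthly_budget > 0:
        raise IncrementalError(f"monthly budget must be positive, got {monthly_budget}")
    return monthly_cost / monthly_budget


def compute_incremental(
    params: PopulationParams,
    uptake_increase: float,
    total_cost: float,
    stockout_reduction_points: float,
) -> IncrementalCostResult:
    """Run the head-count chain and unit-cost ratios.

    ``stockout_reduction_points`` is on the 0-100 scale (21.7 for the
    default stockout effect).
    """
    eligible = eligible_children(params)
    vaccinated = vaccinated_children(eligible, params.coverage)
    additional = additional_children(vaccinated, uptake_increase)
    if not stockout_reduction_points > 0:
        raise IncrementalError(
            f"stockout reduction must be positive, got {stockout_reduction_points}"
        )
    return IncrementalCostResult(
        eligible_children=eligible,
        vaccinated_children=vaccinated,
        additional_children=additional,
        total_cost=total_cost,
        cost_per_child=cost_per_child(total_cost, additional),
        cost_per_stockout_point=total_cost / stockout_reduction_points,
    )
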