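"""Annualization and CPI inflation adjustment of the monthly program cost.

The reference monthly cost (measured in the most complete reporting year)
is spread over the operational period — 6 months of 2015, then 12 months
each of 2016-2018 for the default Jul 2015 - Dec 2018 window — and each
year's cost is restated with annual consumer-price-index inflation rates.

The verbal description "for each year, the inflation rate was applied"
admits several arithmetic readings, so the convention is an explicit,
named choice rather than an implicit one:

``none``
    No adjustment; the nominal annual cost.
``own_year``
    Each year's cost is multiplied by (1 + that year's rate).
``compound_to_end``
    Each year's cost is compounded forward through the final program
    year: prod of (1 + r_j) for j from the cost year to the end year.
``compound_to_reference``
    Compounded forward through the reference year (default 2019), i.e.
    restated in reference-year prices assuming costs accrue at the start
    of their year.
``deflate_from_reference``
    The reference-year monthly cost is deflated back to each program
    year's price level: divided by prod of (1 + r_j) for j from the year
    after the cost year through the reference year.

None of these is privileged by the chain: downstream ratios consume an
explicit total (see the pipeline's ``total_cost_override``), and the
convention-computed total is reported alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .rounding import round_half_up

Convention = Literal[
    "none",
    "own_year",
    "compound_to_end",
    "compound_to_reference",
    "deflate_from_reference",
]

CONVENTIONS: tuple[str, ...] = (
    "none",
    "own_year",
    "compound_to_end",
    "compound_to_reference",
    "deflate_from_reference",
)


class InflationError(ValueError):
    """Raised on an unknown convention or a missing rate."""


@dataclass(frozen=True)
class ProgramPeriod:
    """Inclusive year-month window of program operation."""

    start: pd.Period
    end: pd.Period

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Period(self.start, freq="M"))
        object.__setattr__(self, "end", pd.Period(self.end, freq="M"))
        if self.start > self.end:
            raise InflationError(f"period start {self.start} after end {self.end}")

    @property
    def n_months(self) -> int:
        return (self.end - self.start).n + 1

    @property
    def years(self) -> range:
        return range(self.start.year, self.end.year + 1)


@dataclass(frozen=True)
class InflationSchedule:
    """Annual CPI inflation fractions by calendar year (0.157 = 15.7%)."""

    rates: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, rate in self.rates.items():
            if rate <= -1:
                raise InflationError(f"rate for {year} must exceed -1, got {rate}")

    def rate(self, year: int) -> float:
        try:
            return self.rates[year]
        except KeyError:
            raise InflationError(f"no inflation rate for year {year}") from None


@dataclass(frozen=True)
class TotalCostResult:
    """Annualized program cost, nominal and inflation-adjusted."""

    nominal_total: float
    adjusted_total: float
    per_year: Mapping[int, float]
    convention: str


def months_in_year(period: ProgramPeriod, year: int) -> int:
    """Operational months of ``year`` inside ``period`` (0 outside)."""
    y_start = pd.Period(f"{year}-01", freq="M")
    y_end = pd.Period(f"{year}-12", freq="M")
    lo = max(period.start, y_start)
    hi = min(period.end, y_end)
    return max(0, (hi - lo).n + 1)


def _factor(
    year: int,
    period: ProgramPeriod,
    schedule: InflationSchedule,
    convention: str,
    reference_year: int,
) -> float:
    if convention == "none":
        return 1.0
    if convention == "own_year":
        return 1.0 + schedule.rate(year)
    if convention == "compound_to_end":
        return math.prod(1.0 + schedule.rate(y) for y in range(year, period.end.year + 1))
    if convention == "compound_to_reference":
        return math.prod(1.0 + schedule.rate(y) for y in range(year, reference_year + 1))
    if convention == "deflate_from_reference":
        return 1.0 / math.prod(
            1.0 + schedule.rate(y) for y in range(year + 1, reference_year + 1)
        )
    raise InflationError(
        f"unknown inflation convention {convention!r}; expected one of {', '.join(CONVENTIONS)}"
    )


def adjust_total(
    monthly_cost: float,
    period: ProgramPeriod,
    schedule: InflationSchedule,
    convention: str = "own_year",
    reference_year: int = 2019,
) -> TotalCostResult:
    """Annualize ``monthly_cost`` over ``period`` and apply inflation.

    Each year's cost is ``monthly_cost x months_in_year x factor`` with the
    convention-specific factor; the adjusted total is the sum over years.

    Raises
    ------
    InflationError
        On an unknown convention label, or a rate missing for a needed year.
    """
    if convention not in CONVENTIONS:
        raise InflationError(
            f"unknown inflation convention {convention!r}; "
            f"expected one of {', '.join(CONVENTIONS)}"
        )
    per_year: dict[int, float] = {}
    nominal = 0.0
    for year in period.years:
        m = months_in_year(period, year)
        if m == 0:
            continue
        nominal += monthly_cost * m
        per_year[year] = monthly_cost * m * _factor(
            year, period, schedule, convention, reference_year
        )
    return TotalCostResult(
        nominal_total=nominal,
        adjusted_total=sum(per_year.values()),
        per_year=per_year,
        convention=convention,
    )


def cost_per_stockout_point(total_cost: float, stockout_reduction_points: float) -> float:
    """Program cost per percentage point of stockout prevalence reduced.

    ``stockout_reduction_points`` is on the 0-100 scale (21.7, not 0.217).
    Returns full precision; display rounds to whole USD.
    """
    if not stockout_reduction_points > 0:
        raise InflationError(
            f"stockout reduction must be positive, got {stockout_reduction_points}"
        )
    return total_cost / stockout_reduction_points


def display_cost_per_point(total_cost: float, stockout_reduction_points: float) -> float:
    """Whole-dollar display value of :func:`cost_per_stockout_point`."""
    return round_half_up(cost_per_stockout_point(total_cost, stockout_reduction_points))
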