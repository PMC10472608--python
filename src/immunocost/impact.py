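"""Translation of stockout prevalence into vaccine-uptake effects.

The chain converts a month-long vaccine stockout in one local government
area (LGA) into a fractional loss of the doses that LGA would otherwise
deliver, then scales that loss by the monthly stockout prevalence with
and without the delivery program:

1. A week of stockout loses ``weekly_dose_loss`` child-vaccinations per
   LGA per month (a measles-derived estimate applied to all program
   vaccines); a month-long stockout loses 4x that (77 x 4 = 308).
2. National monthly dose throughput divided by the number of LGAs gives
   doses per LGA per month (508,052 / 774 = 656.398..., displayed 656).
3. Their ratio is the fractional dose reduction a month-long stockout
   causes in one LGA (308 / 656.398 = 0.46923, displayed 0.469).
4. Multiplying by the stockout prevalence gives the percentage-point
   uptake reduction; the difference between the without-program and
   with-program prevalences gives the program's uptake increase.

Two computation modes exist. ``exact`` carries full precision end to
end. ``paper`` reproduces the printed chain: the reduction fraction is
rounded to 3 decimals before step 4 (0.469 x 0.389 = 0.18244 -> 0.182;
the unrounded fraction would print 0.183), and the uptake increase is
rounded to 3 decimals (0.102) before the downstream head-count step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

from .rounding import round_half_up

Mode = Literal["paper", "exact"]


class ImpactError(ValueError):
    """Raised on out-of-range or degenerate impact inputs."""


@dataclass(frozen=True)
class StockoutEffect:
    """Monthly stockout prevalence without and with the program."""

    rate_before: float
    rate_after: float

    def __post_init__(self) -> None:
        for name, value in (("rate_before", self.rate_before), ("rate_after", self.rate_after)):
            if not 0.0 <= value <= 1.0:
                raise ImpactError(f"{name} must lie in [0, 1], got {value}")

    @property
    def difference(self) -> float:
        """Prevalence reduction attributable to the program (may be < 0)."""
        return self.rate_before - self.rate_after


@dataclass(frozen=True)
class UptakeTranslationParams:
    """Dose-loss and throughput parameters of the translation chain."""

    weekly_dose_loss: int = 77
    weeks_per_month: int = 4
    national_monthly_doses: int = 508_052
    n_lgas: int = 774

    def __post_init__(self) -> None:
        for name in ("weekly_dose_loss", "weeks_per_month", "national_monthly_doses", "n_lgas"):
            if getattr(self, name) <= 0:
                raise ImpactError(f"{name} must be a positive count")


class LgaThroughput(NamedTuple):
    """Doses per LGA per month: full precision plus rounded display."""

    exact: float
    display: int


@dataclass(frozen=True)
class ImpactResult:
    """Every intermediate of the stockout-to-uptake chain.

    Fractions are on the 0-1 scale; ``uptake_increase`` is the value the
    head-count step consumes (3-decimal rounded in paper mode, full
    precision in exact mode).
    """

    monthly_dose_loss: int
    doses_per_lga: LgaThroughput
    reduction_fraction: float
    reduction_fraction_working: float
    uptake_reduction_no_program: float
    uptake_reduction_with_program: float
    uptake_increase: float
    uptake_increase_exact: float
    mode: Mode


def monthly_dose_loss(weekly_dose_loss: int, weeks_per_month: int) -> int:
    """Doses lost per LGA per month of stockout (77 x 4 weeks = 308)."""
    if weekly_dose_loss <= 0 or weeks_per_month <= 0:
        raise ImpactError("weekly dose loss and weeks per month must be positive")
    return weekly_dose_loss * weeks_per_month


def doses_per_lga(national_monthly_doses: int, n_lgas: int) -> LgaThroughput:
    """Monthly dose throughput of one LGA, exact and rounded."""
    if n_lgas < 1:
        raise ImpactError(f"n_lgas must be >= 1, got {n_lgas}")
    exact = national_monthly_doses / n_lgas
    return LgaThroughput(exact=exact, display=int(round_half_up(exact)))


def reduction_fraction(monthly_loss: float, lga_throughput: float) -> float:
    """Fractional dose reduction caused by a one-month stockout in a LGA.

    Uses the full-precision throughput denominator: 308 / 656.398 = 0.46923,
    which displays as 0.469 under half-up rounding.
    """
    if not lga_throughput > 0:
        raise ImpactError(f"LGA throughput must be positive, got {lga_throughput}")
    frac = monthly_loss / lga_throughput
    if frac > 1.0:
        raise ImpactError("stockout loss exceeds monthly throughput")
    return frac


def uptake_reduction(reduction_frac: float, stockout_rate: float) -> float:
    """Percentage-point uptake reduction (0-1 scale) at a stockout prevalence."""
    for name, value in (("reduction fraction", reduction_frac), ("stockout rate", stockout_rate)):
        if not 0.0 <= value <= 1.0:
            raise ImpactError(f"{name} must lie in [0, 1], got {value}")
    return reduction_frac * stockout_rate


def uptake_increase(
    reduction_frac: float, effect: StockoutEffect, mode: Mode = "exact"
) -> float:
    """Program-attributable uptake increase, 0-1 scale.

    ``reduction_frac x (rate_before - rate_after)`` at full precision; in
    paper mode the result is then rounded to 3 decimals (0.102).
    """
    value = reduction_frac * effect.difference
    if mode == "paper":
        return round_half_up(value, 3)
    return value


def compute_impact(
    params: UptakeTranslationParams,
    effect: StockoutEffect,
    mode: Mode = "paper",
) -> ImpactResult:
    """Run the full stockout-to-uptake chain in the requested mode."""
    if mode not in ("paper", "exact"):
        raise ImpactError(f"unknown mode {mode!r}; expected 'paper' or 'exact'")
    loss = monthly_dose_loss(params.weekly_dose_loss, params.weeks_per_month)
    throughput = doses_per_lga(params.national_monthly_doses, params.n_lgas)
    frac = reduction_fraction(loss, throughput.exact)
    working = round_half_up(frac, 3) if mode == "paper" else frac
    return ImpactResult(
        monthly_dose_loss=loss,
        doses_per_lga=throughput,
        reduction_fraction=frac,
        reduction_fraction_working=working,
        uptake_reduction_no_program=uptake_reduction(working, effect.rate_before),
        uptake_reduction_with_program=uptake_reduction(working, effect.rate_after),
        uptake_increase=uptake_increase(working, effect, mode=mode),
        uptake_increase_exact=uptake_increase(frac, effect, mode="exact"),
        mode=mode,
    )
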