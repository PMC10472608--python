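"""End-to-end orchestration: config (+ optional ledger) to a result report.

Runs the four stages in order — ledger aggregation, annualization and
inflation adjustment, stockout-to-uptake translation, head-count and
unit costs — logging every intermediate at INFO with both its full-
precision and displayed value, since the display-rounding chain is the
subtlest part of reproducing the printed figures.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Any, Literal, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .impact import ImpactResult, StockoutEffect, UptakeTranslationParams, compute_impact
from .incremental import (
    IncrementalCostResult,
    PopulationParams,
    budget_share,
    compute_incremental,
)
from .inflation import InflationSchedule, ProgramPeriod, TotalCostResult, adjust_total
from .ledger import CostBreakdown, ExpenseLineItem, FxRate, average_monthly_breakdown
from .rounding import fraction_to_points, round_half_up

logger = logging.getLogger("immunocost")


class PipelineError(ValueError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PipelineReport:
    """Every intermediate of one pipeline run, plus the resolved config."""

    breakdown: CostBreakdown
    total_cost: TotalCostResult
    effective_total: float
    impact: ImpactResult
    incremental: IncrementalCostResult
    budget_share: float
    mode: str
    config_echo: dict[str, Any]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ValueError) and not isinstance(
                exc, PipelineError
            ):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    config: AnalysisConfig,
    ledger_items: Optional[Sequence[ExpenseLineItem]] = None,
) -> PipelineReport:
    """Execute the full costing chain.

    When ``ledger_items`` is given, its average monthly breakdown
    overrides the configured per-category monthly costs; otherwise the
    configured 2019 reference breakdown is used directly.
    """
    with _stage("ledger"):
        if ledger_items is not None:
            breakdown = average_monthly_breakdown(
                ledger_items, config.n_projects, FxRate(config.fx_naira_per_usd)
            )
        else:
            per_cat = dict(config.monthly_category_costs_usd)
            breakdown = CostBreakdown(per_category=per_cat, total=sum(per_cat.values()))
    monthly = breakdown.total
    logger.info("monthly implementation cost: %.6f USD (display %d)", monthly, round_half_up(monthly))

    with _stage("inflation"):
        period = ProgramPeriod(config.period.start, config.period.end)
        schedule = InflationSchedule(config.inflation.rates)
        total = adjust_total(
            monthly,
            period,
            schedule,
            convention=config.inflation.convention,
            reference_year=config.inflation.reference_year,
        )
        effective_total = (
            config.total_cost_override
            if config.total_cost_override is not None
            else total.adjusted_total
        )
        if config.include_capital:
            effective_total += (
                config.reference_costs.development_usd + config.reference_costs.capital_usd
            )
    logger.info(
        "total cost: convention(%s)=%.2f, effective=%.2f USD",
        total.convention,
        total.adjusted_total,
        effective_total,
    )

    with _stage("impact"):
        effect = StockoutEffect(config.impact.stockout_before, config.impact.stockout_after)
        impact = compute_impact(
            UptakeTranslationParams(
                weekly_dose_loss=config.impact.weekly_dose_loss,
                weeks_per_month=config.impact.weeks_per_month,
                national_monthly_doses=config.impact.national_monthly_doses,
                n_lgas=config.impact.n_lgas,
            ),
            effect,
            mode=config.mode,
        )
    logger.info(
        "impact: reduction fraction %.6f (working %.3f), uptake increase %.6f (exact %.6f)",
        impact.reduction_fraction,
        impact.reduction_fraction_working,
        impact.uptake_increase,
        impact.uptake_increase_exact,
    )

    with _stage("incremental"):
        incr = compute_incremental(
            PopulationParams(
                total_population=config.population.total,
                frac_under_two=config.population.frac_under_two,
                coverage=config.population.coverage,
            ),
            impact.uptake_increase,
            effective_total,
            fraction_to_points(effect.difference),
        )
        share = budget_share(monthly, config.budget.monthly_usd)
    logger.info(
        "incremental: %d additional children, %.4f USD/child (display %.2f), %.2f USD per stockout point",
        incr.additional_children,
        incr.cost_per_child,
        round_half_up(incr.cost_per_child, 2),
        incr.cost_per_stockout_point,
    )

    return PipelineReport(
        breakdown=breakdown,
        total_cost=total,
        effective_total=effective_total,
        impact=impact,
        incremental=incr,
        budget_share=share,
        mode=config.mode,
        config_echo=config.model_dump(),
    )


def _report_rows(report: PipelineReport) -> list[tuple[str, str, str]]:
    """(section, item, displayed value) rows; the single source for both formats."""
    rows: list[tuple[str, str, str]] = []
    for cat, value in report.breakdown.per_category.items():
        rows.append(("monthly_costs", cat, f"{round_half_up(value):.0f}"))
    rows.append(("monthly_costs", "total", f"{round_half_up(report.breakdown.total):.0f}"))
    rows.append(
        ("total_cost", f"adjusted ({report.total_cost.convention})",
         f"{round_half_up(report.total_cost.adjusted_total):.0f}")
    )
    rows.append(("total_cost", "nominal", f"{round_half_up(report.total_cost.nominal_total):.0f}"))
    rows.append(("total_cost", "effective", f"{round_half_up(report.effective_total):.0f}"))
    imp = report.impact
    rows.append(("impact", "monthly dose loss per LGA", str(imp.monthly_dose_loss)))
    rows.append(("impact", "doses per LGA per month", str(imp.doses_per_lga.display)))
    rows.append(("impact", "reduction fraction", f"{round_half_up(imp.reduction_fraction, 3):.3f}"))
    rows.append(
        ("impact", "uptake reduction without program",
         f"{round_half_up(imp.uptake_reduction_no_program, 3):.3f}")
    )
    rows.append(
        ("impact", "uptake reduction with program",
         f"{round_half_up(imp.uptake_reduction_with_program, 3):.3f}")
    )
    rows.append(("impact", "uptake increase", f"{round_half_up(imp.uptake_increase, 3):.3f}"))
    inc = report.incremental
    rows.append(("incremental", "eligible children", str(inc.eligible_children)))
    rows.append(("incremental", "vaccinated children", str(inc.vaccinated_children)))
    rows.append(("incremental", "additional children", str(inc.additional_children)))
    rows.append(
        ("incremental", "cost per additional child", f"{round_half_up(inc.cost_per_child, 2):.2f}")
    )
    rows.append(
        ("incremental", "cost per stockout percentage point",
         f"{round_half_up(inc.cost_per_stockout_point):.0f}")
    )
    rows.append(
        ("incremental", "share of routine immunization budget",
         f"{round_half_up(100 * report.budget_share, 1):.1f}%")
    )
    rows.append(("meta", "mode", report.mode))
    return rows


def render_report(report: PipelineReport, format: Literal["csv", "text"] = "text") -> str:
    """Serialize a report deterministically as CSV or human-readable text.

    Dollar values print to whole USD except the cost per child (2
    decimals); fractions print to 3 decimals.
    """
    rows = _report_rows(report)
    if format == "csv":
        frame = pd.DataFrame(rows, columns=["section", "item", "value"])
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "text":
        lines = []
        section = None
        for sec, item, value in rows:
            if sec != section:
                lines.append(f"== {sec} ==")
                section = sec
            lines.append(f"{item}: {value}")
        return "\n".join(lines) + "\n"
    raise PipelineError("report", f"unknown report format {format!r}")
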