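"""Expense-ledger ingestion and monthly cost aggregation.

An expense ledger is a CSV table of dated cost line items in naira (NGN),
labelled with one of four implementation-cost categories (personnel,
vaccine transportation, software support, other) and a flag marking costs
shared with the implementer's other concurrent projects. This module
parses such ledgers, attributes each item's per-project share, converts
to USD at a fixed exchange rate, and aggregates into the per-category
monthly cost breakdown that heads the costing chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .rounding import round_half_up

#: The closed set of implementation-cost categories.
CATEGORIES: tuple[str, ...] = (
    "personnel",
    "vaccine_transportation",
    "software_support",
    "other",
)

#: Required columns of the CSV ledger dialect.
LEDGER_COLUMNS: tuple[str, ...] = ("month", "category", "sub_category", "amount_ngn", "shared")


class LedgerError(ValueError):
    """Raised when a ledger fails validation."""


def normalize_category(label: str) -> str:
    """Map a free-form category label onto the closed category set.

    Matching is case- and whitespace-insensitive ("Vaccine Transportation"
    -> "vaccine_transportation"). Unknown labels raise :class:`LedgerError`.
    """
    key = "_".join(str(label).strip().lower().split())
    if key not in CATEGORIES:
        raise LedgerError(
            f"unknown category {label!r}; expected one of {', '.join(CATEGORIES)}"
        )
    return key


@dataclass(frozen=True)
class ExpenseLineItem:
    """One dated expense entry in NGN.

    Attributes
    ----------
    month : pandas.Period
        Calendar year-month of the expense (day-level dates are truncated;
        the costing unit is the month).
    category : str
        One of :data:`CATEGORIES`.
    sub_category : str
        Free-text label; never drives computation.
    amount_ngn : float
        Non-negative amount in naira.
    shared : bool
        True when the cost is shared across concurrent projects and must
        be apportioned.
    """

    month: pd.Period
    category: str
    sub_category: str
    amount_ngn: float
    shared: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "month", pd.Period(self.month, freq="M"))
        object.__setattr__(self, "category", normalize_category(self.category))
        if self.amount_ngn < 0:
            raise LedgerError(f"negative amount {self.amount_ngn} for {self.sub_category!r}")


@dataclass(frozen=True)
class FxRate:
    """Fixed NGN-per-USD exchange rate (default in the chain: 360)."""

    naira_per_usd: float

    def __post_init__(self) -> None:
        if not self.naira_per_usd > 0:
            raise LedgerError(f"exchange rate must be positive, got {self.naira_per_usd}")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category monthly costs in USD, with their total."""

    per_category: Mapping[str, float]
    total: float

    def rounded(self) -> dict[str, float]:
        """Whole-dollar display values, category order preserved."""
        out = {c: round_half_up(self.per_category[c]) for c in CATEGORIES}
        out["total"] = round_half_up(self.total)
        return out


def parse_ledger(source: str | IO[str]) -> list[ExpenseLineItem]:
    """Read a CSV expense ledger into line items, preserving row order.

    Parameters
    ----------
    source : path or text stream
        CSV with columns ``month`` (YYYY-MM), ``category``, ``sub_category``,
        ``amount_ngn`` and ``shared`` (true/false).

    Raises
    ------
    LedgerError
        On a missing column, a non-numeric or negative amount, or an
        unknown category label (naming the offending row).
    """
    frame = pd.read_csv(
        source,
        dtype={"sub_category": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in LEDGER_COLUMNS if c not in frame.columns]
    if missing:
        raise LedgerError(f"ledger is missing column(s): {', '.join(missing)}")

    items: list[ExpenseLineItem] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            amount = float(row.amount_ngn)
        except (TypeError, ValueError) as exc:
            raise LedgerError(f"row {idx}: non-numeric amount {row.amount_ngn!r}") from exc
        shared = str(row.shared).strip().lower() in {"true", "1", "yes"}
        try:
            items.append(
                ExpenseLineItem(
                    month=pd.Period(row.month, freq="M"),
                    category=str(row.category),
                    sub_category=str(row.sub_category),
                    amount_ngn=amount,
                    shared=shared,
                )
            )
        except LedgerError as exc:
            raise LedgerError(f"row {idx}: {exc}") from None
    return items


def write_ledger(items: Iterable[ExpenseLineItem], target: str | IO[str]) -> None:
    """Write line items back to the CSV ledger dialect (round-trips exactly)."""
    rows = list(items)
    frame = pd.DataFrame(
        {
            "month": [str(i.month) for i in rows],
            "category": [i.category for i in rows],
            "sub_category": [i.sub_category for i in rows],
            # shortest round-trip repr: pandas' default float formatting
            # caps at 15 significant digits and would lose precision
            "amount_ngn": [repr(float(i.amount_ngn)) for i in rows],
            "shared": [i.shared for i in rows],
        },
        columns=list(LEDGER_COLUMNS),
    )
    frame.to_csv(target, index=False)


def apportion_shared(item: ExpenseLineItem, n_active_projects: int) -> float:
    """Per-project NGN share of a line item.

    A shared item's cost is divided equally across the ``n_active_projects``
    concurrent projects; a non-shared item is attributed in full.
    """
    if n_active_projects < 1:
        raise LedgerError(f"n_active_projects must be >= 1, got {n_active_projects}")
    if item.shared:
        return item.amount_ngn / n_active_projects
    return item.amount_ngn


def convert_currency(amount_ngn: float, rate: FxRate) -> float:
    """Convert NGN to USD at ``rate`` (full precision retained)."""
    return amount_ngn / rate.naira_per_usd


def monthly_breakdown(
    items: Sequence[ExpenseLineItem],
    n_active_projects: int,
    rate: FxRate,
) -> CostBreakdown:
    """Aggregate one month's items into the per-category USD breakdown.

    Items are assumed to share the aggregation month (apply a month filter
    first otherwise). An empty input yields a breakdown of zeros.
    """
    sums = {c: 0.0 for c in CATEGORIES}
    for item in items:
        sums[item.category] += convert_currency(
            apportion_shared(item, n_active_projects), rate
        )
    return CostBreakdown(per_category=sums, total=sum(sums.values()))


def average_monthly_breakdown(
    items: Sequence[ExpenseLineItem],
    n_active_projects: int,
    rate: FxRate,
) -> CostBreakdown:
    """Average per-category monthly breakdown over the months present.

    Aggregates the whole ledger and divides by the number of distinct
    months, giving the representative monthly cost the chain consumes.
    An empty ledger yields zeros.
    """
    if not items:
        return monthly_breakdown(items, n_active_projects, rate)
    n_months = len({item.month for item in items})
    total = monthly_breakdown(items, n_active_projects, rate)
    per_cat = {c: v / n_months for c, v in total.per_category.items()}
    return CostBreakdown(per_category=per_cat, total=total.total / n_months)
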