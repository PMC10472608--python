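"""Synthetic expense-ledger and parameter-fixture generation.

Real expense reports for the program are not public, so testing the
ingestion path needs ledgers with the same shape: monthly NGN line items
across the four implementation-cost categories, some flagged as shared
across concurrent projects. :func:`generate_ledger` builds such a ledger
so that, after shared-cost apportionment and currency conversion, each
month's per-category USD sums hit a chosen target breakdown — exactly at
zero noise, in expectation otherwise. :func:`default_params` returns the
complete study parameter fixture.

Amounts within a category-month are split across items with a seeded
symmetric Dirichlet draw for realistic heterogeneity, with the last item
set by exact residual correction so the NGN sum is bit-exact at zero
noise. Noise, when requested, is multiplicative log-normal with mean 1
(keeps amounts positive and the aggregate unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .ledger import CATEGORIES, ExpenseLineItem

#: Representative sub-category labels per category, cycled across items.
SUB_CATEGORIES: Mapping[str, tuple[str, ...]] = {
    "personnel": (
        "Drivers",
        "Delivery Coordinator",
        "Program Manager",
        "Project Manager",
        "Finance support staff",
        "GIS support",
        "Software support staff",
        "Fringe",
    ),
    "vaccine_transportation": (
        "Fueling",
        "Servicing and repairs",
        "Vehicle license",
        "Training for drivers",
        "Vehicle insurance",
        "Insurance",
    ),
    "software_support": ("License and support",),
    "other": (
        "Office Rent",
        "Phone allowance for personnel",
        "Internet usage",
        "Laptop maintenance",
        "Tablet maintenance",
        "Office supplies",
        "Miscellaneous",
    ),
}

#: 2019 reference monthly USD breakdown used as the default target.
DEFAULT_TARGETS: dict[str, float] = {
    "personnel": 4891.0,
    "vaccine_transportation": 1628.0,
    "software_support": 2244.0,
    "other": 1792.0,
}


class SynthError(ValueError):
    """Raised when a ledger spec cannot be realized."""


def _default_months() -> tuple[pd.Period, ...]:
    return tuple(pd.period_range("2015-07", "2018-12", freq="M"))


@dataclass(frozen=True)
class LedgerSpec:
    """Recipe for a synthetic expense ledger.

    ``target_breakdown`` is the per-category USD/month aggregate the
    ledger should reproduce after apportionment and conversion. Shared
    categories have their NGN amounts pre-inflated by ``n_projects`` so
    that apportionment recovers the target.
    """

    target_breakdown: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    months: Sequence[pd.Period] = field(default_factory=_default_months)
    items_per_category_month: int = 3
    noise_sd: float = 0.0
    shared_categories: frozenset[str] = frozenset({"other"})
    fx_naira_per_usd: float = 360.0
    n_projects: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, target in self.target_breakdown.items():
            if cat not in CATEGORIES:
                raise SynthError(f"unknown category {cat!r} in target breakdown")
            if target < 0:
                raise SynthError(f"target for {cat!r} must be non-negative, got {target}")
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be non-negative")
        if self.items_per_category_month < 1 and any(
            v > 0 for v in self.target_breakdown.values()
        ):
            raise SynthError("cannot split a positive target across zero items")


def generate_ledger(spec: LedgerSpec) -> list[ExpenseLineItem]:
    """Generate a synthetic ledger realizing ``spec``.

    Deterministic for a fixed seed: identical specs yield identical
    ledgers item for item.
    """
    rng = np.random.default_rng(spec.seed)
    items: list[ExpenseLineItem] = []
    n = spec.items_per_category_month
    for month in spec.months:
        for cat in CATEGORIES:
            target_usd = spec.target_breakdown.get(cat, 0.0)
            shared = cat in spec.shared_categories
            scale = spec.n_projects if shared else 1
            ngn_total = target_usd * spec.fx_naira_per_usd * scale
            if n < 1:
                continue
            weights = rng.dirichlet(np.full(n, 5.0))
            amounts = weights * ngn_total
            # residual correction: make the NGN sum bit-exact at zero noise
            amounts[-1] = ngn_total - float(amounts[:-1].sum())
            if spec.noise_sd > 0:
                sigma = spec.noise_sd
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
                amounts = amounts * noise
            labels = SUB_CATEGORIES[cat]
            for j, amount in enumerate(amounts):
                items.append(
                    ExpenseLineItem(
                        month=month,
                        category=cat,
                        sub_category=labels[j % len(labels)],
                        amount_ngn=float(amount),
                        shared=shared,
                    )
                )
    return items


def default_params() -> AnalysisConfig:
    """The complete study parameter fixture.

    Feeding this through the pipeline in paper mode reproduces every
    headline figure of the chain (10,555 monthly; 0.102 uptake increase;
    26,373 additional children; 20.56 per child; 24,983 per stockout
    point).
    """
    return AnalysisConfig()
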