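"""Ledger parsing, shared-cost apportionment, conversion, aggregation."""

import io
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunocost.ledger import (
    CATEGORIES,
    CostBreakdown,
    ExpenseLineItem,
    FxRate,
    LedgerError,
    apportion_shared,
    convert_currency,
    monthly_breakdown,
    normalize_category,
    parse_ledger,
)

CSV_HEADER = "month,category,sub_category,amount_ngn,shared\n"


def item(category="personnel", amount=1000.0, shared=False, month="2019-01"):
    return ExpenseLineItem(
        month=month, category=category, sub_category="x", amount_ngn=amount, shared=shared
    )


amounts = st.floats(min_value=0.01, max_value=1e9, allow_nan=False, allow_infinity=False)


class TestParse:
    def test_identity_parse_preserves_rows_and_order(self):
        csv = CSV_HEADER + "".join(
            f"2019-0{i + 1},{cat},sub{i},{100.5 * (i + 1)},false\n"
            for i, cat in enumerate(CATEGORIES)
        )
        items = parse_ledger(io.StringIO(csv))
        assert [i.category for i in items] == list(CATEGORIES)
        assert [i.amount_ngn for i in items] == [100.5, 201.0, 301.5, 402.0]

    def test_header_only_gives_empty_sequence(self):
        assert parse_ledger(io.StringIO(CSV_HEADER)) == []

    def test_category_labels_normalized_case_and_space_insensitive(self):
        csv = CSV_HEADER + "2019-01, Vaccine Transportation ,fuel,10,true\n"
        (parsed,) = parse_ledger(io.StringIO(csv))
        assert parsed.category == "vaccine_transportation"
        assert parsed.shared is True

    def test_unknown_category_rejected_naming_row(self):
        csv = CSV_HEADER + "2019-01,personnel,a,10,false\n2019-01,catering,b,10,false\n"
        with pytest.raises(LedgerError, match="row 1.*catering"):
            parse_ledger(io.StringIO(csv))

    def test_negative_amount_rejected(self):
        csv = CSV_HEADER + "2019-01,other,rent,-5,false\n"
        with pytest.raises(LedgerError, match="row 0.*negative"):
            parse_ledger(io.StringIO(csv))

    def test_missing_column_rejected_naming_column(self):
        csv = "month,category,sub_category,shared\n2019-01,other,rent,false\n"
        with pytest.raises(LedgerError, match="amount_ngn"):
            parse_ledger(io.StringIO(csv))

    def test_day_level_dates_truncate_to_month(self):
        assert item(month="2019-03-15").month == item(month="2019-03").month

    def test_unknown_label_raises(self):
        with pytest.raises(LedgerError, match="unknown category"):
            normalize_category("catering")


class TestApportion:
    def test_non_shared_item_passes_through(self):
        assert apportion_shared(item(amount=1000.0), 14) == 1000.0

    def test_shared_item_split_across_projects(self):
        # 14 concurrent projects each carry 1/14 of a shared cost
        assert apportion_shared(item(amount=14_000.0, shared=True), 14) == 1000.0

    def test_invalid_project_count_rejected(self):
        with pytest.raises(LedgerError):
            apportion_shared(item(), 0)

    @given(amount=amounts, n=st.integers(min_value=1, max_value=60))
    def test_apportionment_conserves_money(self, amount, n):
        share = apportion_shared(item(amount=amount, shared=True), n)
        assert math.isclose(share * n, amount, rel_tol=1e-12)


class TestConvert:
    @pytest.mark.parametrize(
        "ngn,rate,usd", [(360.0, 360.0, 1.0), (0.0, 360.0, 0.0), (3_600_000.0, 360.0, 10_000.0)]
    )
    def test_conversion_examples(self, ngn, rate, usd):
        assert convert_currency(ngn, FxRate(rate)) == usd

    def test_non_positive_rate_rejected(self):
        with pytest.raises(LedgerError):
            FxRate(0.0)

    @given(a=amounts, b=amounts, k=st.floats(min_value=0.01, max_value=100))
    def test_conversion_is_linear(self, a, b, k):
        rate = FxRate(360.0)
        assert math.isclose(
            convert_currency(a + b, rate),
            convert_currency(a, rate) + convert_currency(b, rate),
            rel_tol=1e-12,
        )
        assert math.isclose(
            convert_currency(k * a, rate), k * convert_currency(a, rate), rel_tol=1e-12
        )


class TestBreakdown:
    def test_reference_category_sums(self):
        # per-category targets in USD, realized as single NGN items at 360/USD
        targets = {
            "personnel": 4891.0,
            "vaccine_transportation": 1628.0,
            "software_support": 2244.0,
            "other": 1792.0,
        }
        items = [item(category=c, amount=usd * 360.0) for c, usd in targets.items()]
        bd = monthly_breakdown(items, 14, FxRate(360.0))
        assert bd.rounded() == {**targets, "total": 10_555.0}

    def test_empty_ledger_gives_zeros(self):
        bd = monthly_breakdown([], 14, FxRate(360.0))
        assert bd.total == 0.0
        assert all(v == 0.0 for v in bd.per_category.values())

    def test_total_invariant_violation_detected_by_rounded(self):
        # CostBreakdown carries total alongside per-category sums
        bd = CostBreakdown(per_category={c: 1.0 for c in CATEGORIES}, total=4.0)
        assert bd.rounded()["total"] == 4.0

    @given(
        data=st.lists(
            st.tuples(st.sampled_from(CATEGORIES), amounts, st.booleans()),
            min_size=0,
            max_size=20,
        )
    )
    def test_breakdown_additive_and_permutation_invariant(self, data):
        items = [item(category=c, amount=a, shared=s) for c, a, s in data]
        rate = FxRate(360.0)
        whole = monthly_breakdown(items, 14, rate)
        assert math.isclose(whole.total, sum(whole.per_category.values()), rel_tol=1e-12)
        # permutation invariance
        rev = monthly_breakdown(items[::-1], 14, rate)
        for c in CATEGORIES:
            assert math.isclose(
                whole.per_category[c], rev.per_category[c], rel_tol=1e-12, abs_tol=1e-9
            )
        # concatenation equals category-wise sum of halves
        half = len(items) // 2
        first = monthly_breakdown(items[:half], 14, rate)
        second = monthly_breakdown(items[half:], 14, rate)
        for c in CATEGORIES:
            assert math.isclose(
                whole.per_category[c],
                first.per_category[c] + second.per_category[c],
                rel_tol=1e-12,
                abs_tol=1e-9,
            )
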