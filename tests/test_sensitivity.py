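"""One-way (tornado) and probabilistic sensitivity analyses."""

import pytest

from immunocost.rounding import round_half_up
from immunocost.sensitivity import (
    ParamSpec,
    SensitivityError,
    one_way,
    probabilistic,
)


def degenerate(name, value):
    return ParamSpec(name=name, base=value, low=value, high=value)


class TestOneWay:
    def test_degenerate_range_returns_base_case(self, study_config):
        spec = degenerate("population.coverage", 0.808)
        res = one_way(study_config, [spec])
        row = res.per_parameter["population.coverage"]
        assert row.at_low == row.at_base == row.at_high == res.base_value
        assert round_half_up(res.base_value, 2) == 20.56

    def test_total_cost_plus_minus_ten_percent(self, study_config):
        spec = ParamSpec(
            name="total_cost_override",
            base=542_132.0,
            low=542_132.0 * 0.9,
            high=542_132.0 * 1.1,
        )
        row = one_way(study_config, [spec]).per_parameter["total_cost_override"]
        assert round_half_up(row.at_low, 2) == 18.50
        assert round_half_up(row.at_base, 2) == 20.56
        assert round_half_up(row.at_high, 2) == 22.61

    def test_lower_coverage_raises_cost_per_child(self, study_config):
        spec = ParamSpec(name="population.coverage", base=0.808, low=0.5, high=1.0)
        row = one_way(study_config, [spec]).per_parameter["population.coverage"]
        assert row.at_low > row.at_high

    def test_unknown_parameter_rejected_by_name(self, study_config):
        with pytest.raises(SensitivityError, match="population.doses_per_lga"):
            one_way(study_config, [degenerate("population.doses_per_lga", 1.0)])

    def test_order_invariance(self, study_config):
        specs = [
            ParamSpec(name="population.coverage", base=0.808, low=0.6, high=0.9),
            ParamSpec(name="impact.stockout_after", base=0.172, low=0.1, high=0.3),
        ]
        fwd = one_way(study_config, specs)
        rev = one_way(study_config, specs[::-1])
        assert fwd.per_parameter == rev.per_parameter

    def test_wider_range_widens_tornado_bar(self, study_config):
        narrow = ParamSpec(name="population.coverage", base=0.808, low=0.7, high=0.9)
        wide = ParamSpec(name="population.coverage", base=0.808, low=0.6, high=1.0)
        r_narrow = one_way(study_config, [narrow]).per_parameter["population.coverage"]
        r_wide = one_way(study_config, [wide]).per_parameter["population.coverage"]
        assert r_wide.range >= r_narrow.range

    def test_tornado_ordering_by_range(self, study_config):
        specs = [
            ParamSpec(name="population.coverage", base=0.808, low=0.79, high=0.82),
            ParamSpec(
                name="total_cost_override", base=542_132.0, low=400_000.0, high=700_000.0
            ),
        ]
        res = one_way(study_config, specs)
        assert res.tornado_order()[0] == "total_cost_override"

    def test_invalid_range_rejected(self):
        with pytest.raises(SensitivityError, match="low <= base <= high"):
            ParamSpec(name="x", base=1.0, low=2.0, high=3.0)


class TestProbabilistic:
    def test_degenerate_distributions_collapse_to_base_case(self, study_config):
        specs = [
            ParamSpec(
                name="impact.stockout_after",
                base=0.172,
                low=0.172,
                high=0.172,
                distribution={"kind": "uniform"},
            )
        ]
        res = probabilistic(study_config, specs, n_draws=50, seed=1)
        s = res.psa_summary
        # mean of identical draws differs from the base case only by
        # floating summation, never by model discreteness
        assert s.mean == pytest.approx(res.base_value, rel=1e-14)
        assert s.p2_5 == s.p97_5 == pytest.approx(s.mean, rel=1e-14)

    def test_same_seed_gives_identical_summary(self, study_config):
        specs = [
            ParamSpec(
                name="impact.stockout_after",
                base=0.172,
                low=0.14,
                high=0.21,
                distribution={"kind": "uniform"},
            )
        ]
        a = probabilistic(study_config, specs, n_draws=200, seed=7)
        b = probabilistic(study_config, specs, n_draws=200, seed=7)
        assert a.psa_summary == b.psa_summary

    def test_uniform_band_mean_near_base(self, study_config):
        # symmetric +/-20% band around the after-rate: mean cost per child
        # should land within 2% of the exact-mode base case
        specs = [
            ParamSpec(
                name="impact.stockout_after",
                base=0.172,
                low=0.172 * 0.8,
                high=0.172 * 1.2,
                distribution={"kind": "uniform"},
            )
        ]
        res = probabilistic(study_config, specs, n_draws=10_000, seed=3)
        assert res.psa_summary.mean == pytest.approx(res.base_value, rel=0.02)
        assert res.psa_summary.p2_5 < res.psa_summary.mean < res.psa_summary.p97_5

    @pytest.mark.parametrize(
        "distribution",
        [
            {"kind": "triangular"},
            {"kind": "normal", "sd": 0.01},
        ],
    )
    def test_other_distributions_sample_within_bounds(self, study_config, distribution):
        specs = [
            ParamSpec(
                name="impact.stockout_after",
                base=0.172,
                low=0.1,
                high=0.25,
                distribution=distribution,
            )
        ]
        res = probabilistic(study_config, specs, n_draws=100, seed=2)
        assert res.psa_summary.p2_5 <= res.psa_summary.p97_5

    def test_missing_distribution_rejected(self, study_config):
        spec = ParamSpec(name="impact.stockout_after", base=0.172, low=0.1, high=0.25)
        with pytest.raises(SensitivityError, match="requires a distribution"):
            probabilistic(study_config, [spec], n_draws=5, seed=0)

    def test_invalid_normal_sd_rejected(self, study_config):
        spec = ParamSpec(
            name="impact.stockout_after",
            base=0.172,
            low=0.1,
            high=0.25,
            distribution={"kind": "normal", "sd": 0.0},
        )
        with pytest.raises(SensitivityError, match="sd > 0"):
            probabilistic(study_config, [spec], n_draws=5, seed=0)

    def test_unknown_distribution_kind_rejected(self, study_config):
        spec = ParamSpec(
            name="impact.stockout_after",
            base=0.172,
            low=0.1,
            high=0.25,
            distribution={"kind": "beta"},
        )
        with pytest.raises(SensitivityError, match="unknown distribution"):
            probabilistic(study_config, [spec], n_draws=5, seed=0)
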