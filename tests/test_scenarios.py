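"""Adoption sweeps, one-way sensitivity, break-even pricing, projection."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy.optimize import brentq

from pdcba import (
    adoption_sweep,
    ai_scan_volume,
    break_even_ai_cost,
    evaluate_scenario,
    linear_ramp,
    logistic_ramp,
    one_way_sensitivity,
    project_long_term,
)

from _strategies import parameter_sets


class TestAdoptionSweep:
    def test_published_net_benefit_columns(self, korea_unrounded, usa):
        kr = adoption_sweep(korea_unrounded, [0.3, 0.65, 1.0])
        us = adoption_sweep(usa, [0.3, 0.65, 1.0])
        for r, expected in zip(kr, (9_290_818, 20_130_105, 30_969_392)):
            assert r.net_benefit == pytest.approx(expected, rel=3e-4)
        for r, expected in zip(us, (75_957_548, 164_574_686, 253_191_825)):
            assert r.net_benefit == pytest.approx(expected, rel=1e-6)

    def test_zero_adoption_zero_net(self, korea):
        (r,) = adoption_sweep(korea, [0.0])
        assert r.net_benefit == 0.0

    def test_linearity_ratio(self, korea_unrounded):
        r30, r65 = adoption_sweep(korea_unrounded, [0.3, 0.65])
        assert r65.net_benefit / r30.net_benefit == pytest.approx(65 / 30, rel=1e-12)

    def test_empty_rates_rejected(self, korea):
        with pytest.raises(ValueError, match="non-empty"):
            adoption_sweep(korea, [])


class TestOneWaySensitivity:
    def test_unaffordability_endpoints(self, korea_unrounded):
        """Published endpoints: 10.90M (117.3% of base) and 5.53M (59.5%)."""
        curve = one_way_sensitivity(korea_unrounded, "pet_unaffordable", [0.0, 1.0])
        assert curve.net_benefit[0] / 1e6 == pytest.approx(10.90, abs=0.005)
        assert curve.net_benefit[1] / 1e6 == pytest.approx(5.53, abs=0.005)
        # the recomputed base carries ~0.03% input-rounding drift, so the
        # ratios are checked to one part in a thousand
        assert curve.ratio_pct[0] == pytest.approx(117.3, abs=0.1)
        assert curve.ratio_pct[1] == pytest.approx(59.5, abs=0.1)

    def test_net_decreasing_in_ai_price(self, korea):
        curve = one_way_sensitivity(korea, "cost_ai", [0.0, 50.0, 100.0, 500.0])
        assert all(b < a for a, b in zip(curve.net_benefit, curve.net_benefit[1:]))

    def test_midpoint_collinearity(self, korea_unrounded):
        curve = one_way_sensitivity(korea_unrounded, "pet_unaffordable", [0.0, 0.5, 1.0])
        lo, mid, hi = curve.net_benefit
        assert mid == pytest.approx((lo + hi) / 2, rel=1e-12)

    @given(params=parameter_sets())
    def test_affine_in_u_changes_sign_at_most_once(self, params):
        grid = [i / 10 for i in range(11)]
        curve = one_way_sensitivity(params, "pet_unaffordable", grid)
        signs = [n > 0 for n in curve.net_benefit if n != 0]
        flips = sum(a != b for a, b in zip(signs, signs[1:]))
        assert flips <= 1

    def test_bad_field_rejected(self, korea):
        with pytest.raises(ValueError, match="unknown parameter"):
            one_way_sensitivity(korea, "nonexistent", [0.0, 1.0])
        with pytest.raises(ValueError, match="not numeric"):
            one_way_sensitivity(korea, "label", [0.0, 1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            one_way_sensitivity(korea, "pet_unaffordable", [1.0, 0.0])


class TestBreakEven:
    def test_usa_published_break_even(self, usa):
        cstar = break_even_ai_cost(usa)
        assert cstar == pytest.approx(1506.6, abs=0.1)
        net_at_root = evaluate_scenario(usa.replace(cost_ai=cstar)).net_benefit
        base = evaluate_scenario(usa)
        assert abs(net_at_root) <= 1e-9 * (base.total_benefit + base.total_cost)

    def test_bisection_oracle(self, usa):
        cstar = break_even_ai_cost(usa)

        def net(c):
            return evaluate_scenario(usa.replace(cost_ai=c)).net_benefit

        root = brentq(net, 0.0, 10 * cstar, xtol=1e-9)
        assert root == pytest.approx(cstar, rel=1e-9)

    def test_already_at_break_even(self, usa):
        cstar = break_even_ai_cost(usa)
        assert break_even_ai_cost(usa.replace(cost_ai=cstar)) == pytest.approx(
            cstar, rel=1e-9
        )

    def test_no_ai_usage_undefined(self, korea):
        assert math.isnan(break_even_ai_cost(korea.replace(ai_adoption=0.0)))

    def test_scan_volume_equals_adopted_cohort(self, korea):
        assert ai_scan_volume(korea) == pytest.approx(
            korea.n_total * korea.ai_adoption, rel=1e-12
        )

    @given(params=parameter_sets())
    def test_root_property(self, params):
        """net(cost_ai = c*) vanishes for random valid parameter sets."""
        assume(params.ai_adoption > 1e-3)
        cstar = break_even_ai_cost(params)
        if cstar < 0:  # economically meaningless but algebraically valid root
            return
        r = evaluate_scenario(params.replace(cost_ai=cstar))
        scale = r.total_benefit + r.total_cost + 1.0
        assert abs(r.net_benefit) <= 1e-9 * scale


class TestProjection:
    def test_stationary_inputs(self, korea):
        """Flat ramp + constant cohort: annual constant, cumulative linear."""
        flat = lambda k: korea.ai_adoption
        series = project_long_term(korea, 2025, 2050, adoption_ramp=flat)
        annual = series.annual_net
        assert all(v == pytest.approx(annual[0], rel=1e-12) for v in annual)
        assert series.cumulative_net[-1] == pytest.approx(26 * annual[0], rel=1e-9)

    def test_cumulative_is_prefix_sum(self, korea_unrounded):
        series = project_long_term(korea_unrounded, 2025, 2050)
        running = 0.0
        for annual, cumulative in zip(series.annual_net, series.cumulative_net):
            running += annual
            assert cumulative == pytest.approx(running, rel=1e-12)

    def test_annual_nets_match_independent_yearly_runs(self, korea_unrounded):
        series = project_long_term(korea_unrounded, 2025, 2050)
        ramp = linear_ramp(korea_unrounded.ai_adoption)
        for k, net in enumerate(series.annual_net):
            expected = evaluate_scenario(
                korea_unrounded.replace(ai_adoption=ramp(k))
            ).net_benefit
            assert net == pytest.approx(expected, rel=1e-12)

    def test_homogeneous_in_cohort_growth(self, korea):
        base = project_long_term(korea, 2025, 2035, cohort_growth=lambda k: 1.0)
        doubled = project_long_term(korea, 2025, 2035, cohort_growth=lambda k: 2.0)
        for b, d in zip(base.annual_net, doubled.annual_net):
            assert d == pytest.approx(2 * b, rel=1e-12)

    def test_default_ramp_reaches_ceiling(self, korea):
        series = project_long_term(korea, 2025, 2050)
        assert series.adoption[0] == korea.ai_adoption
        assert series.adoption[10] == pytest.approx(0.8)
        assert all(a == pytest.approx(0.8) for a in series.adoption[10:])

    def test_discounting_shrinks_later_years(self, korea):
        flat = lambda k: korea.ai_adoption
        undiscounted = project_long_term(korea, 2025, 2035, adoption_ramp=flat)
        discounted = project_long_term(
            korea, 2025, 2035, adoption_ramp=flat, discount_rate=0.03
        )
        assert discounted.annual_net[0] == pytest.approx(undiscounted.annual_net[0])
        assert discounted.annual_net[5] == pytest.approx(
            undiscounted.annual_net[5] / 1.03**5, rel=1e-12
        )

    def test_logistic_ramp_anchored_and_bounded(self, korea):
        ramp = logistic_ramp(korea.ai_adoption, ceiling=0.8, midpoint_year=5.0)
        assert ramp(0) == pytest.approx(korea.ai_adoption)
        values = [ramp(k) for k in range(30)]
        assert all(korea.ai_adoption - 1e-9 <= v <= 0.8 + 1e-9 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_invalid_inputs_rejected(self, korea):
        with pytest.raises(ValueError, match="start_year"):
            project_long_term(korea, 2050, 2025)
        with pytest.raises(ValueError, match="outside"):
            project_long_term(korea, 2025, 2030, adoption_ramp=lambda k: 1.5)
        with pytest.raises(ValueError, match="non-positive"):
            project_long_term(korea, 2025, 2030, cohort_growth=lambda k: 0.0)
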