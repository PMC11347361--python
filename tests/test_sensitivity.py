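import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biasbound.meta import MetaResult
from biasbound.sensitivity import (
    ConfounderScenario,
    analyse_scenario,
    bounding_curve,
    bounding_factor,
    evalue_ci,
    evalue_point,
    invert_evalue,
    proportion_explained,
    required_complementary_rr,
)


def _meta(rr, lo, hi):
    return MetaResult(
        k=5,
        pooled_log_rr=math.log(rr),
        se_pooled=0.02,
        ci_lower=lo,
        ci_upper=hi,
        tau2=0.0,
        q_stat=0.0,
        i2=0.0,
    )


class TestEValue:
    @pytest.mark.parametrize(
        "rr, expected_2dp",
        [(1.14, 1.54), (1.10, 1.43), (1.41, 2.17), (1.0, 1.0), (1.12, 1.49)],
    )
    def test_point_values(self, rr, expected_2dp):
        assert round(evalue_point(rr), 2) == expected_2dp

    def test_protective_estimate_uses_reciprocal(self):
        assert evalue_point(0.5) == pytest.approx(evalue_point(2.0), rel=1e-12)

    def test_non_positive_rr_rejected(self):
        with pytest.raises(ValueError):
            evalue_point(0.0)

    def test_invert_closed_form(self):
        assert invert_evalue(2.0) == pytest.approx(4.0 / 3.0, rel=1e-12)
        assert invert_evalue(1.0) == 1.0
        assert invert_evalue(1.55) == pytest.approx(1.55**2 / 2.10, rel=1e-12)

    def test_invert_rejects_below_one(self):
        with pytest.raises(ValueError):
            invert_evalue(0.9)

    @given(st.floats(0.05, 20.0))
    @settings(max_examples=200, derandomize=True)
    def test_invert_is_left_inverse_after_orientation(self, rr):
        oriented = rr if rr >= 1 else 1 / rr
        assert invert_evalue(evalue_point(rr)) == pytest.approx(oriented, abs=1e-12, rel=1e-12)

    def test_ci_evalue_uses_null_side_limit(self):
        assert round(evalue_ci(1.14, 1.10, 1.19), 2) == 1.43
        assert evalue_ci(1.14, 0.95, 1.30) == 1.0
        assert evalue_ci(0.80, 0.70, 0.91) == pytest.approx(evalue_point(1 / 0.91), rel=1e-12)

    def test_ci_evalue_rejects_inconsistent_ordering(self):
        with pytest.raises(ValueError):
            evalue_ci(1.14, 1.20, 1.19)


class TestBoundingFactor:
    def test_depression_scenario_value(self):
        assert round(bounding_factor(1.48, 1.39), 2) == 1.10

    def test_worked_example_value(self):
        assert bounding_factor(3.00, 1.60) == pytest.approx(4.0 / 3.0, rel=1e-9)

    def test_null_axis_gives_unit_bound(self):
        for x in (1.0, 1.5, 4.0):
            assert bounding_factor(1.0, x) == 1.0

    def test_pre_orientation_required(self):
        with pytest.raises(ValueError):
            bounding_factor(0.9, 1.5)

    @given(st.floats(1.0, 10.0), st.floats(1.0, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_bounded_by_min(self, a, b):
        assert bounding_factor(a, b) == pytest.approx(bounding_factor(b, a), rel=1e-12)
        assert bounding_factor(a, b) <= min(a, b) + 1e-12

    def test_strictly_increasing_in_each_argument(self):
        grid = np.linspace(1.01, 5.0, 20)
        vals = [bounding_factor(a, 2.0) for a in grid]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    @pytest.mark.parametrize("rr", np.linspace(1.05, 5.0, 25).tolist())
    def test_evalue_bounding_identity(self, rr):
        """B(E, E) = RR when E is the E-value of RR."""
        e = evalue_point(rr)
        assert bounding_factor(e, e) == pytest.approx(rr, abs=1e-9)


class TestProportionExplained:
    def test_depression_proportions(self):
        b = bounding_factor(1.48, 1.39)
        assert proportion_explained(1.14, b) == pytest.approx(71.5, abs=0.01)
        assert proportion_explained(1.10, b) == 100.0  # capped

    def test_null_bound_explains_nothing(self):
        assert proportion_explained(1.5, 1.0) == 0.0

    def test_null_observed_rr_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="nothing to explain"):
            assert proportion_explained(1.0, 1.2) == 0.0

    def test_monotone_in_b_and_exact_at_total_confounding(self):
        bs = np.linspace(1.0, 1.14, 10)
        props = [proportion_explained(1.14, b) for b in bs]
        assert all(x <= y for x, y in zip(props, props[1:]))
        assert proportion_explained(1.14, 1.14) == 100.0


class TestRequiredComplementaryRr:
    def test_worked_example_closed_form(self):
        assert required_complementary_rr(3.00, 4.0 / 3.0) == pytest.approx(1.60, abs=1e-12)

    def test_overeating_closed_form(self):
        assert required_complementary_rr(1.49, 1.14) == pytest.approx(
            1.14 * 0.49 / 0.35, rel=1e-12
        )
        assert round(required_complementary_rr(1.49, 1.14), 2) == 1.60

    def test_unattainable_below_target(self):
        assert required_complementary_rr(1.10, 1.14) is None

    def test_target_at_or_below_null_rejected(self):
        with pytest.raises(ValueError):
            required_complementary_rr(2.0, 1.0)

    @given(st.floats(1.2, 10.0), st.floats(1.01, 5.0))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_through_bounding_factor(self, a, t):
        x = required_complementary_rr(a, t)
        if x is not None:
            assert bounding_factor(a, x) == pytest.approx(t, abs=1e-9)


class TestAnalyseScenario:
    def test_depression_scenario_against_pooled_estimate(self):
        res = analyse_scenario(
            ConfounderScenario("depression", rr_eu=1.39, rr_ud=1.48),
            _meta(1.14, 1.10, 1.19),
        )
        assert round(res.b, 2) == 1.10
        assert res.proportion_explained_point == pytest.approx(71.5, abs=0.01)
        assert res.proportion_explained_lower_ci == 100.0
        assert not res.fully_explains_point
        assert res.fully_explains_lower_ci

    def test_null_scenario_explains_nothing(self):
        res = analyse_scenario(
            ConfounderScenario("null", rr_eu=1.0, rr_ud=1.0), _meta(1.14, 1.10, 1.19)
        )
        assert res.b == 1.0
        assert res.proportion_explained_point == 0.0
        assert not res.fully_explains_point
        assert not res.fully_explains_lower_ci

    def test_food_insecurity_scenario(self):
        res = analyse_scenario(
            ConfounderScenario("food_insecurity", rr_eu=1.60, rr_ud=1.42),
            _meta(1.14, 1.10, 1.19),
        )
        assert res.b == pytest.approx(1.1248, abs=5e-5)
        assert res.proportion_explained_point == pytest.approx(89.1, abs=0.5)
        assert res.proportion_explained_lower_ci == 100.0

    def test_null_pooled_estimate_warns(self):
        with pytest.warns(UserWarning):
            res = analyse_scenario(
                ConfounderScenario("depression", rr_eu=1.39, rr_ud=1.48),
                _meta(0.98, 0.90, 1.07),
            )
        assert res.proportion_explained_point == 0.0

    def test_scenario_orientation_enforced(self):
        with pytest.raises(ValueError):
            ConfounderScenario("bad", rr_eu=0.8, rr_ud=1.5)


class TestBoundingCurve:
    def test_contour_satisfies_definition_everywhere(self):
        crv = bounding_curve(4.0 / 3.0)
        assert len(crv.points) >= 200
        for ud, eu in crv.points:
            assert abs(bounding_factor(ud, eu) - crv.target_b) < 1e-9

    def test_symmetric_point_at_rr_ud_two_for_target_four_thirds(self):
        eu = required_complementary_rr(2.0, 4.0 / 3.0)
        assert eu == pytest.approx(2.0, rel=1e-12)

    def test_contour_contains_evalue_marker(self):
        """The B=1.14 contour passes through (E, E) with E the E-value
        of 1.14, the marker annotated on published contour plots."""
        crv = bounding_curve(1.14)
        marker = min(crv.points, key=lambda p: abs(p[0] - p[1]))
        e = evalue_point(1.14)
        assert marker[0] == pytest.approx(e, abs=1e-9)
        assert marker[1] == pytest.approx(e, abs=1e-9)
        assert e == pytest.approx(1.55, abs=0.02)

    def test_monotone_decreasing_rr_eu(self):
        crv = bounding_curve(1.5, n_points=50)
        eus = [eu for _, eu in crv.points]
        assert all(x > y for x, y in zip(eus, eus[1:]))

    @pytest.mark.parametrize("target, rr_ud_max", [(1.0, 5.0), (1.5, 1.4)])
    def test_invalid_configurations_rejected(self, target, rr_ud_max):
        with pytest.raises(ValueError):
            bounding_curve(target, rr_ud_max=rr_ud_max)
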