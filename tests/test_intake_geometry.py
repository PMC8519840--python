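"""Rail geometry, rule projections, array fitting and slope tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrigeo.intake_geometry import (
    IntakeTarget,
    NutrientPoint,
    Rail,
    classify_rule,
    fit_intake_array,
    project_closest,
    project_equal_distance,
    project_no_interaction,
    project_rule,
    rail_from_diet,
    slope_test,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


def brute_force_closest(T, rail, n=1_000_001):
    """Dense grid minimizer of Euclidean distance over the rail parameter."""
    uu = rail.u_aa**2 + rail.u_c**2
    s_opt = (T.aa * rail.u_aa + T.c * rail.u_c) / uu
    s_max = 4 * s_opt + 1.0
    s = np.linspace(0.0, s_max, n)
    d2 = (s * rail.u_aa - T.aa) ** 2 + (s * rail.u_c - T.c) ** 2
    return float(s[np.argmin(d2)]), s_max


class TestRails:
    def test_sucrose_only_rail_is_c_axis(self, panel_by_id):
        rail = rail_from_diet(panel_by_id["0:1"])
        assert (rail.u_aa, rail.u_c) == (0.0, 0.5)

    def test_one_to_ten_rail_direction(self, panel_by_id):
        rail = rail_from_diet(panel_by_id["1:10"])
        assert (rail.u_aa, rail.u_c) == pytest.approx((0.05, 0.5))
        assert rail.contains(NutrientPoint(0.05, 0.5))
        assert not rail.contains(NutrientPoint(0.05, 0.6))

    def test_degenerate_rail_rejected(self):
        with pytest.raises(ValueError):
            Rail("bad", 0.0, 0.0)


class TestNoInteraction:
    def test_regulate_c(self):
        p = project_no_interaction(IntakeTarget(2, 2), Rail("r", 1, 2), "c")
        assert (p.aa, p.c) == pytest.approx((1.0, 2.0))

    def test_target_on_rail_returned_for_either_nutrient(self):
        T, rail = IntakeTarget(1, 2), Rail("r", 1, 2)
        for reg in ("aa", "c"):
            p = project_no_interaction(T, rail, reg)
            assert (p.aa, p.c) == pytest.approx((1.0, 2.0))

    def test_unreachable_regulation_is_undefined_not_error(self):
        assert project_no_interaction(IntakeTarget(1, 3), Rail("0:1", 0, 0.5), "aa") is None


class TestEqualDistance:
    def test_balance_example(self):
        p = project_equal_distance(IntakeTarget(2, 2), Rail("r", 1, 2))
        assert (p.aa, p.c) == pytest.approx((4 / 3, 8 / 3))
        assert (2 - p.aa) == pytest.approx(p.c - 2)  # deficit equals surplus

    def test_symmetric_rail_closed_form(self):
        p = project_equal_distance(IntakeTarget(1, 3), Rail("r", 1, 1))
        assert (p.aa, p.c) == pytest.approx((2.0, 2.0))

    def test_target_on_rail_is_fixed_point(self):
        p = project_equal_distance(IntakeTarget(1, 2), Rail("r", 1, 2))
        assert (p.aa, p.c) == pytest.approx((1.0, 2.0))

    @settings(derandomize=True, deadline=None)
    @given(positive, positive, positive, positive)
    def test_deficit_surplus_balance_and_on_rail(self, ta, tc, ua, uc):
        T, rail = IntakeTarget(ta, tc), Rail("r", ua, uc)
        p = project_equal_distance(T, rail)
        scale = max(abs(ta), abs(tc), abs(p.aa), abs(p.c), 1.0)
        assert (T.aa - p.aa) == pytest.approx(p.c - T.c, abs=1e-9 * scale)
        assert abs(p.aa * rail.u_c - p.c * rail.u_aa) <= 1e-9 * scale * max(ua, uc)


class TestClosestDistance:
    def test_orthogonal_projection_example(self):
        p = project_closest(IntakeTarget(2, 2), Rail("r", 1, 2))
        assert (p.aa, p.c) == pytest.approx((1.2, 2.4))

    def test_axis_rail(self):
        p = project_closest(IntakeTarget(1, 3), Rail("0:1", 0, 0.5))
        assert (p.aa, p.c) == pytest.approx((0.0, 3.0))

    def test_target_on_rail_is_fixed_point(self):
        p = project_closest(IntakeTarget(1, 2), Rail("r", 1, 2))
        assert (p.aa, p.c) == pytest.approx((1.0, 2.0))

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            T = IntakeTarget(*rng.uniform(0.1, 10, size=2))
            rail = Rail("r", *rng.uniform(0.01, 5, size=2))
            p = project_closest(T, rail)
            s_hat = p.c / rail.u_c
            s_grid, s_max = brute_force_closest(T, rail, n=100_001)
            assert abs(s_hat - s_grid) <= 1e-4 * s_max

    @settings(derandomize=True, deadline=None)
    @given(positive, positive, positive, positive)
    def test_distance_ordering_across_rules(self, ta, tc, ua, uc):
        """closest <= equal-distance <= worst defined no-interaction point."""
        T, rail = IntakeTarget(ta, tc), Rail("r", ua, uc)
        t = np.array([ta, tc])

        def dist(p):
            return np.hypot(p.aa - ta, p.c - tc)

        d_closest = dist(project_closest(T, rail))
        d_equal = dist(project_equal_distance(T, rail))
        d_ni = max(
            dist(project_no_interaction(T, rail, "aa")),
            dist(project_no_interaction(T, rail, "c")),
        )
        assert d_closest <= d_equal + 1e-9 * max(1, d_equal)
        assert d_equal <= d_ni + 1e-9 * max(1, d_ni)


class TestFitIntakeArray:
    def test_collinear_negative_slope(self):
        arr = fit_intake_array([NutrientPoint(0, 2), NutrientPoint(1, 1), NutrientPoint(2, 0)])
        assert arr.slope == pytest.approx(-1.0)
        assert arr.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        arr = fit_intake_array([NutrientPoint(0, 1), NutrientPoint(1, 3), NutrientPoint(2, 2)])
        assert arr.slope == pytest.approx(0.5)
        assert arr.intercept == pytest.approx(1.5)
        assert arr.slope_se == pytest.approx(np.sqrt(3) / 2, abs=1e-9)

    def test_identity_line(self):
        arr = fit_intake_array([NutrientPoint(0, 0), NutrientPoint(1, 1), NutrientPoint(2, 2)])
        assert arr.slope == pytest.approx(1.0)

    def test_vertical_array_rejected(self):
        with pytest.raises(ValueError, match="undefined slope"):
            fit_intake_array([NutrientPoint(1, 0), NutrientPoint(1, 1), NutrientPoint(1, 2)])


class TestSlopeTest:
    def test_seven_diet_degrees_of_freedom_and_t(self):
        res = slope_test(-0.127, 1.05, 0.0, 7)
        assert res.df == 5
        assert res.t_stat == pytest.approx(-0.127 / 1.05)
        assert 0 < res.p_two_tailed <= 1

    def test_slope_equal_to_hypothesis(self):
        res = slope_test(-1.0, 0.5, -1.0, 7)
        assert res.t_stat == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_formula_value_for_unit_offset(self):
        res = slope_test(-1.68, 1.05, -1.0, 7)
        assert res.t_stat == pytest.approx(-0.68 / 1.05)

    def test_exact_fit_branches(self):
        assert slope_test(-1.0, 0.0, -1.0, 7).p_two_tailed == 1.0
        res = slope_test(-1.0, 0.0, 0.0, 7)
        assert res.p_two_tailed == 0.0 and res.exact_fit

    @settings(derandomize=True, deadline=None)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 5), st.integers(3, 12))
    def test_antisymmetry_in_slope_exchange(self, ba, bh, se, n):
        a = slope_test(ba, se, bh, n)
        b = slope_test(bh, se, ba, n)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)


def _means_frame(rails, points):
    return pd.DataFrame(
        {
            "diet_id": [r.diet_id for r in rails],
            "mean_aa_mmol": [p.aa for p in points],
            "se_aa": 0.0,
            "mean_c_mmol": [p.c for p in points],
            "se_c": 0.0,
        }
    )


class TestClassifyRule:
    def test_equal_distance_round_trip(self, rails):
        T = IntakeTarget(1.0, 4.0)
        points = [project_equal_distance(T, r) for r in rails]
        ranking = classify_rule(_means_frame(rails, points), rails)
        best = ranking[0]
        assert best.rule == "equal_distance"
        assert best.sse == pytest.approx(0.0, abs=1e-12)
        # the equal-distance target is identified only through its sum
        assert best.estimated_target.aa + best.estimated_target.c == pytest.approx(5.0, rel=1e-4)
        assert all(best.sse <= r.sse for r in ranking)

    def test_no_interaction_c_round_trip(self, rails):
        T = IntakeTarget(0.02, 3.0)
        points = [project_rule("no_interaction_c", T, r) for r in rails]
        frame = _means_frame(rails, points)
        ranking = classify_rule(frame, rails)
        assert ranking[0].rule == "no_interaction_c"
        assert ranking[0].estimated_target.c == pytest.approx(3.0, rel=1e-4)
        arr = fit_intake_array(frame)
        assert arr.slope == pytest.approx(0.0, abs=1e-12)

    def test_closest_distance_round_trip_identifies_target(self, rails):
        T = IntakeTarget(0.025, 3.0)
        points = [project_closest(T, r) for r in rails]
        ranking = classify_rule(_means_frame(rails, points), rails)
        assert ranking[0].rule == "closest_distance"
        assert ranking[0].estimated_target.aa == pytest.approx(T.aa, rel=1e-2)
        assert ranking[0].estimated_target.c == pytest.approx(T.c, rel=1e-3)

    def test_predictions_lie_on_rails(self, rails):
        T = IntakeTarget(0.02, 2.0)
        points = [project_closest(T, r) for r in rails]
        for result in classify_rule(_means_frame(rails, points), rails):
            for rail in rails:
                if rail.diet_id in result.predicted:
                    assert rail.contains(result.predicted[rail.diet_id], tol=1e-9)

    def test_duplicate_rails_rejected(self, rails):
        T = IntakeTarget(0.02, 2.0)
        points = [project_closest(T, r) for r in rails]
        with pytest.raises(ValueError, match="duplicate"):
            classify_rule(_means_frame(rails, points), list(rails) + [rails[0]])

    def test_no_interaction_aa_excludes_axis_rail(self, rails):
        T = IntakeTarget(0.02, 2.0)
        points = [project_closest(T, r) for r in rails]
        ranking = classify_rule(_means_frame(rails, points), rails)
        by_rule = {r.rule: r for r in ranking}
        assert "0:1" not in by_rule["no_interaction_aa"].predicted
        assert by_rule["no_interaction_aa"].n_rails_used == len(rails) - 1
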