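"""Unit and property tests for the generic Mamdani engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzpk import (ConfigurationError, FISOptions, FuzzyRule, LinguisticVariable,
                    MamdaniFIS, MembershipFunction, NoRuleFired,
                    defuzz_center_average, defuzz_centroid, fuzzify, mf_eval,
                    rule_strength)

import _oracle


def _var(fis, name):
    return next(v for v in fis.inputs if v.name == name)


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("shape,params,x,expected", [
    ("trapezoidal", (670, 670, 670.3, 672.5), 670.3, 1.0),   # plateau endpoint
    ("trapezoidal", (670, 670, 670.3, 672.5), 670.0, 1.0),   # zero-width rise
    ("triangular", (670, 672.5, 675), 670.5, 0.2),           # rising edge
    ("trapezoidal", (670, 670, 670.3, 672.5), 670.5, (672.5 - 670.5) / (672.5 - 670.3)),
    ("triangular", (670, 672.5, 675), 672.5, 1.0),           # apex
    ("triangular", (670, 672.5, 675), 676.0, 0.0),           # outside support
    ("triangular", (670, 672.5, 675), 669.0, 0.0),
])
def test_mf_eval_piecewise_values(shape, params, x, expected):
    mf = MembershipFunction(shape, params)
    assert mf_eval(mf, x) == pytest.approx(expected, abs=1e-12)


def test_mf_open_shoulders_saturate_beyond_peaks():
    mf = MembershipFunction("trapezoidal", (691, 695, 695, 698), open_right=True)
    assert mf_eval(mf, 707.5) == 1.0
    assert mf_eval(mf, 696.0) == 1.0  # open shoulder overrides the falling edge
    left = MembershipFunction("trapezoidal", (676.6, 679.6, 680.4, 683.4), open_left=True)
    assert mf_eval(left, 600.0) == 1.0


@pytest.mark.parametrize("shape,params", [
    ("triangular", (1.0, 0.5, 2.0)),       # non-monotone breakpoints
    ("trapezoidal", (0, 2, 1, 3)),
    ("triangular", (0, 1, 2, 3)),          # wrong arity
    ("trapezoidal", (0, 1, 2)),
    ("gaussian", (0, 1)),                  # unknown shape
])
def test_mf_construction_rejects_invalid_configuration(shape, params):
    with pytest.raises(ConfigurationError):
        MembershipFunction(shape, params)


def test_mf_eval_requires_finite_input():
    mf = MembershipFunction("triangular", (0, 1, 2))
    with pytest.raises(ValueError):
        mf_eval(mf, float("nan"))


@settings(max_examples=200, derandomize=True)
@given(
    pts=st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=4),
    x=st.floats(-150, 150, allow_nan=False),
)
def test_mf_eval_bounded_and_plateau_exact(pts, x):
    """Degrees stay in [0,1] for any valid breakpoints; the plateau is exactly 1."""
    a, b, c, d = sorted(pts)
    mf = MembershipFunction("trapezoidal", (a, b, c, d))
    mu = mf_eval(mf, x)
    assert 0.0 <= mu <= 1.0
    if b <= x <= c:
        assert mu == 1.0
    if (x < a or x > d):
        assert mu == 0.0


def test_mf_eval_is_continuous_and_piecewise_linear():
    """Midpoint of each linear segment equals the mean of its endpoints."""
    mf = MembershipFunction("trapezoidal", (1.0, 3.0, 5.0, 9.0))
    for lo, hi in [(1, 3), (3, 5), (5, 9)]:
        mid = (lo + hi) / 2
        assert mf_eval(mf, mid) == pytest.approx(
            0.5 * (mf_eval(mf, lo) + mf_eval(mf, hi)), abs=1e-12)
    # continuity at breakpoints
    for bp in (1.0, 3.0, 5.0, 9.0):
        assert mf_eval(mf, bp - 1e-9) == pytest.approx(mf_eval(mf, bp + 1e-9), abs=1e-6)


# ---------------------------------------------------------------------------
# Fuzzification
# ---------------------------------------------------------------------------

def test_fuzzify_midpoint_splits_between_adjacent_terms(reference_fis):
    degrees = fuzzify(_var(reference_fis, "AIC"), 673.75)
    assert degrees["Low"] == pytest.approx(0.5)
    assert degrees["Medium"] == pytest.approx(0.5)
    assert all(degrees[t] == 0.0 for t in ("Very Low", "High", "Very High"))


def test_fuzzify_left_edge_of_lowest_plateau(reference_fis):
    degrees = fuzzify(_var(reference_fis, "AIC"), 670.0)
    assert degrees["Very Low"] == 1.0
    assert degrees["Low"] == 0.0


def test_fuzzify_saturates_beyond_universe(reference_fis):
    degrees = fuzzify(_var(reference_fis, "CS"), 707.5, policy="saturate_extremes")
    assert degrees["Very High"] == 1.0
    assert sum(v for k, v in degrees.items() if k != "Very High") == 0.0


def test_fuzzify_clamp_policy_evaluates_printed_shapes(reference_fis):
    # clamped to the CS universe top (698) the printed Very High trapezoid is 0
    degrees = fuzzify(_var(reference_fis, "CS"), 707.5, policy="clamp_to_universe")
    assert all(v == 0.0 for v in degrees.values())


@settings(max_examples=300, derandomize=True)
@given(x=st.floats(-1e6, 1e6, allow_nan=False),
       var_name=st.sampled_from(["AIC", "CS", "MSE"]))
def test_saturating_fuzzification_covers_every_finite_input(reference_fis, x, var_name):
    degrees = fuzzify(_var(reference_fis, var_name), x, policy="saturate_extremes")
    assert max(degrees.values()) > 0.0


# ---------------------------------------------------------------------------
# Rule firing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("degrees,expected", [
    ((0.2, 0.4, 0.333), 0.2),
    ((0.0, 0.9, 1.0), 0.0),
    ((1.0, 1.0, 1.0), 1.0),
])
def test_rule_strength_is_min_of_antecedents(degrees, expected):
    rule = FuzzyRule.make({"A": "t", "B": "t", "C": "t"}, "out")
    fuzzified = {v: {"t": d} for v, d in zip("ABC", degrees)}
    assert rule_strength(rule, fuzzified) == expected


def test_rule_strength_missing_variable_is_an_error():
    rule = FuzzyRule.make({"A": "t", "B": "t"}, "out")
    with pytest.raises(ValueError, match="missing"):
        rule_strength(rule, {"A": {"t": 1.0}})


# ---------------------------------------------------------------------------
# Defuzzifiers
# ---------------------------------------------------------------------------

def _grid(lo=0.0, hi=100.0, n=10_001):
    return np.linspace(lo, hi, n)


def test_centroid_of_symmetric_triangle_is_its_apex():
    g = _grid()
    mu = MembershipFunction("triangular", (30, 50, 70))(g)
    assert defuzz_centroid(mu, g) == pytest.approx(50.0, abs=1e-9)


def test_centroid_of_two_equal_triangles_is_their_midpoint():
    g = _grid()
    mu = np.maximum(MembershipFunction("triangular", (20, 30, 40))(g),
                    MembershipFunction("triangular", (60, 70, 80))(g))
    assert defuzz_centroid(mu, g) == pytest.approx(50.0, abs=1e-9)


def test_centroid_of_right_weighted_trapezoid_exceeds_85():
    g = _grid()
    mf = MembershipFunction("trapezoidal", (70, 90, 100, 100))
    value = defuzz_centroid(mf(g), g)
    assert value > 85.0
    # agree with a fine-grid integration oracle
    fine = _oracle.ORACLE_GRID
    gf = np.linspace(0, 100, fine)
    muf = mf(gf)
    assert value == pytest.approx(float((gf * muf).sum() / muf.sum()), abs=1e-2)


def test_centroid_of_zero_profile_signals_no_rule_fired():
    g = _grid()
    with pytest.raises(NoRuleFired):
        defuzz_centroid(np.zeros_like(g), g)


def test_center_average_single_consequent_returns_its_center():
    mf = MembershipFunction("triangular", (50, 70, 90))
    assert defuzz_center_average([(mf, 0.6)], (0, 100)) == pytest.approx(70.0)


def test_center_average_equal_areas_balance_at_midpoint():
    m1 = MembershipFunction("triangular", (10, 20, 30))
    m2 = MembershipFunction("triangular", (70, 80, 90))
    assert defuzz_center_average([(m1, 1.0), (m2, 1.0)], (0, 100)) == pytest.approx(
        50.0, abs=1e-6)


def test_center_average_weights_centers_by_clipped_area():
    # centers 50 and 90 with areas 2 and 1 -> (50*2 + 90*1)/3
    m1 = MembershipFunction("triangular", (48, 50, 52))  # area 2 at full height
    m2 = MembershipFunction("triangular", (89, 90, 91))  # area 1 at full height
    value = defuzz_center_average([(m1, 1.0), (m2, 1.0)], (0, 100),
                                  grid_resolution=100_001)
    assert value == pytest.approx((50 * 2 + 90 * 1) / 3, abs=1e-3)


def test_center_average_all_zero_strengths_signal_no_rule_fired():
    mf = MembershipFunction("triangular", (0, 50, 100))
    with pytest.raises(NoRuleFired):
        defuzz_center_average([(mf, 0.0)], (0, 100))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def test_evaluate_fully_very_low_inputs_land_on_the_optimal_centroid(reference_fis):
    # all antecedents fire Very Low at full degree -> centroid of "Optimal"
    value = reference_fis.evaluate({"AIC": 670.0, "CS": 680.4, "MSE": 0.0936})
    oracle = _oracle.evaluate(reference_fis, {"AIC": 670.0, "CS": 680.4, "MSE": 0.0936})
    assert value == pytest.approx(oracle, abs=0.05)


def test_evaluate_matches_brute_force_oracle_on_random_sample(reference_fis):
    rng = np.random.default_rng(42)
    for _ in range(50):
        values = {"AIC": rng.uniform(670, 680), "CS": rng.uniform(676.6, 698),
                  "MSE": rng.uniform(0.092, 0.14)}
        assert reference_fis.evaluate(values) == pytest.approx(
            _oracle.evaluate(reference_fis, values), abs=0.1)


def test_evaluate_output_stays_within_output_universe(reference_fis):
    rng = np.random.default_rng(7)
    for _ in range(25):
        values = {"AIC": rng.uniform(600, 750), "CS": rng.uniform(600, 800),
                  "MSE": rng.uniform(0.0, 0.3)}
        assert 0.0 <= reference_fis.evaluate(values) <= 100.0


def test_centroid_converges_as_the_grid_refines(reference_fis):
    values = {"AIC": 677.0, "CS": 686.0, "MSE": 0.12}
    coarse = reference_fis.with_options(grid_resolution=10_001).evaluate(values)
    fine = reference_fis.with_options(grid_resolution=20_001).evaluate(values)
    assert abs(fine - coarse) < 1e-2


def test_evaluate_propagates_no_rule_fired(reference_fis):
    clamped = reference_fis.with_options(out_of_range="clamp_to_universe")
    # CS clamps to its universe floor where no printed term has support
    with pytest.raises(NoRuleFired):
        clamped.evaluate({"AIC": 675.0, "CS": 600.0, "MSE": 0.1})


# ---------------------------------------------------------------------------
# Surface
# ---------------------------------------------------------------------------

def test_surface_grid_is_row_major_over_evaluate(reference_fis):
    xs, ys, Z = reference_fis.surface("AIC", "CS", {"MSE": 0.1}, grid=2)
    assert Z.shape == (2, 2)
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            assert Z[i, j] == reference_fis.evaluate({"AIC": xv, "CS": yv, "MSE": 0.1})


def test_surface_low_cs_low_mse_at_low_aic_scores_well(reference_fis):
    # a Low-CS / Low-MSE candidate at a Low AIC slice is rated better than
    # the Acceptable midpoint
    value = reference_fis.evaluate({"AIC": 674.5, "CS": 684.0, "MSE": 0.1})
    assert value < 50.0


def test_single_rule_system_yields_a_constant_surface():
    term = MembershipFunction("triangular", (0, 50, 100))
    x = LinguisticVariable("x", (0, 1), {"any": MembershipFunction("trapezoidal", (0, 0, 1, 1))})
    y = LinguisticVariable("y", (0, 1), {"any": MembershipFunction("trapezoidal", (0, 0, 1, 1))})
    out = LinguisticVariable("out", (0, 100), {"mid": term})
    fis = MamdaniFIS([x, y], out, [FuzzyRule.make({"x": "any", "y": "any"}, "mid")])
    _, _, Z = fis.surface("x", "y", {}, grid=3)
    assert np.allclose(Z, Z[0, 0])


def test_surface_requires_two_distinct_free_variables(reference_fis):
    with pytest.raises(ValueError):
        reference_fis.surface("AIC", "AIC", {"CS": 690, "MSE": 0.1})
    with pytest.raises(ValueError):
        reference_fis.surface("AIC", "CS", {})  # MSE not fixed


# ---------------------------------------------------------------------------
# Configuration round-trip
# ---------------------------------------------------------------------------

def test_config_round_trip_is_lossless(reference_fis, tmp_path):
    path = tmp_path / "fis.yaml"
    reference_fis.save(path)
    loaded = MamdaniFIS.load(path)
    assert loaded.to_dict() == reference_fis.to_dict()
    assert loaded.config_hash() == reference_fis.config_hash()
    values = {"AIC": 674.2, "CS": 688.8, "MSE": 0.11}
    assert loaded.evaluate(values) == reference_fis.evaluate(values)


def test_rules_referencing_unknown_terms_are_rejected(reference_fis):
    bad = FuzzyRule.make({"AIC": "Nope", "CS": "Low", "MSE": "Low"}, "Optimal")
    with pytest.raises(ConfigurationError):
        MamdaniFIS(reference_fis.inputs, reference_fis.output, [bad])


def test_options_validation():
    with pytest.raises(ConfigurationError):
        FISOptions(defuzzifier="mean_of_maxima")
    with pytest.raises(ConfigurationError):
        FISOptions(out_of_range="wrap")
    with pytest.raises(ConfigurationError):
        FISOptions(grid_resolution=1)
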