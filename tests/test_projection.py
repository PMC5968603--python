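import numpy as np
import pandas as pd
import pytest

from plysim import (
    BenchmarkSet,
    Constraint,
    UpratingRule,
    apply_disease_trend,
    calibrate_weights,
    constraint_matrix,
    uprate_profile,
)
from plysim.projection import CalibrationError, InfeasibleConstraintsError


def greg_closed_form(d, X, T):
    """Independent oracle: unbounded chi-square calibration in one linear
    solve, w = d (1 + X lambda), lambda = (X'DX)^+ (T - X'd)."""
    M = X.T @ (d[:, None] * X)
    lam = np.linalg.pinv(M) @ (T - X.T @ d)
    return d * (1.0 + X @ lam)


def test_identity_calibration_returns_weights_unchanged():
    d = np.array([1.0, 2.0, 3.0])
    X = np.array([[1.0], [1.0], [1.0]])
    res = calibrate_weights(d, X, [6.0])
    np.testing.assert_array_equal(res.weights, d)
    assert res.iterations <= 1
    assert res.max_constraint_gap == 0.0


def test_single_total_constraint_scales_uniformly():
    """Doubling the single grand total doubles every weight (the
    chi-square solution with one total constraint is a uniform scaling)."""
    rng = np.random.default_rng(1)
    d = rng.uniform(0.5, 2.0, 50)
    X = np.ones((50, 1))
    res = calibrate_weights(d, X, [2.0 * d.sum()], bounds=None)
    np.testing.assert_allclose(res.weights, 2.0 * d, rtol=1e-12)


def test_three_records_two_overlapping_constraints_closed_form():
    d = np.array([1.0, 1.0, 1.0])
    X = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])  # total and a subgroup
    T = np.array([4.0, 1.5])
    res = calibrate_weights(d, X, T, bounds=None)
    np.testing.assert_allclose(res.weights, greg_closed_form(d, X, T), atol=1e-10)
    np.testing.assert_allclose(X.T @ res.weights, T, atol=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_small_unbounded_instances_match_closed_form(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    k = int(rng.integers(1, 4))
    d = rng.uniform(0.5, 3.0, n)
    X = rng.integers(0, 2, (n, k)).astype(float)
    X[:, 0] = 1.0
    T = X.T @ d * rng.uniform(0.8, 1.25, k)
    res = calibrate_weights(d, X, T, bounds=None)
    np.testing.assert_allclose(res.weights, greg_closed_form(d, X, T), atol=1e-10)


def test_bounds_are_respected_exactly_and_reported():
    rng = np.random.default_rng(3)
    n = 200
    d = rng.uniform(0.5, 2.0, n)
    cell = (rng.random(n) < 0.1).astype(float)
    X = np.column_stack([np.ones(n), cell])
    # demand a big increase in a small cell so some weights hit the cap
    T = np.array([d.sum() * 1.05, (cell * d).sum() * 2.8])
    res = calibrate_weights(d, X, T, bounds=(0.5, 3.0), tol=1e-6, max_iter=100)
    assert np.all(res.weights <= 3.0 * d + 1e-9)
    assert np.all(res.weights >= 0.5 * d - 1e-9)
    assert res.max_constraint_gap <= 1e-6


def test_infeasible_target_raises():
    d = np.ones(10)
    X = np.ones((10, 1))
    with pytest.raises(InfeasibleConstraintsError):
        calibrate_weights(d, X, [1000.0], bounds=(0.5, 2.0))


def test_solution_optimises_the_chisquare_distance():
    """Any feasible perturbation within the constraint null space must not
    reduce the chi-square objective (brute-force optimality check)."""
    rng = np.random.default_rng(4)
    n, k = 30, 3
    d = rng.uniform(0.5, 2.0, n)
    X = rng.integers(0, 2, (n, k)).astype(float)
    X[:, 0] = 1.0
    T = X.T @ d * rng.uniform(0.9, 1.15, k)
    res = calibrate_weights(d, X, T, bounds=None)
    obj = np.sum((res.weights - d) ** 2 / d)
    # null-space directions keep the constraints satisfied
    _, _, vt = np.linalg.svd(X.T)
    null = vt[k:]
    for _ in range(50):
        z = null.T @ rng.normal(size=n - k)
        perturbed = res.weights + 0.1 * z
        assert np.sum((perturbed - d) ** 2 / d) >= obj - 1e-10


def test_nonconvergence_carries_best_gap():
    # inconsistent constraints: same cell, two different targets
    d = np.ones(5)
    X = np.column_stack([np.ones(5), np.ones(5)])
    with pytest.raises(CalibrationError) as err:
        calibrate_weights(d, X, [5.0, 9.0], bounds=None)
    assert err.value.gap is not None and err.value.gap > 0


# --- uprating -------------------------------------------------------------


def _profile(earnings=100.0, other=20.0, welfare=311.67, tax=30.0):
    return pd.DataFrame(
        {
            "weekly_earnings": [earnings],
            "weekly_other_income": [other],
            "weekly_welfare": [welfare],
            "weekly_tax": [tax],
            "weekly_total_income": [earnings + other + welfare],
        }
    )


def test_uprating_base_year_is_identity():
    p = _profile()
    pd.testing.assert_frame_equal(uprate_profile(p, UpratingRule(), 2013), p)


def test_welfare_constant_in_real_terms():
    for year in (2015, 2020, 2025, 2030):
        up = uprate_profile(_profile(), UpratingRule(), year)
        assert up["weekly_welfare"].iloc[0] == 311.67


def test_two_years_of_one_percent_growth():
    up = uprate_profile(_profile(earnings=100.0, other=0.0, welfare=0.0), UpratingRule(), 2015)
    assert up["weekly_earnings"].iloc[0] == pytest.approx(102.01)


def test_uprating_composes_multiplicatively():
    p = _profile()
    via_2020 = uprate_profile(
        uprate_profile(p, UpratingRule(), 2020),
        UpratingRule(base_year=2020),
        2030,
    )
    direct = uprate_profile(p, UpratingRule(), 2030)
    pd.testing.assert_frame_equal(via_2020, direct)


def test_uprating_preserves_accounting_identity():
    up = uprate_profile(_profile(), UpratingRule(), 2030)
    assert up["weekly_total_income"].iloc[0] == pytest.approx(
        up[["weekly_earnings", "weekly_other_income", "weekly_welfare"]].iloc[0].sum()
    )


def test_uprating_rejects_past_years():
    with pytest.raises(ValueError):
        uprate_profile(_profile(), UpratingRule(), 2010)


# --- disease trend adjustment --------------------------------------------


def _bench():
    cons = [
        Constraint("group_FT_no_arth", {"group": "FT_no_arth"}, 500.0),
        Constraint("group_FT_arth", {"group": "FT_arth"}, 60.0),
        Constraint("group_NILF_arth", {"group": "NILF_arth"}, 40.0),
        Constraint("age45-49_female", {"age_group": "45-49", "sex": "female"}, 80.0),
    ]
    return BenchmarkSet(year=2020, population_total=600.0, constraints=cons, trend_multiplier=1.1)


def test_unit_multiplier_changes_nothing():
    b = _bench()
    out = apply_disease_trend(b, 1.0)
    assert [c.target for c in out.constraints] == [c.target for c in b.constraints]


def test_trend_scales_arthritis_and_conserves_total():
    b = _bench()
    out = apply_disease_trend(b, 1.1)
    targets = {c.name: c.target for c in out.constraints}
    assert targets["group_FT_arth"] == pytest.approx(66.0)
    assert targets["group_NILF_arth"] == pytest.approx(44.0)
    group_total = sum(t for n, t in targets.items() if n.startswith("group_"))
    assert group_total == pytest.approx(600.0)  # conserved to machine precision
    assert targets["age45-49_female"] == 80.0  # non-group constraints untouched


def test_trend_cannot_drive_cells_negative():
    with pytest.raises(ValueError):
        apply_disease_trend(_bench(), 7.0)


def test_constraint_matrix_unknown_column():
    df = pd.DataFrame({"group": ["FT_no_arth"]})
    with pytest.raises(KeyError):
        constraint_matrix(df, [Constraint("x", {"nope": 1}, 1.0)])
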