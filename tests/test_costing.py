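import numpy as np
import pandas as pd
import pytest

from plysim import (
    CounterfactualProbs,
    adjusted_median_difference,
    analysis_group,
    bootstrap_cis,
    estimate_counterfactual_probs,
    fit_median_model,
    flag_lost_ply,
    national_costs,
    percent_change,
    summarize_groups,
)
from plysim._stats import weighted_median
from plysim.costing import is_arthritis_code


# --- lost-PLY flag --------------------------------------------------------


@pytest.mark.parametrize(
    "status, code, expected",
    [
        ("NILF_ill_health", "M05", True),
        ("NILF_ill_health", "M19", True),
        ("NILF_ill_health", "M00", True),
        ("NILF_ill_health", "M20", False),  # just past the arthritis range
        ("NILF_ill_health", "M54", False),
        ("NILF_ill_health", "I21", False),
        ("FT", "M05", False),
        ("NILF_other", "M05", False),
        ("NILF_ill_health", "M05.3", True),  # four-character subdivision
    ],
)
def test_flag_lost_ply(status, code, expected):
    assert flag_lost_ply({"labour_force_status": status, "main_condition": code}) is expected


def test_malformed_icd_code_raises():
    with pytest.raises(ValueError):
        is_arthritis_code("arthritis")
    with pytest.raises(ValueError):
        is_arthritis_code("5M0")


def test_null_condition_is_not_arthritis():
    assert not is_arthritis_code(None)
    assert not flag_lost_ply({"labour_force_status": "NILF_ill_health", "main_condition": None})


# --- group summaries ------------------------------------------------------


def _toy_persons():
    rows = []
    spec = [
        ("FT", None, 1300.0, 0.0, 240.0, 2.0),
        ("FT", None, 1500.0, 0.0, 280.0, 1.0),
        ("FT", "M05", 1100.0, 0.0, 180.0, 1.0),
        ("PT", None, 600.0, 0.0, 20.0, 1.0),
        ("PT", "M16", 550.0, 0.0, 0.0, 1.0),
        ("NILF_ill_health", "M06", 320.0, 311.67, 0.0, 1.0),
    ]
    for i, (lfs, cond, inc, wel, tax, w) in enumerate(spec):
        rows.append(
            {
                "record_id": f"t{i}",
                "labour_force_status": lfs,
                "main_condition": cond,
                "age_group": "50-54",
                "sex": "female",
                "education": "degree+",
                "survey_weight": w,
                "weekly_total_income": inc,
                "weekly_welfare": wel,
                "weekly_tax": tax,
            }
        )
    return pd.DataFrame(rows)


def test_summarize_groups_weighted_medians():
    out = summarize_groups(_toy_persons(), 2015).set_index("group")
    # lower weighted median of (1300 w2, 1500 w1) is 1300
    assert out.loc["FT_no_arth", "income_median"] == 1300.0
    assert out.loc["NILF_arth", "welfare_median"] == 311.67
    assert out.loc["FT_no_arth", "weighted_count"] == 3.0
    assert out.loc["FT_no_arth", "share_pct"] == pytest.approx(3.0 / 7.0 * 100)


def test_summarize_empty_group_warns_not_crashes():
    df = _toy_persons()
    df = df[df["labour_force_status"] != "NILF_ill_health"]
    with pytest.warns(UserWarning, match="NILF_arth"):
        out = summarize_groups(df)
    row = out.set_index("group").loc["NILF_arth"]
    assert row["weighted_count"] == 0.0 and np.isnan(row["income_median"])


def test_group_counts_conserve_population(calibrated_2015):
    groups = analysis_group(calibrated_2015)
    total = calibrated_2015["survey_weight"].sum()
    assert total == pytest.approx(calibrated_2015.attrs["benchmark"].population_total, rel=1e-9)
    assert groups.isin(
        ["FT_no_arth", "FT_arth", "PT_no_arth", "PT_arth", "NILF_arth", "unemployed", "NILF_other", "NILF_ill_other"]
    ).all()


# --- adjusted median differences ------------------------------------------


def test_saturated_model_equals_weighted_median_differences(small_population):
    """With group indicators only, the regression contrasts must equal
    differences of within-group lower weighted medians."""
    fit = fit_median_model(small_population, "income", covariates=())
    groups = analysis_group(small_population)
    w = small_population["survey_weight"]
    y = small_population["weekly_total_income"]

    def med(g):
        m = (groups == g).to_numpy()
        return weighted_median(y[m], w[m])

    ref = med("FT_no_arth")
    for j, g in enumerate(("FT_arth", "PT_no_arth", "PT_arth", "NILF_arth")):
        assert fit.params[1 + j] == pytest.approx(med(g) - ref, abs=1e-8)


def test_adjusted_difference_table_shape_and_reference(small_population):
    out = adjusted_median_difference(small_population, "welfare", year=2015, reps=25, seed=1)
    ref = out[out["group"] == "FT_no_arth"].iloc[0]
    assert ref["estimate"] == 0.0
    assert (out["ci_low"] <= out["ci_high"]).all()
    nilf = out.set_index("group").loc["NILF_arth"]
    assert nilf["estimate"] == pytest.approx(311.67)
    assert bool(nilf["significant"])


def test_collinear_covariate_is_reported(small_population):
    df = small_population.copy()
    df["dup"] = df["sex"]
    with pytest.raises(ValueError, match="dup|sex"):
        fit_median_model(df, "income", covariates=("sex", "dup"))


def test_empty_reference_group_raises(small_population):
    df = small_population[analysis_group(small_population) != "FT_no_arth"]
    with pytest.raises(ValueError, match="reference"):
        fit_median_model(df, "income")


# --- counterfactual probabilities ----------------------------------------


def test_all_ft_world_gives_certain_ft_destination():
    df = _toy_persons()
    df.loc[df["labour_force_status"] == "PT", "labour_force_status"] = "FT"
    probs = estimate_counterfactual_probs(df)
    assert (probs.p_ft, probs.p_pt, probs.p_unemp) == (1.0, 0.0, 0.0)


def test_probabilities_sum_to_one_exactly(small_population):
    probs = estimate_counterfactual_probs(small_population, 2015)
    assert probs.p_ft + probs.p_pt + probs.p_unemp == 1.0
    assert 0 < probs.p_pt < probs.p_ft < 1


def test_default_run_destination_shares_near_anchor(calibrated_2015):
    probs = estimate_counterfactual_probs(calibrated_2015, 2015)
    assert probs.p_ft == pytest.approx(0.72, abs=0.02)
    assert probs.p_pt == pytest.approx(0.25, abs=0.02)


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError):
        CounterfactualProbs(2015, 1.2, -0.1, -0.1)


# --- national costs -------------------------------------------------------


def _lost_person(weight, income, welfare=311.67, tax=0.0):
    return pd.DataFrame(
        [
            {
                "labour_force_status": "NILF_ill_health",
                "main_condition": "M05",
                "age_group": "50-54",
                "sex": "female",
                "education": "degree+",
                "survey_weight": weight,
                "weekly_total_income": income,
                "weekly_welfare": welfare,
                "weekly_tax": tax,
            }
        ]
    )


def test_single_person_hand_arithmetic():
    """One lost-PLY person, w=1000, certain full-time destination with
    counterfactual income 1308.88 vs actual 321.87: 1000 x 987.01 x 52."""
    person = _lost_person(1000.0, 321.87)
    probs = CounterfactualProbs(2015, 1.0, 0.0, 0.0)
    fits = _fits_with_flat_predictions(income_ft=1308.88)
    out = national_costs(person, probs, fits, 2015, covariates=())
    assert out["lost_income"] == pytest.approx(1000 * 987.01 * 52 / 1e6)
    assert out["lost_income"] == pytest.approx(51.32, abs=0.01)


def _fits_with_flat_predictions(income_ft=1308.88, income_pt=602.86, welfare_ft=0.0, tax_ft=243.18):
    from plysim.quantreg import QuantregFit

    names = ["intercept", "group[FT_arth]", "group[PT_no_arth]", "group[PT_arth]", "group[NILF_arth]"]
    inc = QuantregFit(np.array([income_ft, 0.0, income_pt - income_ft, 0.0, 0.0]), 0.5, names)
    wel = QuantregFit(np.array([welfare_ft, 0.0, 0.0, 0.0, 0.0]), 0.5, names)
    tax = QuantregFit(np.array([tax_ft, 0.0, 0.0, 0.0, 0.0]), 0.5, names)
    return {"income": inc, "welfare": wel, "tax": tax}


def test_counterfactual_equal_to_actual_gives_zero_loss():
    person = _lost_person(1000.0, 321.87)
    probs = CounterfactualProbs(2015, 0.7, 0.3, 0.0)
    fits = _fits_with_flat_predictions(income_ft=321.87, income_pt=321.87)
    out = national_costs(person, probs, fits, 2015, covariates=())
    assert out["lost_income"] == pytest.approx(0.0, abs=1e-12)


def test_unemployed_destination_contributes_no_earnings_gap():
    person = _lost_person(1000.0, 321.87, welfare=311.67)
    probs = CounterfactualProbs(2015, 0.0, 0.0, 1.0)
    fits = _fits_with_flat_predictions()
    out = national_costs(person, probs, fits, 2015, covariates=(), unemployment_benefit=255.0)
    assert out["lost_income"] == 0.0
    assert out["extra_welfare"] == pytest.approx(1000 * (311.67 - 255.0) * 52 / 1e6)


def test_lost_income_monotone_in_counterfactual_income():
    """Raising both counterfactual destinations by delta raises the national
    figure by exactly sum(w) x delta x 52 / 1e6."""
    person = pd.concat([_lost_person(700.0, 321.87), _lost_person(300.0, 400.0)], ignore_index=True)
    probs = CounterfactualProbs(2015, 0.7, 0.25, 0.05)
    base = national_costs(person, probs, _fits_with_flat_predictions(), 2015, covariates=())
    delta = 37.5
    shifted = _fits_with_flat_predictions(income_ft=1308.88 + delta, income_pt=602.86 + delta)
    out = national_costs(person, probs, shifted, 2015, covariates=())
    expected = base["lost_income"] + 1000.0 * (probs.p_ft + probs.p_pt) * delta * 52 / 1e6
    assert out["lost_income"] == pytest.approx(expected, rel=1e-12)


def test_no_lost_persons_gives_zero_costs():
    df = _toy_persons()
    df = df[df["labour_force_status"] != "NILF_ill_health"]
    out = national_costs(df, CounterfactualProbs(2015, 0.7, 0.3, 0.0), year=2015)
    assert out["lost_income"] == 0.0 and out["lost_workers"] == 0.0


# --- bootstrap and reporting arithmetic -----------------------------------


def test_bootstrap_constant_data_degenerate_interval():
    df = pd.DataFrame({"x": np.full(30, 4.2), "survey_weight": np.ones(30)})
    lo, hi = bootstrap_cis(df, lambda d: d["x"].mean(), reps=50, seed=0)
    assert lo == hi == pytest.approx(4.2)


def test_bootstrap_is_seed_deterministic():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"x": rng.normal(size=100)})
    a = bootstrap_cis(df, lambda d: d["x"].mean(), reps=80, seed=5)
    b = bootstrap_cis(df, lambda d: d["x"].mean(), reps=80, seed=5)
    assert a == b
    assert bootstrap_cis(df, lambda d: d["x"].mean(), reps=80, seed=6) != a


def test_bootstrap_rejects_no_replications():
    with pytest.raises(ValueError):
        bootstrap_cis(pd.DataFrame({"x": [1.0]}), lambda d: 0.0, reps=0)


@pytest.mark.parametrize(
    "v0, v1, expected",
    [
        (54_000, 61_000, 13),
        (1516, 2406, 59),
        (847, 959, 13),
        (352, 549, 56),
        (6208, 8191, 32),
        (100, 100, 0),
        (200, 201, 1),  # 0.5 rounds away from zero
        (200, 199, -1),
    ],
)
def test_percent_change(v0, v1, expected):
    assert percent_change(v0, v1) == expected


def test_percent_change_requires_positive_base():
    with pytest.raises(ValueError):
        percent_change(0, 10)
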