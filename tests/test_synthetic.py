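import numpy as np
import pandas as pd
import pytest

from plysim import GeneratorConfig, generate_benchmarks, generate_donor_pool, generate_population, generate_survey
from plysim._stats import weighted_median
from plysim.config import ConfigurationError, TaxSchedule
from plysim.synthetic import ECON_COLUMNS, MATCH_COLUMNS, PERSON_COLUMNS, injected_gap_config
from plysim import scenario


def test_same_seed_is_byte_identical(default_cfg):
    a = generate_population(default_cfg)
    b = generate_population(default_cfg)
    pd.testing.assert_frame_equal(a, b)


def test_zero_records_yields_empty_frame():
    df = generate_population(GeneratorConfig(n_records=0))
    assert len(df) == 0
    assert list(df.columns) == PERSON_COLUMNS + ECON_COLUMNS


def test_record_count_and_total_weight(population, default_cfg):
    assert len(population) == default_cfg.n_records
    assert population["survey_weight"].sum() == pytest.approx(default_cfg.weighted_population)
    assert (population["survey_weight"] > 0).all()


def test_weighted_group_shares_hit_targets(population, default_cfg):
    """Weighted shares per analysis group within 0.5 percentage points."""
    shares = population.groupby("group")["survey_weight"].sum() / population["survey_weight"].sum()
    for g, target in default_cfg.all_group_shares.items():
        assert abs(shares[g] - target) * 100 < 0.5


def test_nilf_arthritis_share_near_scenario(population):
    w = population["survey_weight"]
    share = w[population["group"] == "NILF_arth"].sum() / w.sum() * 100
    assert share == pytest.approx(0.91, abs=0.05)


def test_group_income_medians_match_targets(population, default_cfg):
    """Weighted median total income per group within 5% of its target."""
    for g, t in default_cfg.median_targets.items():
        m = population["group"] == g
        med = weighted_median(
            population.loc[m, "weekly_total_income"], population.loc[m, "survey_weight"]
        )
        assert med == pytest.approx(t["income"], rel=0.05)


def test_accounting_identity_exact(population):
    total = (
        population["weekly_earnings"]
        + population["weekly_other_income"]
        + population["weekly_welfare"]
    )
    np.testing.assert_array_equal(total.to_numpy(), population["weekly_total_income"].to_numpy())
    assert (population["weekly_welfare"] >= 0).all()


def test_structural_invariants(population):
    nilf_ill = population["labour_force_status"] == "NILF_ill_health"
    assert population.loc[nilf_ill, "main_condition"].notna().all()
    employed = population["labour_force_status"].isin(["FT", "PT"])
    assert population.loc[employed, "hours_band"].notna().all()
    assert population.loc[~employed, "hours_band"].isna().all()
    assert set(population["age_group"]) <= {"45-49", "50-54", "55-59", "60-64"}
    assert population["income_quintile"].between(1, 5).all()


def test_new_seed_changes_records_but_not_shares(default_cfg):
    import dataclasses

    other = dataclasses.replace(default_cfg, seed=default_cfg.seed + 1)
    a = generate_population(default_cfg)
    b = generate_population(other)
    assert not a["weekly_total_income"].equals(b["weekly_total_income"])
    sa = a.groupby("group")["survey_weight"].sum() / a["survey_weight"].sum()
    sb = b.groupby("group")["survey_weight"].sum() / b["survey_weight"].sum()
    assert (np.abs(sa - sb) * 100 < 0.5).all()


def test_invalid_configurations_raise():
    with pytest.raises(ConfigurationError):
        generate_population(GeneratorConfig(group_shares={"FT_no_arth": 0.9, "NILF_arth": 0.2}))
    with pytest.raises(ConfigurationError):
        generate_population(GeneratorConfig(n_records=3))  # fewer records than groups
    with pytest.raises(ConfigurationError):
        cfg = GeneratorConfig()
        cfg.median_targets["FT_no_arth"]["income"] = -1.0
        generate_population(cfg)


# --- donor pool -----------------------------------------------------------


def test_donor_pool_columns_and_dsp_profile(default_cfg):
    donors = generate_donor_pool(default_cfg)
    assert list(donors.columns) == MATCH_COLUMNS + ECON_COLUMNS
    assert donors[MATCH_COLUMNS].drop(columns="hours_band").notna().all().all()
    # an ill-health non-participant on the disability pension: flat rate, no tax
    m = (donors["labour_force_status"] == "NILF_ill_health") & donors["receives_dsp"]
    assert weighted_median(donors.loc[m, "weekly_welfare"], donors.loc[m, "survey_weight"] if "survey_weight" in donors else np.ones(m.sum())) == pytest.approx(311.67)
    assert (donors.loc[m, "weekly_tax"] < 5.0).mean() > 0.95


def test_tax_schedule_floor_and_identity():
    sched = TaxSchedule()
    # earnings below the tax-free threshold attract no tax
    assert sched.weekly_tax(np.array([200.0]))[0] == 0.0
    assert np.all(np.diff(sched.annual_tax(np.linspace(0, 3e5, 200))) >= 0)


def test_zero_earnings_zero_welfare_total_is_other_income(population):
    m = (population["weekly_earnings"] == 0) & (population["weekly_welfare"] == 0)
    assert m.any()
    np.testing.assert_allclose(
        population.loc[m, "weekly_total_income"], population.loc[m, "weekly_other_income"]
    )


# --- benchmarks -----------------------------------------------------------


def test_benchmark_population_paths(default_cfg):
    bench = generate_benchmarks(default_cfg, [2015, 2030])
    assert bench[2030].population_total == pytest.approx(7_130_000)
    assert bench[2015].population_total == pytest.approx(5_945_000)


def test_benchmark_cells_sum_to_population(default_cfg):
    bench = generate_benchmarks(default_cfg, list(scenario.YEARS))
    for year, b in bench.items():
        for block in ("group_", "age", "edu_"):
            total = sum(c.target for c in b.constraints if c.name.startswith(block))
            assert total == pytest.approx(b.population_total), (year, block)


def test_flat_growth_path_gives_identical_benchmarks(default_cfg):
    pops = {y: 5_945_000 for y in (2015, 2030)}
    shares = {y: scenario.GROUP_SHARES[2015] for y in (2015, 2030)}
    bench = generate_benchmarks(default_cfg, [2015, 2030], populations=pops, group_shares=shares)
    t15 = bench[2015].to_frame().drop(columns="year")
    t30 = bench[2030].to_frame().drop(columns="year")
    pd.testing.assert_frame_equal(t15, t30)
    assert bench[2030].trend_multiplier == 1.0


def test_unknown_year_raises(default_cfg):
    with pytest.raises(ConfigurationError):
        generate_benchmarks(default_cfg, [1999])


# --- injected-gap design --------------------------------------------------


def test_injected_gap_config_realises_exact_gaps():
    cfg = injected_gap_config(income_gap=700.0, welfare_gap=312.0, tax_gap=170.0, n_records=4000, seed=3)
    pop = generate_population(cfg)
    w = pop["survey_weight"]

    def med(col, g):
        m = pop["group"] == g
        return weighted_median(pop.loc[m, col], w[m])

    assert med("weekly_total_income", "FT_no_arth") - med("weekly_total_income", "NILF_arth") == pytest.approx(700.0, abs=1e-6)
    assert med("weekly_welfare", "NILF_arth") - med("weekly_welfare", "FT_no_arth") == pytest.approx(312.0)
    assert med("weekly_tax", "FT_no_arth") - med("weekly_tax", "NILF_arth") == pytest.approx(170.0, rel=0.02)
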