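"""Synthetic survey, donor-pool and benchmark generation.

Emulates the statistical structure of a pooled national disability survey
of 45-64 year olds together with a tax-transfer donor snapshot, so the
whole costing pipeline can be exercised without confidential microdata.

The generative model, per analysis group (labour-force status crossed with
arthritis as main condition):

* categorical covariates (age band, sex, education, income-unit type,
  home ownership, hours band) drawn from group-specific mixes;
* earnings for the employed are log-normal with group-specific spread and
  multiplicative education/age effects; the non-employed earn nothing;
* welfare follows flat status-based payment rules (disability-pension
  rate for ill-health non-participants, unemployment benefit for the
  unemployed, occasional family supplements for workers);
* other (investment-type) income is a zero-inflated log-normal;
* tax comes from a stylised annual schedule applied to annualised
  non-welfare income (or, optionally, is drawn around per-group target
  medians);
* after assembly each group's weighted median total income is anchored to
  its configured target by a small additive shift, so generated medians
  match targets essentially exactly at any sample size.

Survey weights are noisy around equal shares and scaled so each group's
weighted share matches its configured target and the grand total matches
the configured weighted population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import weighted_median, weighted_quintile_labels
from .config import ConfigurationError, GeneratorConfig
from .projection import BenchmarkSet, Constraint
from . import scenario

__all__ = [
    "generate_population",
    "generate_survey",
    "generate_donor_pool",
    "generate_benchmarks",
    "injected_gap_config",
    "PERSON_COLUMNS",
    "ECON_COLUMNS",
    "MATCH_COLUMNS",
]

ECON_COLUMNS = [
    "weekly_earnings",
    "weekly_other_income",
    "weekly_welfare",
    "weekly_tax",
    "weekly_total_income",
]

MATCH_COLUMNS = [
    "labour_force_status",
    "income_unit_type",
    "income_quintile",
    "receives_age_pension",
    "receives_dsp",
    "sex",
    "age_group",
    "hours_band",
    "education",
    "home_ownership",
]

PERSON_COLUMNS = [
    "record_id",
    "survey_year",
    "group",
    "age_group",
    "sex",
    "education",
    "income_unit_type",
    "home_ownership",
    "labour_force_status",
    "main_condition",
    "hours_band",
    "receives_age_pension",
    "receives_dsp",
    "income_quintile",
    "survey_weight",
]

_LF_STATUS = {
    "FT_no_arth": "FT",
    "FT_arth": "FT",
    "PT_no_arth": "PT",
    "PT_arth": "PT",
    "NILF_arth": "NILF_ill_health",
    "NILF_ill_other": "NILF_ill_health",
    "unemployed": "unemployed",
    "NILF_other": "NILF_other",
}

ARTHRITIS_CODES = ("M00", "M05", "M06", "M10", "M13", "M15", "M16", "M17", "M19")
OTHER_CONDITION_CODES = ("M54", "I21", "E11", "F32", "J44", "C50", "G35")

_INCOME_UNIT_TYPES = ("couple_no_dep", "couple_dep", "single_no_dep", "single_dep")
_INCOME_UNIT_P = (0.35, 0.30, 0.25, 0.10)

_OWNER_PROB = {
    "FT_no_arth": 0.78,
    "FT_arth": 0.75,
    "PT_no_arth": 0.72,
    "PT_arth": 0.70,
    "NILF_arth": 0.55,
    "NILF_ill_other": 0.55,
    "unemployed": 0.55,
    "NILF_other": 0.65,
}

_OTHER_INCOME_MEDIAN = {
    "FT_no_arth": 60.0,
    "FT_arth": 50.0,
    "PT_no_arth": 60.0,
    "PT_arth": 50.0,
    "NILF_arth": 15.0,
    "NILF_ill_other": 15.0,
    "unemployed": 30.0,
    "NILF_other": 80.0,
}

_FT_HOURS = ("35-44", "45+")
_PT_HOURS = ("1-15", "16-24", "25-34")


def _allocate_counts(n: int, shares: dict) -> dict:
    """Largest-remainder allocation; every positive-share group gets >= 1."""
    groups = [g for g in scenario.GROUPS if shares.get(g, 0.0) > 0]
    if n == 0:
        return {}
    if n < len(groups):
        raise ConfigurationError(f"n_records={n} cannot realise {len(groups)} groups")
    total = sum(shares[g] for g in groups)
    quota = {g: n * shares[g] / total for g in groups}
    counts = {g: int(np.floor(q)) for g, q in quota.items()}
    remainder = n - sum(counts.values())
    for g in sorted(groups, key=lambda g: quota[g] - counts[g], reverse=True)[:remainder]:
        counts[g] += 1
    for g in groups:  # guarantee representation
        if counts[g] == 0:
            donor = max(counts, key=counts.get)
            counts[donor] -= 1
            counts[g] = 1
    return counts


def _choice(rng, options, p, size):
    return np.asarray(options, dtype=object)[rng.choice(len(options), size=size, p=np.asarray(p) / np.sum(p))]


def _group_frame(cfg: GeneratorConfig, group: str, n: int, rng) -> pd.DataFrame:
    mixes = cfg.covariate_mixes
    edu_mix = mixes["education"][group]
    age_mix = mixes["age_group"][group]
    female = mixes["female_share"][group]
    status = _LF_STATUS[group]
    employed = status in ("FT", "PT")

    df = pd.DataFrame(index=range(n))
    df["group"] = group
    df["age_group"] = _choice(rng, list(age_mix), list(age_mix.values()), n)
    df["sex"] = np.where(rng.random(n) < female, "female", "male").astype(object)
    df["education"] = _choice(rng, list(edu_mix), list(edu_mix.values()), n)
    df["income_unit_type"] = _choice(rng, _INCOME_UNIT_TYPES, _INCOME_UNIT_P, n)
    df["home_ownership"] = np.where(rng.random(n) < _OWNER_PROB[group], "owner", "non-owner").astype(object)
    df["labour_force_status"] = status

    if status == "FT":
        df["hours_band"] = _choice(rng, _FT_HOURS, (0.7, 0.3), n)
    elif status == "PT":
        df["hours_band"] = _choice(rng, _PT_HOURS, (0.3, 0.35, 0.35), n)
    else:
        df["hours_band"] = None

    if group in ("FT_arth", "PT_arth", "NILF_arth"):
        df["main_condition"] = _choice(rng, ARTHRITIS_CODES, np.ones(len(ARTHRITIS_CODES)), n)
    elif group == "NILF_ill_other":
        df["main_condition"] = _choice(rng, OTHER_CONDITION_CODES, np.ones(len(OTHER_CONDITION_CODES)), n)
    else:
        cond = _choice(rng, OTHER_CONDITION_CODES, np.ones(len(OTHER_CONDITION_CODES)), n)
        cond[rng.random(n) >= 0.30] = None
        df["main_condition"] = cond

    # welfare by rules
    rules = cfg.welfare_rules
    welfare = np.zeros(n)
    dsp = np.zeros(n, dtype=bool)
    u = rng.random(n)
    if status == "NILF_ill_health":
        dsp = u < rules.dsp_prob_nilf_ill
        welfare[dsp] = rules.dsp_rate
        supp = (~dsp) & (u < rules.dsp_prob_nilf_ill + rules.supplement_prob_nilf_ill)
        welfare[supp] = rules.dsp_rate + rules.family_supplement * 0.5
    elif status == "unemployed":
        welfare[:] = rules.unemployment_benefit
    elif status == "NILF_other":
        dsp = u < rules.dsp_prob_nilf_other
        welfare[dsp] = rules.dsp_rate
        ben = (~dsp) & (u < rules.dsp_prob_nilf_other + rules.benefit_prob_nilf_other)
        welfare[ben] = rules.unemployment_benefit
    else:
        prob = rules.supplement_prob_ft if status == "FT" else rules.supplement_prob_pt
        supp = u < prob
        welfare[supp] = rules.family_supplement * rng.lognormal(0.0, 0.4, int(supp.sum()))
    df["receives_dsp"] = dsp

    old = (df["age_group"] == "60-64").to_numpy()
    ap_prob = np.where(old, 0.01 if employed else 0.15, 0.0 if employed else 0.02)
    df["receives_age_pension"] = rng.random(n) < ap_prob

    # earnings with multiplicative education/age effects
    target_income = cfg.median_targets[group]["income"]
    earnings = np.zeros(n)
    if employed:
        eff = cfg.covariate_log_effects
        log_eff = np.array([eff["education"][e] for e in df["education"]]) + np.array(
            [eff["age_group"][a] for a in df["age_group"]]
        )
        base = max(target_income - _OTHER_INCOME_MEDIAN[group] / 2.0, 50.0)
        sigma = cfg.income_dispersion[group]
        earnings = base * np.exp(log_eff + sigma * rng.standard_normal(n))
    df["weekly_earnings"] = earnings

    other = np.exp(np.log(_OTHER_INCOME_MEDIAN[group]) + cfg.other_income_sigma * rng.standard_normal(n))
    other[rng.random(n) < cfg.other_income_zero_prob] = 0.0
    df["weekly_other_income"] = other
    df["weekly_welfare"] = welfare
    return df


def generate_population(cfg: GeneratorConfig, seed=None, n_records=None) -> pd.DataFrame:
    """Draw a full synthetic population table including economic variables.

    This is the common mechanism behind :func:`generate_survey` (which
    drops the economic columns) and :func:`generate_donor_pool` (an
    independent draw keeping the matching variables and the profile).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_records if n_records is None else n_records
    counts = _allocate_counts(n, cfg.all_group_shares)
    if not counts:
        return pd.DataFrame(columns=PERSON_COLUMNS + ECON_COLUMNS)

    frames = [_group_frame(cfg, g, counts[g], rng) for g in counts]
    df = pd.concat(frames, ignore_index=True)

    # survey weights: noisy, scaled to exact group shares of the population
    d = cfg.weight_dispersion
    w = rng.uniform(1.0 - d, 1.0 + d, len(df))
    shares = cfg.all_group_shares
    total_share = sum(shares[g] for g in counts)
    for g in counts:
        m = (df["group"] == g).to_numpy()
        w[m] *= (shares[g] / total_share) * cfg.weighted_population / w[m].sum()
    df["survey_weight"] = w

    # anchor weighted median total income to the group targets
    if cfg.calibrate_medians:
        for g in counts:
            m = (df["group"] == g).to_numpy()
            target = cfg.median_targets[g]["income"]
            employed = _LF_STATUS[g] in ("FT", "PT")
            col = "weekly_earnings" if employed else "weekly_other_income"
            for _ in range(2):
                total = (
                    df.loc[m, "weekly_earnings"]
                    + df.loc[m, "weekly_other_income"]
                    + df.loc[m, "weekly_welfare"]
                ).to_numpy()
                delta = target - weighted_median(total, w[m])
                df.loc[m, col] = np.maximum(df.loc[m, col] + delta, 0.0)

    # tax
    taxable = df["weekly_earnings"] + df["weekly_other_income"]
    if cfg.tax_mode == "schedule":
        df["weekly_tax"] = cfg.tax_schedule.weekly_tax(taxable.to_numpy())
    elif cfg.tax_mode == "target":
        # tax as a progressive power function of taxable income, scaled so
        # each group's weighted median tax hits its target: monotone in
        # income like a schedule, but with the median exactly injectable
        tax = np.zeros(len(df))
        taxable_arr = taxable.to_numpy()
        for g in counts:
            target = cfg.median_targets[g]["tax"] or 0.0
            m = (df["group"] == g).to_numpy()
            if target <= 0:
                continue
            med_taxable = weighted_median(taxable_arr[m], w[m])
            tax[m] = target * (taxable_arr[m] / med_taxable) ** cfg.tax_elasticity
            if cfg.calibrate_medians:
                delta = target - weighted_median(tax[m], w[m])
                tax[m] = np.maximum(tax[m] + delta, 0.0)
        df["weekly_tax"] = tax
    else:
        raise ConfigurationError(f"unknown tax_mode {cfg.tax_mode!r}")

    df["weekly_total_income"] = (
        df["weekly_earnings"] + df["weekly_other_income"] + df["weekly_welfare"]
    )
    df["income_quintile"] = weighted_quintile_labels(
        df["weekly_total_income"].to_numpy(), df["survey_weight"].to_numpy()
    )

    # alternate survey years within each group for balanced pooling
    years = np.asarray(cfg.survey_years, dtype=np.int64)
    within = df.groupby("group").cumcount().to_numpy()
    df["survey_year"] = years[within % len(years)]

    df.insert(0, "record_id", [f"r{i:06d}" for i in range(len(df))])
    return df[PERSON_COLUMNS + ECON_COLUMNS]


def generate_survey(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the synthetic survey table (no economic columns).

    Income quintile and pension-receipt flags are retained: they are
    observed in the emulated survey and used as matching variables.
    """
    return generate_population(cfg, seed=cfg.seed)[PERSON_COLUMNS]


def generate_donor_pool(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the economic donor pool: matching variables plus profile.

    An independent draw from the same mechanism as the survey (different
    seed substream), with size ``n_records * donor_coverage``. Larger
    coverage raises the probability that every realised survey cell holds
    at least one donor.
    """
    if not cfg.tax_schedule.brackets:
        raise ConfigurationError("tax schedule has no brackets")
    n = int(round(cfg.n_records * cfg.donor_coverage))
    pop = generate_population(cfg, seed=np.random.SeedSequence([cfg.seed, 1]), n_records=n)
    return pop[MATCH_COLUMNS + ECON_COLUMNS].copy()


def generate_benchmarks(cfg: GeneratorConfig, years, populations=None, group_shares=None) -> dict:
    """Projection-year benchmark sets for the configured scenario.

    Per year: cell totals for age-band x sex and for every analysis group,
    plus marginals for education, home ownership and disability-pension
    receipt, all derived from the year's group shares and the generator's
    covariate mixes so that every block sums exactly to the year's
    population total. The arthritis trend multiplier is the year's
    arthritis prevalence relative to 2015.

    ``populations`` ({year: total}) and ``group_shares`` ({year: {group:
    share}}) override the default growth paths; a flat path (equal totals
    and shares each year) yields identical benchmarks across years.
    """
    cfg.validate()
    populations = scenario.POPULATION if populations is None else populations
    share_table = scenario.GROUP_SHARES if group_shares is None else group_shares
    base_pop = populations.get(2015, next(iter(populations.values())))
    out = {}
    for year in years:
        if year not in populations:
            raise ConfigurationError(f"no projection benchmarks defined for year {year}")
        pop = populations[year] * cfg.weighted_population / base_pop
        shares = share_table[year]
        # restrict to groups present in the configured design, renormalised
        active = {g: s for g, s in cfg.all_group_shares.items() if s > 0}
        year_shares = {g: shares[g] for g in active}
        norm = sum(year_shares.values())
        year_shares = {g: s / norm for g, s in year_shares.items()}

        cons = []
        mixes = cfg.covariate_mixes
        for age in ("45-49", "50-54", "55-59", "60-64"):
            for sex in ("female", "male"):
                p = sum(
                    year_shares[g]
                    * mixes["age_group"][g][age]
                    * (mixes["female_share"][g] if sex == "female" else 1 - mixes["female_share"][g])
                    for g in year_shares
                )
                cons.append(Constraint(f"age{age}_{sex}", {"age_group": age, "sex": sex}, pop * p))
        for g, s in year_shares.items():
            cons.append(Constraint(f"group_{g}", {"group": g}, pop * s))
        for edu in ("none-post-school", "certificate/diploma", "degree+"):
            p = sum(year_shares[g] * mixes["education"][g][edu] for g in year_shares)
            cons.append(Constraint(f"edu_{edu}", {"education": edu}, pop * p))
        p_own = sum(year_shares[g] * _OWNER_PROB[g] for g in year_shares)
        cons.append(Constraint("owner", {"home_ownership": "owner"}, pop * p_own))
        rules = cfg.welfare_rules
        dsp_prob = {
            "NILF_arth": rules.dsp_prob_nilf_ill,
            "NILF_ill_other": rules.dsp_prob_nilf_ill,
            "NILF_other": rules.dsp_prob_nilf_other,
        }
        p_dsp = sum(year_shares[g] * dsp_prob.get(g, 0.0) for g in year_shares)
        cons.append(Constraint("dsp", {"receives_dsp": True}, pop * p_dsp))

        def _arth_share(s):
            return sum(s.get(g, 0.0) for g in ("FT_arth", "PT_arth", "NILF_arth"))

        base_shares = share_table.get(2015, shares)
        out[year] = BenchmarkSet(
            year=year,
            population_total=pop,
            constraints=cons,
            trend_multiplier=_arth_share(shares) / _arth_share(base_shares)
            if _arth_share(base_shares) > 0
            else 1.0,
        )
    return out


def injected_gap_config(
    income_gap: float = 700.0,
    welfare_gap: float = 312.0,
    tax_gap: float = 170.0,
    n_records: int = 5000,
    reference_income: float = 1300.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Two-group design with known median gaps, for parameter recovery.

    Full-time workers without arthritis (reference) and ill-health
    non-participants with arthritis in equal shares, balanced covariate
    mixes, no covariate income effects, and exact injected gaps: the NILF
    group's median income sits ``income_gap`` below the reference, its
    welfare is a flat payment ``welfare_gap``, and taxes are drawn around
    medians ``tax_gap`` apart.
    """
    cfg = GeneratorConfig(
        n_records=n_records,
        group_shares={"FT_no_arth": 0.5, "NILF_arth": 0.5},
        tax_mode="target",
        seed=seed,
    )
    cfg.median_targets = {
        "FT_no_arth": {"income": reference_income, "welfare": 0.0, "tax": tax_gap},
        "NILF_arth": {"income": reference_income - income_gap, "welfare": welfare_gap, "tax": 0.0},
    }
    cfg.welfare_rules = type(cfg.welfare_rules)(
        dsp_rate=welfare_gap,
        dsp_prob_nilf_ill=1.0,
        supplement_prob_nilf_ill=0.0,
        supplement_prob_ft=0.0,
        supplement_prob_pt=0.0,
    )
    balanced_edu = {"none-post-school": 1 / 3, "certificate/diploma": 1 / 3, "degree+": 1 / 3}
    balanced_age = {"45-49": 0.25, "50-54": 0.25, "55-59": 0.25, "60-64": 0.25}
    for g in ("FT_no_arth", "NILF_arth"):
        cfg.covariate_mixes["education"][g] = dict(balanced_edu)
        cfg.covariate_mixes["age_group"][g] = dict(balanced_age)
        cfg.covariate_mixes["female_share"][g] = 0.5
    cfg.covariate_log_effects = {
        "education": {k: 0.0 for k in balanced_edu},
        "age_group": {k: 0.0 for k in balanced_age},
    }
    return cfg
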