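"""Lost productive life years: identification, group summaries, adjusted
median gaps and national indirect costs.

A person has lost a productive life year (PLY) to arthritis when they are
out of the labour force because of their own ill-health and their main
chronic condition is arthritis or a related disorder (ICD-10 M00-M19).
The costing chain is:

1. weighted group summaries of weekly income, welfare and tax for five
   analysis groups (full/part-time by arthritis, plus the lost-PLY group);
2. covariate-adjusted differences in median weekly outcomes versus
   full-time workers without arthritis, from weighted median regression
   with age band, sex and education as covariates, with percentile
   bootstrap confidence intervals;
3. counterfactual labour-force destination probabilities for lost-PLY
   people (full-time / part-time / unemployed absent arthritis),
   age-sex-standardised from the non-arthritis population;
4. national annual lost income, extra welfare and lost tax: per-person
   gaps to regression-predicted counterfactual outcomes, weighted,
   annualised at 52 weeks, in AU$ millions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scenario
from ._stats import weighted_mean, weighted_median, weighted_sd
from .quantreg import QuantregFit, fit_weighted_quantreg

__all__ = [
    "flag_lost_ply",
    "is_arthritis_code",
    "analysis_group",
    "summarize_groups",
    "fit_median_model",
    "adjusted_median_difference",
    "estimate_counterfactual_probs",
    "national_costs",
    "bootstrap_cis",
    "percent_change",
    "CounterfactualProbs",
    "OUTCOME_COLUMNS",
    "REFERENCE_GROUP",
]

OUTCOME_COLUMNS = {
    "income": "weekly_total_income",
    "welfare": "weekly_welfare",
    "tax": "weekly_tax",
}

REFERENCE_GROUP = "FT_no_arth"
_CONTRAST_GROUPS = ("FT_arth", "PT_no_arth", "PT_arth", "NILF_arth")

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


def is_arthritis_code(code) -> bool:
    """True for ICD-10 categories M00-M19 (arthritis and related disorders).

    Comparison is on the three-character category; a fourth-character
    subdivision (e.g. ``M05.3``) is accepted. Raises on malformed codes.
    """
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return False
    m = _ICD_RE.match(str(code).strip().upper())
    if not m:
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return m.group(1) == "M" and int(m.group(2)) <= 19


def flag_lost_ply(persons) -> pd.Series | bool:
    """Flag people with lost PLYs due to arthritis.

    True iff out of the labour force through own ill-health with an
    arthritis main condition. Accepts a person table (returns a boolean
    Series) or a single record mapping (returns bool).
    """
    if isinstance(persons, pd.DataFrame):
        cond = persons["main_condition"].map(is_arthritis_code).astype(bool)
        return (persons["labour_force_status"] == "NILF_ill_health") & cond
    return persons["labour_force_status"] == "NILF_ill_health" and is_arthritis_code(
        persons["main_condition"]
    )


def analysis_group(persons: pd.DataFrame) -> pd.Series:
    """Assign each person to an analysis group.

    Employment status crossed with arthritis main condition for workers;
    the lost-PLY group for ill-health non-participants with arthritis;
    residual categories otherwise.
    """
    arth = persons["main_condition"].map(is_arthritis_code).astype(bool)
    lfs = persons["labour_force_status"]
    out = pd.Series("NILF_other", index=persons.index, dtype=object)
    out[lfs == "unemployed"] = "unemployed"
    out[(lfs == "FT") & ~arth] = "FT_no_arth"
    out[(lfs == "FT") & arth] = "FT_arth"
    out[(lfs == "PT") & ~arth] = "PT_no_arth"
    out[(lfs == "PT") & arth] = "PT_arth"
    out[(lfs == "NILF_ill_health") & arth] = "NILF_arth"
    out[(lfs == "NILF_ill_health") & ~arth] = "NILF_ill_other"
    return out


def summarize_groups(persons: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Weighted per-group summaries of weekly income, welfare and tax.

    Returns one row per reported analysis group with the weighted count
    (and its value rounded to the nearest 1,000 for presentation), the
    share of the total weighted population, and weighted mean, SD and
    lower weighted median for each outcome. Empty groups yield null
    statistics and a warning rather than an error.
    """
    groups = analysis_group(persons)
    w_all = persons["survey_weight"].to_numpy(dtype=float)
    total_w = w_all.sum()
    rows = []
    for g in scenario.REPORTED_GROUPS:
        m = (groups == g).to_numpy()
        row = {"group": g, "year": year}
        if not m.any():
            warnings.warn(f"analysis group {g} is empty; statistics are null")
            row.update({"weighted_count": 0.0, "weighted_count_rounded": 0, "share_pct": 0.0})
            for o in OUTCOME_COLUMNS:
                row.update({f"{o}_mean": np.nan, f"{o}_sd": np.nan, f"{o}_median": np.nan})
        else:
            w = w_all[m]
            count = w.sum()
            row.update(
                {
                    "weighted_count": count,
                    "weighted_count_rounded": int(round(count / 1000.0) * 1000),
                    "share_pct": 100.0 * count / total_w,
                }
            )
            for o, col in OUTCOME_COLUMNS.items():
                v = persons.loc[m, col].to_numpy(dtype=float)
                row.update(
                    {
                        f"{o}_mean": weighted_mean(v, w),
                        f"{o}_sd": weighted_sd(v, w),
                        f"{o}_median": weighted_median(v, w),
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adjusted median differences


def _design(persons: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + group contrasts (reference full-time, no arthritis) +
    covariate dummies (first level of each covariate as reference).

    Only groups realised in the data get a contrast column, so reduced
    designs (e.g. two-group experiments) stay full rank.
    """
    groups = analysis_group(persons)
    present = set(groups.unique())
    contrasts = [g for g in _CONTRAST_GROUPS if g in present]
    cols = [np.ones(len(persons))]
    names = ["intercept"]
    for g in contrasts:
        cols.append((groups == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    for cov in covariates:
        levels = sorted(persons[cov].dropna().unique())
        for lev in levels[1:]:
            cols.append((persons[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names, contrasts


def _analysis_subset(persons: pd.DataFrame) -> pd.DataFrame:
    groups = analysis_group(persons)
    return persons[groups.isin(scenario.REPORTED_GROUPS).to_numpy()]


def fit_median_model(
    persons: pd.DataFrame,
    outcome: str,
    covariates=("age_group", "sex", "education"),
    weights=None,
) -> QuantregFit:
    """Weighted median regression of an outcome on group contrasts.

    Restricted to the five reported analysis groups; the full-time
    no-arthritis group is the reference, so each group coefficient is the
    covariate-adjusted median difference versus that reference.
    """
    sub = _analysis_subset(persons)
    if (analysis_group(sub) == REFERENCE_GROUP).sum() == 0:
        raise ValueError("reference group (full-time, no arthritis) is empty")
    X, names, _ = _design(sub, covariates)
    y = sub[OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
    w = sub["survey_weight"].to_numpy(dtype=float) if weights is None else weights
    return fit_weighted_quantreg(X, y, w, tau=0.5, columns=names)


def adjusted_median_difference(
    persons: pd.DataFrame,
    outcome: str,
    year: int | None = None,
    covariates=("age_group", "sex", "education"),
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Adjusted median differences versus full-time workers without
    arthritis, with 95% percentile-bootstrap confidence intervals.

    Case-resampling bootstrap (records resampled with their weights
    carried, implemented as multinomial count reweighting) with ``reps``
    replications. The reference-group row is included with a difference of
    exactly zero.
    """
    sub = _analysis_subset(persons).reset_index(drop=True)
    X, names, contrasts = _design(sub, covariates)
    y = sub[OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
    w = sub["survey_weight"].to_numpy(dtype=float)
    fit = fit_weighted_quantreg(X, y, w, tau=0.5, columns=names)

    rng = np.random.default_rng(seed)
    n = len(sub)
    boot = np.empty((reps, len(contrasts)))
    for r in range(reps):
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        keep = counts > 0
        bfit = fit_weighted_quantreg(X[keep], y[keep], w[keep] * counts[keep], tau=0.5)
        boot[r] = bfit.params[1 : 1 + len(contrasts)]

    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    rows = [
        {
            "outcome": outcome,
            "group": REFERENCE_GROUP,
            "year": year,
            "estimate": 0.0,
            "ci_low": 0.0,
            "ci_high": 0.0,
            "significant": False,
        }
    ]
    for j, g in enumerate(contrasts):
        est = fit.params[1 + j]
        rows.append(
            {
                "outcome": outcome,
                "group": g,
                "year": year,
                "estimate": est,
                "ci_low": lo[j],
                "ci_high": hi[j],
                "significant": bool(lo[j] > 0 or hi[j] < 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counterfactual destinations and national costs


@dataclass(frozen=True)
class CounterfactualProbs:
    """Labour-force destination probabilities absent arthritis."""

    year: int | None
    p_ft: float
    p_pt: float
    p_unemp: float

    def __post_init__(self):
        for p in (self.p_ft, self.p_pt, self.p_unemp):
            if not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError("probabilities must lie in [0, 1]")


def estimate_counterfactual_probs(persons: pd.DataFrame, year: int | None = None) -> CounterfactualProbs:
    """Destination distribution of the active non-arthritis population,
    standardised to the age-sex profile of the lost-PLY group.

    Within each age-sex stratum the weighted full-time / part-time /
    unemployed distribution of people without an arthritis main condition
    is computed; strata are then mixed with the lost-PLY group's age-sex
    weights. The unemployment probability is taken as the complement so
    the three sum to one exactly. Strata with no active non-arthritis
    people fall back to the unstandardised distribution with a warning.
    """
    arth = persons["main_condition"].map(is_arthritis_code).astype(bool)
    active = persons["labour_force_status"].isin(["FT", "PT", "unemployed"])
    pool = persons[~arth & active]
    if len(pool) == 0:
        raise ValueError("no active non-arthritis population to standardise on")
    lost = persons[flag_lost_ply(persons)]

    def dist(sub):
        w = sub["survey_weight"].to_numpy(dtype=float)
        tot = w.sum()
        p_ft = w[(sub["labour_force_status"] == "FT").to_numpy()].sum() / tot
        p_pt = w[(sub["labour_force_status"] == "PT").to_numpy()].sum() / tot
        return p_ft, p_pt

    if len(lost) == 0:
        p_ft, p_pt = dist(pool)
        return CounterfactualProbs(year, p_ft, p_pt, max(0.0, 1.0 - p_ft - p_pt))

    strata = lost.groupby(["age_group", "sex"], observed=True)["survey_weight"].sum()
    strata = strata / strata.sum()
    p_ft = p_pt = 0.0
    for (age, sex), share in strata.items():
        cell = pool[(pool["age_group"] == age) & (pool["sex"] == sex)]
        if len(cell) == 0:
            warnings.warn(f"no active non-arthritis people in stratum ({age}, {sex}); using marginal distribution")
            cell = pool
        f, p = dist(cell)
        p_ft += share * f
        p_pt += share * p
    return CounterfactualProbs(year, p_ft, p_pt, max(0.0, 1.0 - p_ft - p_pt))


def _counterfactual_prediction(fit: QuantregFit, persons: pd.DataFrame, destination: str, covariates):
    """Predicted median outcome had each person been in ``destination``
    (FT or PT work without arthritis), at their own covariates."""
    if fit.columns is None:
        raise ValueError("model fit lacks column names; fit via fit_median_model")
    X = np.zeros((len(persons), len(fit.columns)))
    X[:, 0] = 1.0
    for j, name in enumerate(fit.columns):
        if name.startswith("group["):
            continue  # destination is a no-arthritis state: contrasts stay zero
        if "[" in name:
            cov, lev = name[:-1].split("[", 1)
            X[:, j] = (persons[cov] == lev).to_numpy(dtype=float)
    if destination == "PT":
        try:
            X[:, fit.columns.index("group[PT_no_arth]")] = 1.0
        except ValueError:
            raise ValueError(
                "missing counterfactual prediction stratum: no part-time "
                "no-arthritis group in the fitted model"
            ) from None
    elif destination != "FT":
        raise ValueError(f"unknown destination {destination!r}")
    return fit.predict(X)


def national_costs(
    persons: pd.DataFrame,
    probs: CounterfactualProbs,
    fits: dict | None = None,
    year: int | None = None,
    covariates=("age_group", "sex", "education"),
    unemployment_benefit: float = scenario.UNEMPLOYMENT_BENEFIT,
    weeks_per_year: float = 52.0,
) -> dict:
    """National annual indirect costs of arthritis, AU$ millions.

    For each lost-PLY person with weight w and current outcomes
    (y, b, t) = (income, welfare, tax):

    * lost income  = p_ft (c_ft - y) + p_pt (c_pt - y); the unemployed
      destination contributes no earnings gap;
    * extra welfare = p_ft (b - b_ft) + p_pt (b - b_pt)
      + p_unemp (b - unemployment_benefit);
    * lost tax = p_ft (t_ft - t) + p_pt (t_pt - t) + p_unemp (0 - t);

    where c_g, b_g, t_g are counterfactual medians predicted from the
    covariate-adjusted median-regression fits for destination g at the
    person's own age, sex and education. Totals are weighted sums,
    annualised at ``weeks_per_year`` and reported in millions.
    """
    lost = persons[flag_lost_ply(persons)]
    if len(lost) == 0:
        return {"year": year, "lost_income": 0.0, "extra_welfare": 0.0, "lost_tax": 0.0, "lost_workers": 0.0}
    if fits is None:
        fits = {o: fit_median_model(persons, o, covariates) for o in OUTCOME_COLUMNS}

    w = lost["survey_weight"].to_numpy(dtype=float)
    factor = weeks_per_year / 1e6

    c_ft = _counterfactual_prediction(fits["income"], lost, "FT", covariates)
    c_pt = _counterfactual_prediction(fits["income"], lost, "PT", covariates)
    y = lost["weekly_total_income"].to_numpy(dtype=float)
    lost_income = float(np.sum(w * (probs.p_ft * (c_ft - y) + probs.p_pt * (c_pt - y))) * factor)

    b_ft = _counterfactual_prediction(fits["welfare"], lost, "FT", covariates)
    b_pt = _counterfactual_prediction(fits["welfare"], lost, "PT", covariates)
    b = lost["weekly_welfare"].to_numpy(dtype=float)
    extra_welfare = float(
        np.sum(
            w
            * (
                probs.p_ft * (b - b_ft)
                + probs.p_pt * (b - b_pt)
                + probs.p_unemp * (b - unemployment_benefit)
            )
        )
        * factor
    )

    t_ft = _counterfactual_prediction(fits["tax"], lost, "FT", covariates)
    t_pt = _counterfactual_prediction(fits["tax"], lost, "PT", covariates)
    t = lost["weekly_tax"].to_numpy(dtype=float)
    lost_tax = float(
        np.sum(w * (probs.p_ft * (t_ft - t) + probs.p_pt * (t_pt - t) + probs.p_unemp * (0.0 - t)))
        * factor
    )

    return {
        "year": year,
        "lost_income": lost_income,
        "extra_welfare": extra_welfare,
        "lost_tax": lost_tax,
        "lost_workers": float(w.sum()),
    }


# ---------------------------------------------------------------------------
# generic bootstrap and reporting arithmetic


def bootstrap_cis(records: pd.DataFrame, statistic, reps: int = 1000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap interval for a statistic of a record table.

    The resampling unit is the survey record; weights travel with the
    record. ``statistic`` maps a resampled DataFrame to a float.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(records)
    vals = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, n)
        vals[r] = statistic(records.iloc[idx])
    alpha = 100.0 * (1.0 - level) / 2.0
    return float(np.percentile(vals, alpha)), float(np.percentile(vals, 100.0 - alpha))


def percent_change(v0: float, v1: float) -> int:
    """Integer percent change from v0 to v1, rounded half away from zero."""
    if v0 <= 0:
        raise ValueError("baseline value must be positive")
    x = (v1 - v0) / v0 * 100.0
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))
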