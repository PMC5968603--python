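"""End-to-end pipeline: generate, impute, project, cost, report.

``run_pipeline`` executes the full chain for every requested projection
year and returns a results bundle holding the four report tables:

1. weighted group summaries (counts, shares, mean/SD/median income,
   welfare and tax per week);
2. covariate-adjusted median differences versus full-time workers without
   arthritis, with bootstrap CIs;
3. national annual lost income, extra welfare and lost tax with bootstrap
   CIs, plus the counterfactual destination split;
4. GDP impact of the missing workers.

The bootstrap for tables 2 and 3 is a single loop: each replicate
resamples survey records (weights carried, implemented as multinomial
count reweighting), refits the three median-regression models and
recomputes both the group contrasts and the national cost components, so
the two tables' intervals come from the same resamples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import costing, gdp, scenario
from .config import RunConfig
from .costing import (
    CounterfactualProbs,
    OUTCOME_COLUMNS,
    REFERENCE_GROUP,
    _analysis_subset,
    _design,
    flag_lost_ply,
)
from .matching import impute_economics
from .projection import calibrate_to_benchmarks, uprate_profile
from .quantreg import fit_weighted_quantreg
from .synthetic import ECON_COLUMNS, PERSON_COLUMNS, generate_benchmarks, generate_population

__all__ = ["run_pipeline", "render_table", "write_outputs", "ResultsBundle", "PipelineError"]

log = logging.getLogger("plysim")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class ResultsBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    metrics: dict
    calibration_log: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(name, e) from e

        return wrapped

    return deco


def run_pipeline(config: RunConfig, covariates=("age_group", "sex", "education")) -> ResultsBundle:
    """Execute all stages for every configured projection year."""
    seeds = config.stage_seeds()
    gen = config.generator
    log.info("stage seeds: %s", seeds)

    survey = _stage("generate")(generate_population)(gen, seed=seeds["generator"])[PERSON_COLUMNS]
    donors = _stage("generate")(generate_population)(
        gen, seed=seeds["donors"], n_records=int(round(gen.n_records * gen.donor_coverage))
    )
    imputed, audit = _stage("impute")(impute_economics)(
        survey, donors, config.fallback, seed=seeds["matching"]
    )
    log.info("imputation fallback depth distribution: %s", audit["fallback_depth"].value_counts().to_dict())

    benchmarks = _stage("benchmarks")(generate_benchmarks)(gen, config.years)

    t1, t2, t3 = [], [], []
    missing = {}
    calibration_log = []
    boot_rng = np.random.default_rng(seeds["bootstrap"])
    for year in config.years:
        econ = _stage("uprate")(uprate_profile)(imputed[ECON_COLUMNS], config.uprating, year)
        persons = imputed.copy()
        persons[ECON_COLUMNS] = econ

        cal = config.calibration
        persons, results = _stage("calibrate")(calibrate_to_benchmarks)(
            persons,
            benchmarks[year],
            bounds=(cal.lower, cal.upper),
            tol=cal.tol,
            max_iter=cal.max_iter,
        )
        for r in results:
            calibration_log.append(
                {
                    "year": year,
                    "iterations": r.iterations,
                    "max_constraint_gap": r.max_constraint_gap,
                    "bounded_count": r.bounded_count,
                }
            )

        t1.append(_stage("summarize")(costing.summarize_groups)(persons, year))
        probs = _stage("probs")(costing.estimate_counterfactual_probs)(persons, year)
        year_seed = int(boot_rng.integers(0, 2**31 - 1))
        tab2, tab3 = _stage("cost")(_cost_tables)(
            persons, probs, year, covariates, config.bootstrap_reps, year_seed
        )
        t2.append(tab2)
        t3.append(tab3)
        missing[year] = (
            tab3["lost_workers"].iloc[0] * probs.p_ft,
            tab3["lost_workers"].iloc[0] * probs.p_pt,
        )

    table4 = _stage("gdp")(gdp.gdp_impact_table)(missing)
    table1 = pd.concat(t1, ignore_index=True)
    table2 = pd.concat(t2, ignore_index=True)
    table3 = pd.concat(t3, ignore_index=True)
    metrics = _metrics(table1, table3, table4, config)
    return ResultsBundle(table1, table2, table3, table4, metrics, calibration_log, seeds)


def _cost_tables(persons, probs: CounterfactualProbs, year, covariates, reps, seed):
    """Point estimates and a shared bootstrap for tables 2 and 3."""
    sub = _analysis_subset(persons).reset_index(drop=True)
    X, names, contrasts = _design(sub, covariates)
    w = sub["survey_weight"].to_numpy(dtype=float)
    ys = {o: sub[OUTCOME_COLUMNS[o]].to_numpy(dtype=float) for o in OUTCOME_COLUMNS}
    fits = {o: fit_weighted_quantreg(X, ys[o], w, tau=0.5, columns=names) for o in OUTCOME_COLUMNS}

    lost_mask = flag_lost_ply(sub).to_numpy()
    lost = sub[lost_mask]
    # counterfactual design matrices for the lost-PLY records are fixed
    Xc_ft, Xc_pt = _counterfactual_designs(lost, covariates, names, contrasts)
    w_lost = w[lost_mask]
    actual = {o: ys[o][lost_mask] for o in OUTCOME_COLUMNS}

    point = _national_components(fits, probs, Xc_ft, Xc_pt, w_lost, actual)

    rng = np.random.default_rng(seed)
    n = len(sub)
    ncontrast = len(contrasts)
    boot_coef = {o: np.empty((reps, ncontrast)) for o in OUTCOME_COLUMNS}
    boot_nat = {k: np.empty(reps) for k in ("lost_income", "extra_welfare", "lost_tax")}
    for r in range(reps):
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        keep = counts > 0
        wb = w * counts
        bfits = {
            o: fit_weighted_quantreg(X[keep], ys[o][keep], wb[keep], tau=0.5) for o in OUTCOME_COLUMNS
        }
        for o in OUTCOME_COLUMNS:
            boot_coef[o][r] = bfits[o].params[1 : 1 + ncontrast]
        keep_lost = counts[lost_mask]
        nat = _national_components(bfits, probs, Xc_ft, Xc_pt, w_lost * keep_lost, actual)
        for k in boot_nat:
            boot_nat[k][r] = nat[k]

    rows2 = []
    for o in OUTCOME_COLUMNS:
        rows2.append(
            {
                "outcome": o,
                "group": REFERENCE_GROUP,
                "year": year,
                "estimate": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
                "significant": False,
            }
        )
        lo = np.percentile(boot_coef[o], 2.5, axis=0)
        hi = np.percentile(boot_coef[o], 97.5, axis=0)
        for j, g in enumerate(contrasts):
            rows2.append(
                {
                    "outcome": o,
                    "group": g,
                    "year": year,
                    "estimate": fits[o].params[1 + j],
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                    "significant": bool(lo[j] > 0 or hi[j] < 0),
                }
            )
    table2 = pd.DataFrame(rows2)

    row3 = {"year": year, "lost_workers": float(w_lost.sum())}
    for k in ("lost_income", "extra_welfare", "lost_tax"):
        row3[k] = point[k]
        row3[f"{k}_ci_low"] = float(np.percentile(boot_nat[k], 2.5))
        row3[f"{k}_ci_high"] = float(np.percentile(boot_nat[k], 97.5))
    row3.update({"p_ft": probs.p_ft, "p_pt": probs.p_pt, "p_unemp": probs.p_unemp})
    return table2, pd.DataFrame([row3])


def _counterfactual_designs(lost, covariates, names, contrasts):
    X, lost_names, _ = _design(lost, covariates)
    if lost_names != names:
        # rebuild on the full design's columns (lost records may not span all levels)
        X = np.zeros((len(lost), len(names)))
        X[:, 0] = 1.0
        for j, name in enumerate(names):
            if name.startswith("group[") or "[" not in name:
                continue
            cov, lev = name[:-1].split("[", 1)
            X[:, j] = (lost[cov] == lev).to_numpy(dtype=float)
    else:
        X = X.copy()
        X[:, 1 : 1 + len(contrasts)] = 0.0
    Xft = X
    Xft[:, 1 : 1 + len(contrasts)] = 0.0
    Xpt = Xft.copy()
    try:
        Xpt[:, names.index("group[PT_no_arth]")] = 1.0
    except ValueError:
        raise ValueError("missing counterfactual prediction stratum: no part-time no-arthritis group") from None
    return Xft, Xpt


def _national_components(fits, probs, Xc_ft, Xc_pt, w_lost, actual, weeks=52.0):
    factor = weeks / 1e6
    out = {}
    c_ft = Xc_ft @ fits["income"].params
    c_pt = Xc_pt @ fits["income"].params
    y = actual["income"]
    out["lost_income"] = float(np.sum(w_lost * (probs.p_ft * (c_ft - y) + probs.p_pt * (c_pt - y))) * factor)
    b_ft = Xc_ft @ fits["welfare"].params
    b_pt = Xc_pt @ fits["welfare"].params
    b = actual["welfare"]
    out["extra_welfare"] = float(
        np.sum(
            w_lost
            * (
                probs.p_ft * (b - b_ft)
                + probs.p_pt * (b - b_pt)
                + probs.p_unemp * (b - scenario.UNEMPLOYMENT_BENEFIT)
            )
        )
        * factor
    )
    t_ft = Xc_ft @ fits["tax"].params
    t_pt = Xc_pt @ fits["tax"].params
    t = actual["tax"]
    out["lost_tax"] = float(
        np.sum(w_lost * (probs.p_ft * (t_ft - t) + probs.p_pt * (t_pt - t) - probs.p_unemp * t)) * factor
    )
    return out


def _metrics(table1, table3, table4, config):
    years = list(config.years)
    metrics = {"years": years}
    nilf = table1[table1["group"] == "NILF_arth"].set_index("year")
    metrics["ply_headcount"] = {int(y): int(nilf.loc[y, "weighted_count_rounded"]) for y in years}
    nat = table3.set_index("year")
    for k in ("lost_income", "extra_welfare", "lost_tax"):
        metrics[k] = {int(y): float(nat.loc[y, k]) for y in years}
    g = table4.set_index("year")
    metrics["lost_gdp"] = {int(y): float(g.loc[y, "lost_gdp"]) for y in years}
    metrics["pct_gain"] = {int(y): float(g.loc[y, "pct_gain"]) for y in years}
    first, last = years[0], years[-1]
    if first != last:
        metrics["growth_pct"] = {
            "ply_headcount": costing.percent_change(
                metrics["ply_headcount"][first], metrics["ply_headcount"][last]
            ),
            "lost_income": costing.percent_change(metrics["lost_income"][first], metrics["lost_income"][last]),
            "extra_welfare": costing.percent_change(
                metrics["extra_welfare"][first], metrics["extra_welfare"][last]
            ),
            "lost_tax": costing.percent_change(metrics["lost_tax"][first], metrics["lost_tax"][last]),
            "lost_gdp": costing.percent_change(metrics["lost_gdp"][first], metrics["lost_gdp"][last]),
        }
    return metrics


_TABLE_ATTRS = {1: "table1", 2: "table2", 3: "table3", 4: "table4"}


def render_table(results: ResultsBundle, table_id: int) -> pd.DataFrame:
    """Presentation view of a results table.

    Currency columns are rounded to 2 decimals, counts to the nearest
    1,000. Headers tag monetary units as real 2013 AU$.
    """
    if table_id not in _TABLE_ATTRS:
        raise ValueError(f"unknown table id {table_id}")
    df = getattr(results, _TABLE_ATTRS[table_id])
    if df is None or len(df) == 0:
        raise ValueError(f"results bundle lacks table {table_id} inputs")
    df = df.copy()
    if table_id == 1:
        money = [c for c in df.columns if c.endswith(("_mean", "_sd", "_median"))]
        df[money] = df[money].round(2)
        df = df.drop(columns=["weighted_count"]).rename(
            columns={"weighted_count_rounded": "weighted_count"}
        )
        df = df.rename(columns={c: f"{c}_real2013AUD" for c in money})
    elif table_id == 2:
        for c in ("estimate", "ci_low", "ci_high"):
            df[c] = df[c].round(2)
        df = df.rename(columns={"estimate": "difference_real2013AUD_per_week"})
    elif table_id == 3:
        money = [c for c in df.columns if c.startswith(("lost_", "extra_")) and c != "lost_workers"]
        df[money] = df[money].round(2)
        df["lost_workers"] = (df["lost_workers"] / 1000.0).round().astype(int) * 1000
        df = df.rename(columns={c: f"{c}_real2013AUD_m" for c in money})
    else:
        df["lost_gdp"] = df["lost_gdp"].round(2)
        df["missing_ft"] = (df["missing_ft"] / 1000.0).round().astype(int) * 1000
        df["missing_pt"] = (df["missing_pt"] / 1000.0).round().astype(int) * 1000
        df = df[["year", "projected_gdp", "missing_ft", "missing_pt", "lost_gdp", "pct_gain"]]
        df = df.rename(
            columns={
                "projected_gdp": "projected_gdp_real2013AUD_m",
                "lost_gdp": "lost_gdp_real2013AUD_m",
            }
        )
    return df


def write_outputs(results: ResultsBundle, outdir) -> None:
    """Write the four tables (CSV), the metrics bundle (JSON) and a log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tid in (1, 2, 3, 4):
        render_table(results, tid).to_csv(out / f"table{tid}.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(results.metrics, fh, indent=2)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"seeds": results.seeds, "calibration": results.calibration_log}, fh, indent=2)
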