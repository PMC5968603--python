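"""Run and generator configuration.

Everything a run needs is collected in plain dataclasses that serialise to
and from YAML, so a complete analysis is reproducible from one structured
text file plus one integer master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import scenario

__all__ = [
    "TaxSchedule",
    "WelfareRules",
    "GeneratorConfig",
    "UpratingRule",
    "CalibrationSettings",
    "FallbackPolicy",
    "RunConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class TaxSchedule:
    """Stylised personal income tax schedule (2012-13 style, AU$ per year).

    ``brackets`` are (upper_threshold, marginal_rate) pairs applied to
    annual taxable income after a flat ``deduction``; the last bracket is
    open-ended. A low-income offset phases out linearly, and a health levy
    applies above a low-income threshold with a phase-in band. Weekly tax is
    the annual liability divided by 52, floored at zero.
    """

    brackets: tuple = ((18_200.0, 0.0), (37_000.0, 0.19), (80_000.0, 0.325), (180_000.0, 0.37), (None, 0.45))
    deduction: float = 5_000.0
    offset_max: float = 445.0
    offset_phaseout_start: float = 37_000.0
    offset_phaseout_rate: float = 0.015
    levy_rate: float = 0.015
    levy_threshold: float = 24_167.0
    levy_phase_in: float = 0.10

    def annual_tax(self, annual_income) -> np.ndarray:
        """Annual income tax + levy for annual gross income (vectorised)."""
        if not self.brackets:
            raise ConfigurationError("tax schedule has no brackets")
        y = np.maximum(np.asarray(annual_income, dtype=float) - self.deduction, 0.0)
        tax = np.zeros_like(y)
        lower = 0.0
        for upper, rate in self.brackets:
            hi = np.inf if upper is None else upper
            tax += rate * np.clip(y - lower, 0.0, hi - lower)
            lower = hi
        offset = np.maximum(
            self.offset_max - self.offset_phaseout_rate * np.maximum(y - self.offset_phaseout_start, 0.0),
            0.0,
        )
        tax = np.maximum(tax - offset, 0.0)
        levy = np.minimum(self.levy_rate * y, self.levy_phase_in * np.maximum(y - self.levy_threshold, 0.0))
        return tax + np.maximum(levy, 0.0)

    def weekly_tax(self, weekly_income) -> np.ndarray:
        return self.annual_tax(np.asarray(weekly_income, dtype=float) * 52.0) / 52.0


@dataclass(frozen=True)
class WelfareRules:
    """Rule-based welfare assignment (flat payment rates, AU$/week).

    Payments are status-dependent rather than distributional: people out of
    the labour force through ill-health mostly receive a disability-pension
    rate, the unemployed an unemployment-benefit rate, and employed people
    occasionally a family-supplement amount. This produces the degenerate
    group medians (a flat pension rate for the ill-health group, zero for
    full-time workers) that characterise welfare in this population.
    """

    dsp_rate: float = scenario.DSP_RATE
    unemployment_benefit: float = scenario.UNEMPLOYMENT_BENEFIT
    family_supplement: float = 230.0
    dsp_prob_nilf_ill: float = 0.85
    supplement_prob_nilf_ill: float = 0.08
    supplement_prob_ft: float = 0.08
    supplement_prob_pt: float = 0.30
    dsp_prob_nilf_other: float = 0.08
    benefit_prob_nilf_other: float = 0.30


def _default_group_shares() -> dict:
    shares = dict(scenario.GROUP_SHARES[2015])
    shares.pop("NILF_other")  # implied remainder
    return shares


def _deindex(x: float, years: int = 2, rate: float = 0.01) -> float:
    """Back out base-year (2013) level from a 2015 anchor under 1%/yr growth."""
    return x / (1.0 + rate) ** years


def _default_median_targets() -> dict:
    targets = {}
    for g in scenario.REPORTED_GROUPS:
        a = scenario.ANCHOR_2015[g]
        targets[g] = {
            "income": _deindex(a["income"][2]) if g != "NILF_arth" else None,
            "welfare": a["welfare"][2],
            "tax": _deindex(a["tax"][2]),
        }
    # welfare has zero real growth, so the NILF income anchor de-indexes
    # only through its small non-welfare component
    nilf = scenario.ANCHOR_2015["NILF_arth"]
    targets["NILF_arth"]["income"] = nilf["welfare"][2] + _deindex(nilf["income"][2] - nilf["welfare"][2])
    for g, med in scenario.RESIDUAL_INCOME_MEDIANS.items():
        targets[g] = {"income": _deindex(med), "welfare": None, "tax": 0.0}
    targets["unemployed"]["income"] = scenario.UNEMPLOYMENT_BENEFIT + _deindex(
        scenario.RESIDUAL_INCOME_MEDIANS["unemployed"] - scenario.UNEMPLOYMENT_BENEFIT
    )
    targets["NILF_ill_other"]["income"] = targets["NILF_arth"]["income"]
    return targets


def _default_income_dispersion() -> dict:
    # log-scale SDs per group, set from the 2015 mean/median skew
    return {
        "FT_no_arth": 0.63,
        "FT_arth": 0.54,
        "PT_no_arth": 0.60,
        "PT_arth": 0.40,
        "NILF_arth": 0.80,
        "unemployed": 0.70,
        "NILF_other": 0.90,
        "NILF_ill_other": 0.80,
    }


_EMPLOYED_EDU_MIX = {"none-post-school": 0.30, "certificate/diploma": 0.40, "degree+": 0.30}
_ARTH_EMPLOYED_EDU_MIX = {"none-post-school": 0.40, "certificate/diploma": 0.40, "degree+": 0.20}
_NILF_ILL_EDU_MIX = {"none-post-school": 0.60, "certificate/diploma": 0.30, "degree+": 0.10}
_RESIDUAL_EDU_MIX = {"none-post-school": 0.45, "certificate/diploma": 0.35, "degree+": 0.20}

_UNIFORM_AGE_MIX = {"45-49": 0.27, "50-54": 0.26, "55-59": 0.24, "60-64": 0.23}
_OLD_AGE_MIX = {"45-49": 0.10, "50-54": 0.20, "55-59": 0.30, "60-64": 0.40}
_NILF_OTHER_AGE_MIX = {"45-49": 0.18, "50-54": 0.22, "55-59": 0.27, "60-64": 0.33}


def _default_covariate_mixes() -> dict:
    return {
        "education": {
            "FT_no_arth": dict(_EMPLOYED_EDU_MIX),
            "PT_no_arth": dict(_EMPLOYED_EDU_MIX),
            "FT_arth": dict(_ARTH_EMPLOYED_EDU_MIX),
            "PT_arth": dict(_ARTH_EMPLOYED_EDU_MIX),
            "NILF_arth": dict(_NILF_ILL_EDU_MIX),
            "NILF_ill_other": dict(_NILF_ILL_EDU_MIX),
            "unemployed": dict(_RESIDUAL_EDU_MIX),
            "NILF_other": dict(_RESIDUAL_EDU_MIX),
        },
        "age_group": {
            "FT_no_arth": dict(_UNIFORM_AGE_MIX),
            "PT_no_arth": dict(_UNIFORM_AGE_MIX),
            "FT_arth": dict(_UNIFORM_AGE_MIX),
            "PT_arth": dict(_UNIFORM_AGE_MIX),
            "NILF_arth": dict(_OLD_AGE_MIX),
            "NILF_ill_other": dict(_OLD_AGE_MIX),
            "unemployed": dict(_UNIFORM_AGE_MIX),
            "NILF_other": dict(_NILF_OTHER_AGE_MIX),
        },
        "female_share": {
            "FT_no_arth": 0.44,
            "FT_arth": 0.44,
            "PT_no_arth": 0.58,
            "PT_arth": 0.58,
            "NILF_arth": 0.52,
            "NILF_ill_other": 0.52,
            "unemployed": 0.45,
            "NILF_other": 0.60,
        },
    }


def _default_covariate_log_effects() -> dict:
    # multiplicative (log-scale) earnings effects by education and age band
    return {
        "education": {"none-post-school": -0.35, "certificate/diploma": 0.0, "degree+": 0.50},
        "age_group": {"45-49": 0.0, "50-54": 0.02, "55-59": -0.05, "60-64": -0.15},
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey / donor-pool generator.

    Defaults reproduce the package's study conditions: 25,104 records over
    two pooled survey years representing 5,945,000 people aged 45-64 in
    2015, group shares and weekly monetary medians matching the 2015
    anchors, log-normal earnings within groups, rule-based welfare, and a
    stylised tax schedule. Monetary levels are at base-year (2013) prices;
    income and tax targets are the 2015 anchors de-indexed by two years of
    1% real growth so that uprating reproduces the anchors in 2015.
    """

    n_records: int = 25_104
    survey_years: tuple = (2003, 2009)
    weighted_population: float = float(scenario.POPULATION[2015])
    group_shares: dict = field(default_factory=_default_group_shares)
    median_targets: dict = field(default_factory=_default_median_targets)
    income_dispersion: dict = field(default_factory=_default_income_dispersion)
    covariate_mixes: dict = field(default_factory=_default_covariate_mixes)
    covariate_log_effects: dict = field(default_factory=_default_covariate_log_effects)
    welfare_rules: WelfareRules = field(default_factory=WelfareRules)
    tax_schedule: TaxSchedule = field(default_factory=TaxSchedule)
    tax_mode: str = "schedule"  # or "target": power-law in income, median pinned
    tax_elasticity: float = 1.8  # progressivity of target-mode tax in income
    other_income_zero_prob: float = 0.5
    other_income_sigma: float = 1.0
    weight_dispersion: float = 0.5  # weights uniform in 1 +/- dispersion (then scaled)
    donor_coverage: float = 1.0  # donor-pool size as a multiple of n_records
    calibrate_medians: bool = True
    seed: int = 1234

    def validate(self) -> None:
        total = sum(self.group_shares.values())
        if total > 1.0 + 1e-9:
            raise ConfigurationError(f"group shares sum to {total:.4f} > 1")
        if any(s < 0 for s in self.group_shares.values()):
            raise ConfigurationError("group shares must be non-negative")
        if self.n_records < 0:
            raise ConfigurationError("n_records must be non-negative")
        active = [g for g, s in self.group_shares.items() if s > 0]
        if 0 < self.n_records < len(active):
            raise ConfigurationError(
                f"n_records={self.n_records} cannot realise {len(active)} groups"
            )
        for g, t in self.median_targets.items():
            for k, v in t.items():
                if v is not None and v < 0:
                    raise ConfigurationError(f"median target {g}/{k} is negative")
        if not 0 < self.donor_coverage:
            raise ConfigurationError("donor_coverage must be positive")

    @property
    def all_group_shares(self) -> dict:
        """Shares for all groups, with NILF_other as the implied remainder."""
        shares = dict(self.group_shares)
        if "NILF_other" not in shares:
            shares["NILF_other"] = max(0.0, 1.0 - sum(shares.values()))
        return shares


@dataclass(frozen=True)
class UpratingRule:
    """Real growth rates applied from the base year to a projection year."""

    income_growth: float = 0.01
    tax_growth: float = 0.01
    welfare_growth: float = 0.0
    base_year: int = 2013

    def __post_init__(self):
        for r in (self.income_growth, self.tax_growth, self.welfare_growth):
            if r < -1.0:
                raise ConfigurationError("growth rates must be >= -1")


@dataclass(frozen=True)
class CalibrationSettings:
    lower: float = 0.1
    upper: float = 10.0
    tol: float = 1e-6
    max_iter: int = 50


@dataclass(frozen=True)
class FallbackPolicy:
    """Ordered list of matching variables to drop when a cell has no donor.

    The default order drops the least outcome-predictive variables first
    and can fall all the way back to the labour-force-status stratifier,
    which is never droppable, so matching on a status-covering donor pool
    always succeeds.
    """

    drop_order: tuple = (
        "home_ownership",
        "income_unit_type",
        "receives_age_pension",
        "hours_band",
        "education",
        "income_quintile",
        "receives_dsp",
        "age_group",
        "sex",
    )

    def __post_init__(self):
        if "labour_force_status" in self.drop_order:
            raise ConfigurationError("labour_force_status can never be dropped")


@dataclass
class RunConfig:
    """Full pipeline configuration: one object, one master seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    years: Sequence[int] = scenario.YEARS
    uprating: UpratingRule = field(default_factory=UpratingRule)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    fallback: FallbackPolicy = field(default_factory=FallbackPolicy)
    bootstrap_reps: int = 1000
    seed: int = 1234
    output_dir: str = "plysim_output"

    def __post_init__(self):
        if not self.years:
            raise ConfigurationError("years must be non-empty")

    def stage_seeds(self) -> dict:
        """Named per-stage seeds derived from the master seed."""
        rng = np.random.default_rng(self.seed)
        names = ("generator", "donors", "matching", "bootstrap")
        draws = rng.integers(0, 2**31 - 1, size=len(names))
        return dict(zip(names, (int(d) for d in draws)))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def _tuplify_brackets(d):
    return tuple((None if u is None else float(u), float(r)) for u, r in d)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gen = raw.get("generator", {})
    if "welfare_rules" in gen:
        gen["welfare_rules"] = WelfareRules(**gen["welfare_rules"])
    if "tax_schedule" in gen:
        ts = gen["tax_schedule"]
        ts["brackets"] = _tuplify_brackets(ts["brackets"])
        gen["tax_schedule"] = TaxSchedule(**ts)
    if "survey_years" in gen:
        gen["survey_years"] = tuple(gen["survey_years"])
    raw["generator"] = GeneratorConfig(**gen)
    if "uprating" in raw:
        raw["uprating"] = UpratingRule(**raw["uprating"])
    if "calibration" in raw:
        raw["calibration"] = CalibrationSettings(**raw["calibration"])
    if "fallback" in raw:
        raw["fallback"] = FallbackPolicy(drop_order=tuple(raw["fallback"]["drop_order"]))
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    return RunConfig(**raw)
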