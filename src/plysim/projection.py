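"""Projection machinery: uprating, benchmark constraints and calibration.

The imputed base-year economic world is carried to a projection year in two
moves. Monetary amounts are *uprated* with compound real growth rates
(income and tax at 1%/yr, welfare flat, by default). Survey weights are
*calibrated* so that weighted totals hit projection-year benchmarks --
generalized-regression (GREG) calibration with the chi-square distance and
weight truncation, the family of methods behind the ABS GREGWT routine.

Calibration solves

    min over w   sum_i (w_i - d_i)^2 / d_i
    subject to   sum_i w_i x_i = T,    L d_i <= w_i <= U d_i,

whose unbounded solution is linear in the constraint multipliers,
``w = d (1 + X lambda)`` with ``(X'DX) lambda = T - X'd``. Bounds are
enforced by clamping breaching weights and re-solving on the free set
until no new weight hits a bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Constraint",
    "BenchmarkSet",
    "CalibrationResult",
    "CalibrationError",
    "InfeasibleConstraintsError",
    "calibrate_weights",
    "calibrate_to_benchmarks",
    "constraint_matrix",
    "uprate_profile",
    "apply_disease_trend",
]

_MONEY_COLS = ("weekly_earnings", "weekly_other_income", "weekly_welfare", "weekly_tax")


class CalibrationError(RuntimeError):
    """Calibration failed to converge; carries the best achieved gap."""

    def __init__(self, message, gap=None):
        super().__init__(message)
        self.gap = gap


class InfeasibleConstraintsError(CalibrationError):
    """Targets cannot be met under the weight bounds."""


@dataclass(frozen=True)
class Constraint:
    """One calibration benchmark: a cell definition and its weighted target."""

    name: str
    where: dict  # column -> required value
    target: float

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for col, val in self.where.items():
            if col not in df.columns:
                raise KeyError(f"constraint {self.name!r} references unknown variable {col!r}")
            m &= (df[col] == val).to_numpy()
        return m


@dataclass
class BenchmarkSet:
    """Projection-year calibration targets plus the disease-trend multiplier."""

    year: int
    population_total: float
    constraints: list = field(default_factory=list)
    trend_multiplier: float = 1.0

    def targets(self) -> np.ndarray:
        return np.array([c.target for c in self.constraints], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.constraints:
            where = ";".join(f"{k}={v}" for k, v in c.where.items())
            rows.append({"year": self.year, "name": c.name, "cell": where, "target": c.target})
        return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    weights: np.ndarray
    multipliers: np.ndarray
    iterations: int
    max_constraint_gap: float
    bounded_count: int


def constraint_matrix(df: pd.DataFrame, constraints) -> np.ndarray:
    """Indicator matrix X (n x k): X[i, j] = 1 if record i is in cell j."""
    return np.column_stack([c.mask(df).astype(float) for c in constraints])


def calibrate_weights(
    design_weights,
    X,
    targets,
    bounds=(0.1, 10.0),
    tol: float = 1e-6,
    max_iter: int = 50,
) -> CalibrationResult:
    """Chi-square (GREG) calibration of survey weights with truncation.

    Parameters
    ----------
    design_weights : array-like, shape (n,)
        Positive starting weights.
    X : array-like, shape (n, k)
        Constraint design matrix; column j holds record contributions to
        benchmark j (indicators for cell totals).
    targets : array-like, shape (k,)
        Benchmark weighted totals.
    bounds : (float, float) or None
        Multiplicative weight bounds relative to the design weights;
        None disables truncation.
    tol : float
        Maximum allowed relative error on any benchmark.
    max_iter : int
        Bound on clamp-and-resolve iterations.

    Raises
    ------
    InfeasibleConstraintsError
        If a target exceeds what bounded weights can deliver.
    CalibrationError
        On non-convergence; the exception carries the best achieved gap.
    """
    d = np.asarray(design_weights, dtype=float)
    if np.any(d <= 0):
        raise ValueError("design weights must be positive")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != d.size:
        raise ValueError("X must be (n, k)")
    T = np.asarray(targets, dtype=float)
    if T.shape != (X.shape[1],):
        raise ValueError("targets must have one entry per constraint column")
    if np.any(T < 0):
        raise ValueError("targets must be non-negative")

    if bounds is None:
        lo_w = np.full_like(d, -np.inf)
        hi_w = np.full_like(d, np.inf)
    else:
        lo, hi = bounds
        if not 0 <= lo <= 1 <= hi:
            raise ValueError("bounds must satisfy lower <= 1 <= upper")
        lo_w, hi_w = lo * d, hi * d
        # capacity check per constraint (cell indicators are non-negative)
        over = T > (X * hi_w[:, None]).sum(axis=0) + 1e-9
        under = T < (X * lo_w[:, None]).sum(axis=0) - 1e-9
        if np.any(over | under):
            j = int(np.argmax(over | under))
            raise InfeasibleConstraintsError(
                f"target {j} ({T[j]:.6g}) outside bounded-weight capacity", gap=None
            )

    w = d.copy()
    free = np.ones(d.size, dtype=bool)
    lam = np.zeros(X.shape[1])
    scale = np.maximum(np.abs(T), 1.0)

    gap = _max_gap(X, w, T, scale)
    if gap <= tol:
        return CalibrationResult(w, lam, 0, gap, 0)

    best_gap = np.inf
    for it in range(1, max_iter + 1):
        Xf = X[free]
        df_ = d[free]
        resid = T - X[~free].T @ w[~free] if (~free).any() else T.copy()
        M = Xf.T @ (df_[:, None] * Xf)
        rhs = resid - Xf.T @ df_
        lam, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        w_free = df_ * (1.0 + Xf @ lam)
        w = w.copy()
        w[free] = w_free

        breach_lo = w < lo_w - 1e-12 * d
        breach_hi = w > hi_w + 1e-12 * d
        new_clamp = (breach_lo | breach_hi) & free
        w = np.clip(w, lo_w, hi_w)
        gap = _max_gap(X, w, T, scale)
        best_gap = min(best_gap, gap)
        if not new_clamp.any():
            if gap <= tol:
                return CalibrationResult(w, lam, it, gap, int((~free).sum()))
            if not free.any():
                raise InfeasibleConstraintsError(
                    f"all weights at bounds, residual gap {gap:.3g}", gap=gap
                )
            raise CalibrationError(
                f"calibration did not reach tol={tol:.1e}; best gap {best_gap:.3g}", gap=best_gap
            )
        free = free & ~new_clamp

    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations; best gap {best_gap:.3g}",
        gap=best_gap,
    )


def _max_gap(X, w, T, scale):
    return float(np.max(np.abs(X.T @ w - T) / scale))


def calibrate_to_benchmarks(
    persons: pd.DataFrame,
    benchmark: BenchmarkSet,
    bounds=(0.1, 10.0),
    tol: float = 1e-6,
    max_iter: int = 50,
    by_survey_year: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Reweight a person table to a projection-year benchmark set.

    The two pooled survey years are calibrated separately, each to half of
    every benchmark target (a 50/50 pooling convention), then recombined.
    Returns the table with ``survey_weight`` replaced and the list of
    :class:`CalibrationResult` diagnostics (one per survey year).
    """
    out = persons.copy()
    results = []
    if by_survey_year and "survey_year" in persons.columns:
        years = sorted(persons["survey_year"].unique())
    else:
        years = [None]
    share = 1.0 / len(years)
    for sy in years:
        sel = slice(None) if sy is None else (persons["survey_year"] == sy).to_numpy()
        sub = persons if sy is None else persons[sel]
        X = constraint_matrix(sub, benchmark.constraints)
        res = calibrate_weights(
            sub["survey_weight"].to_numpy(),
            X,
            benchmark.targets() * share,
            bounds=bounds,
            tol=tol,
            max_iter=max_iter,
        )
        results.append(res)
        if sy is None:
            out["survey_weight"] = res.weights
        else:
            out.loc[sel, "survey_weight"] = res.weights
    return out, results


def uprate_profile(profile, rule, target_year: int):
    """Uprate economic amounts from the base year to ``target_year``.

    Earnings and other income grow at ``income_growth``, tax at
    ``tax_growth`` and welfare at ``welfare_growth``, all compounded over
    ``target_year - base_year`` years; the total-income accounting identity
    is recomputed. Accepts a DataFrame (or Series-like mapping) carrying
    the weekly amount columns and returns the same shape.
    """
    if target_year < rule.base_year:
        raise ValueError(f"target year {target_year} precedes base year {rule.base_year}")
    n = target_year - rule.base_year
    f_inc = (1.0 + rule.income_growth) ** n
    f_tax = (1.0 + rule.tax_growth) ** n
    f_wel = (1.0 + rule.welfare_growth) ** n
    out = profile.copy()
    out["weekly_earnings"] = profile["weekly_earnings"] * f_inc
    out["weekly_other_income"] = profile["weekly_other_income"] * f_inc
    out["weekly_welfare"] = profile["weekly_welfare"] * f_wel
    out["weekly_tax"] = profile["weekly_tax"] * f_tax
    out["weekly_total_income"] = (
        out["weekly_earnings"] + out["weekly_other_income"] + out["weekly_welfare"]
    )
    return out


def apply_disease_trend(benchmark: BenchmarkSet, multiplier: float | None = None) -> BenchmarkSet:
    """Scale arthritis-cell targets and rebalance to conserve the total.

    Constraints whose cell definition pins an arthritis analysis group
    (``group`` in FT_arth / PT_arth / NILF_arth) are scaled by
    ``multiplier`` (default: the benchmark's own trend multiplier); other
    ``group`` cells are scaled by the complementary factor so the year's
    population total is conserved exactly. Non-group constraints (age-sex,
    marginals) are left untouched.
    """
    m = benchmark.trend_multiplier if multiplier is None else multiplier
    if m < 0:
        raise ValueError("multiplier must be non-negative")
    arth = {"FT_arth", "PT_arth", "NILF_arth"}
    group_cons = [c for c in benchmark.constraints if set(c.where) == {"group"}]
    arth_cons = [c for c in group_cons if c.where["group"] in arth]
    rest_cons = [c for c in group_cons if c.where["group"] not in arth]
    arth_total = sum(c.target for c in arth_cons)
    rest_total = sum(c.target for c in rest_cons)
    grand = arth_total + rest_total
    new_arth = arth_total * m
    if new_arth > grand and rest_total > 0:
        raise ValueError("trend multiplier drives non-arthritis cells negative")
    rebal = (grand - new_arth) / rest_total if rest_total > 0 else 1.0
    if rebal < 0:
        raise ValueError("trend multiplier drives non-arthritis cells negative")

    new_constraints = []
    for c in benchmark.constraints:
        if c in arth_cons:
            new_constraints.append(Constraint(c.name, c.where, c.target * m))
        elif c in rest_cons:
            new_constraints.append(Constraint(c.name, c.where, c.target * rebal))
        else:
            new_constraints.append(c)
    return BenchmarkSet(
        year=benchmark.year,
        population_total=benchmark.population_total,
        constraints=new_constraints,
        trend_multiplier=m,
    )
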