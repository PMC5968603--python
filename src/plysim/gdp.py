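"""GDP impact of missing workers.

Converts counts of workers missing from the labour force into lost GDP by
an average-product attribution: each missing full-time worker forgoes one
full-time-equivalent (FTE) worker-year of GDP, each part-time worker a
configurable fraction of one, valued at GDP per FTE in the year. The
potential percentage gain in GDP is the ratio of lost to projected GDP.
"""

from __future__ import annotations

import pandas as pd

from . import scenario

__all__ = ["compute_gdp_loss", "pct_gain", "gdp_per_fte", "gdp_impact_table"]


def compute_gdp_loss(
    missing_ft: float,
    missing_pt: float,
    gdp_per_fte_value: float,
    pt_fte_factor: float = 0.5,
) -> float:
    """Lost GDP in AU$ millions from missing worker counts.

    ``gdp_per_fte_value`` is AU$ per FTE worker-year; part-time workers
    count as ``pt_fte_factor`` of an FTE.
    """
    if missing_ft < 0 or missing_pt < 0 or gdp_per_fte_value < 0:
        raise ValueError("inputs must be non-negative")
    if not 0.0 < pt_fte_factor <= 1.0:
        raise ValueError("pt_fte_factor must be in (0, 1]")
    return gdp_per_fte_value * (missing_ft + pt_fte_factor * missing_pt) / 1e6


def pct_gain(lost_gdp: float, projected_gdp: float) -> float:
    """Lost GDP as a percentage of projected GDP, to 2 decimals
    (rounded half away from zero)."""
    if projected_gdp <= 0:
        raise ValueError("projected GDP must be positive")
    x = lost_gdp / projected_gdp * 100.0
    scaled = x * 100.0
    rounded = int(scaled + 0.5) if scaled >= 0 else -int(-scaled + 0.5)
    return rounded / 100.0


def gdp_per_fte(year: int) -> float:
    """Scenario GDP per FTE worker-year, grown from the 2015 level at the
    assumed real productivity growth rate."""
    return scenario.GDP_PER_FTE_2015 * (1.0 + scenario.PRODUCTIVITY_GROWTH) ** (year - 2015)


def gdp_impact_table(
    missing_workers: dict,
    projected_gdp: dict | None = None,
    pt_fte_factor: float = 0.5,
) -> pd.DataFrame:
    """Year-by-year GDP impact table.

    Parameters
    ----------
    missing_workers : dict
        ``{year: (missing_ft, missing_pt)}`` worker counts.
    projected_gdp : dict, optional
        ``{year: AU$ millions}``; defaults to the scenario series.
    """
    projected_gdp = projected_gdp or scenario.PROJECTED_GDP
    rows = []
    for year, (ft, pt) in sorted(missing_workers.items()):
        lost = compute_gdp_loss(ft, pt, gdp_per_fte(year), pt_fte_factor)
        proj = projected_gdp[year]
        rows.append(
            {
                "year": year,
                "projected_gdp": proj,
                "missing_ft": ft,
                "missing_pt": pt,
                "lost_gdp": lost,
                "pct_gain": pct_gain(lost, proj),
            }
        )
    return pd.DataFrame(rows)
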