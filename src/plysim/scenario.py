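"""Default projection scenario: Australians aged 45-64, 2015-2030.

This module holds the fixed quantities that define the package's default
study conditions: projection-year population totals, labour-force group
shares, the 2015 monetary anchors (weekly income, welfare and tax by
group, in real 2013 AU$) the synthetic generator is calibrated to, and
the externally-given macroeconomic series (projected GDP, missing-worker
counts) consumed by the GDP module.

Monetary anchors are week-level statistics for five analysis groups formed
by crossing labour-force status with arthritis (ICD-10 M00-M19) as the
main chronic condition. The three residual categories (unemployed, not in
the labour force for other reasons, and out of the labour force through
ill-health with a non-arthritis main condition) complete the population
but are not separately costed.
"""

from __future__ import annotations

YEARS = (2015, 2020, 2025, 2030)

#: Weighted population aged 45-64 per projection year.
POPULATION = {
    2015: 5_945_000,
    2020: 6_374_000,
    2025: 6_677_000,
    2030: 7_130_000,
}

#: The five costed analysis groups, in reporting order.
REPORTED_GROUPS = ("FT_no_arth", "FT_arth", "PT_no_arth", "PT_arth", "NILF_arth")

#: Residual categories completing the population.
RESIDUAL_GROUPS = ("unemployed", "NILF_other", "NILF_ill_other")

GROUPS = REPORTED_GROUPS + RESIDUAL_GROUPS

# Group shares of the weighted population per projection year. The five
# reported shares follow the scenario reference paths; unemployment is
# held at 2.0% (the value implied by the 2015 full-time destination share
# of 71.68% among the non-arthritis active population) and the
# ill-health-other-condition share at 2.0%; NILF_other absorbs the rest.
_REPORTED_SHARES = {
    2015: (0.4898, 0.0516, 0.1736, 0.0313, 0.0091),
    2020: (0.4972, 0.0532, 0.1811, 0.0327, 0.0091),
    2025: (0.4996, 0.0537, 0.1894, 0.0333, 0.0088),
    2030: (0.5049, 0.0531, 0.1879, 0.0331, 0.0085),
}
_UNEMPLOYED_SHARE = 0.020
_NILF_ILL_OTHER_SHARE = 0.020

GROUP_SHARES = {
    year: dict(
        zip(REPORTED_GROUPS, shares),
        unemployed=_UNEMPLOYED_SHARE,
        NILF_ill_other=_NILF_ILL_OTHER_SHARE,
        NILF_other=round(1.0 - sum(shares) - _UNEMPLOYED_SHARE - _NILF_ILL_OTHER_SHARE, 6),
    )
    for year, shares in _REPORTED_SHARES.items()
}

#: 2015 anchor statistics per reported group: {outcome: (mean, sd, median)}
#: in AU$/week at real 2013 prices.
ANCHOR_2015 = {
    "FT_no_arth": {
        "income": (1597.29, 1558.02, 1308.88),
        "welfare": (18.27, 62.34, 0.00),
        "tax": (353.62, 488.20, 243.18),
    },
    "FT_arth": {
        "income": (1366.59, 1116.91, 1180.65),
        "welfare": (19.92, 71.13, 0.00),
        "tax": (278.53, 358.89, 184.99),
    },
    "PT_no_arth": {
        "income": (722.14, 794.20, 602.86),
        "welfare": (73.41, 140.41, 0.00),
        "tax": (84.29, 203.91, 19.08),
    },
    "PT_arth": {
        "income": (597.41, 551.25, 551.77),
        "welfare": (100.13, 162.92, 0.00),
        "tax": (49.73, 118.28, 0.00),
    },
    "NILF_arth": {
        "income": (334.06, 148.69, 321.87),
        "welfare": (305.51, 158.51, 311.67),
        "tax": (-0.16, 6.79, 0.00),
    },
}

#: Income medians assumed for the residual categories (AU$/week, 2015 level).
RESIDUAL_INCOME_MEDIANS = {
    "unemployed": 330.0,
    "NILF_other": 400.0,
    "NILF_ill_other": 321.87,
}

#: Disability-pension-style flat weekly payment rate; the NILF-arthritis
#: welfare median anchor.
DSP_RATE = 311.67

#: Unemployment-benefit-style flat weekly payment rate.
UNEMPLOYMENT_BENEFIT = 255.0

#: Projected GDP per year, AU$ millions at real 2013 prices (externally given).
PROJECTED_GDP = {
    2015: 1_483_861,
    2020: 1_678_852,
    2025: 1_899_467,
    2030: 2_149_073,
}

#: Externally-given missing-worker series (full- plus part-time) used by the
#: GDP scenario table. Kept distinct from the pipeline's own lost-PLY
#: headcounts, which are computed from the microdata.
MISSING_WORKERS = {
    2015: 53_000,
    2020: 56_000,
    2025: 58_000,
    2030: 59_000,
}

#: Average-product GDP attribution: GDP per full-time-equivalent worker-year
#: in 2015 (real 2013 AU$) and its assumed real growth rate per annum.
GDP_PER_FTE_2015 = 135_000.0
PRODUCTIVITY_GROWTH = 0.0117

#: Arthritis prevalence trend multipliers relative to 2015, derived from the
#: arthritis group-share paths above.
def arthritis_trend_multiplier(year: int) -> float:
    def arth_share(y):
        s = GROUP_SHARES[y]
        return s["FT_arth"] + s["PT_arth"] + s["NILF_arth"]

    return arth_share(year) / arth_share(2015)
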