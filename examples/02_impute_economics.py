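"""Hot-deck imputation of economic profiles onto the survey.

Each survey person is matched to a donor on ten categorical variables
(labour-force status, income-unit type, income quintile, pension flags,
sex, age band, hours band, education, home ownership); the donor's weekly
earnings, other income, welfare and tax are copied over. Empty cells fall
back by dropping variables one at a time, never the labour-force status.
"""

from plysim import GeneratorConfig, generate_donor_pool, generate_survey, impute_economics, summarize_groups

cfg = GeneratorConfig()
survey = generate_survey(cfg)
donors = generate_donor_pool(cfg)
imputed, audit = impute_economics(survey, donors, seed=11)

depths = audit["fallback_depth"].value_counts().sort_index()
print("fallback depth distribution (0 = exact ten-variable cell):")
for depth, count in depths.items():
    print(f"  depth {depth}: {count} recipients ({count / len(audit):.1%})")

summary = summarize_groups(imputed).set_index("group")
print(
    f"\nimputed NILF-arthritis welfare median: {summary.loc['NILF_arth', 'welfare_median']:.2f}"
    f"\nimputed NILF-arthritis income median:  {summary.loc['NILF_arth', 'income_median']:.2f}"
)
print(
    "\nExact-cell matching preserves within-cell distributions, so the"
    "\nimputed group medians reproduce the donor pool's calibration targets."
)
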