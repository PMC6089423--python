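"""Sample a synthetic multi-country engagement survey and inspect it.

The packaged ground-truth model emulates a 25,530-respondent survey of
older adults in 11 countries, with questionnaire skip patterns
(INELIGIBLE) and small random missingness (MISSING). Here we draw a
reduced cohort and look at data quality for a few items.
"""

from engagenet import (GeneratorConfig, default_ihps_model, sample_survey,
                       variable_report)

model = default_ihps_model()
table = sample_survey(model, GeneratorConfig(n_respondents=5000, seed=1))

print(f"table: {table.shape[0]} respondents x {table.shape[1]} variables\n")
report = variable_report(table)
items = ["CC_contacted", "SP_Involvement", "SP_What_matters",
         "SP_Family_involved", "Country"]
print(report.loc[items, ["prop_ineligible", "prop_missing"]].round(3))
print("""
prop_ineligible is the share of respondents the questionnaire never
asked (skip patterns: ~28% for chronic-care items, ~43% for
specialist-care items, ~97% for the Netherlands-only item);
prop_missing is refusal-type missingness among those actually asked.
""")
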