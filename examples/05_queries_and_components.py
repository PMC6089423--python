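"""Fit CPTs on the true structure and answer conditional queries.

Reproduces the pipeline's headline numbers: the probability that a
patient has a feasible treatment plan given that professionals did (or
did not) provide a written plan, and the component structure of the
network ("separate networks").
"""

from engagenet import (GeneratorConfig, components, default_ihps_model,
                       fit_cpts, query, sample_survey)

model = default_ihps_model()
table = sample_survey(model, GeneratorConfig(25_530, seed=1))
fitted = fit_cpts(table, model.analysis_dag(), model.meta)

p_yes = query(fitted, ("CC_Feasible_plan", "Yes"), {"CC_Written_plan": "Yes"})
p_no = query(fitted, ("CC_Feasible_plan", "Yes"), {"CC_Written_plan": "No"})
print(f"P(feasible plan | written plan)     = {100 * p_yes:.1f}%")
print(f"P(feasible plan | no written plan)  = {100 * p_no:.1f}%")

summary = components(model.analysis_dag())
print(f"\nseparate networks: {summary.n_networks} "
      f"({summary.n_variables_in_networks} connected variables)")
print(f"component sizes: {sorted(summary.sizes, reverse=True)}")
print(f"isolated: {', '.join(summary.isolated)}")
print("""
The two probabilities estimate the planted values 82.7% and 47.9%:
patients given a written plan are far more likely to have a plan they
can carry out day to day. The graph decomposes into 19 separate
networks over 66 variables (largest: 8), with the Sweden-only
family-involvement item unconnected.
""")
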