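# engagenet

Bayesian-network analysis of categorical patient-engagement survey
data: who gets engaged in their own care, and which survey measures of
engagement hang together?

Large multi-country health-policy surveys measure patient engagement
with a handful of categorical items — did specialists offer treatment
choices, were patients given a written care plan, could they reach a
professional between visits — alongside demographics and care
experience. Regression forces one item to be "the outcome";
`engagenet` instead learns a discrete Bayesian network over all items
at once, so the analyst sees which variables are directly linked,
which are conditionally independent, and which "separate networks"
the survey decomposes into. It is written for biostatisticians and
health-services researchers working with layered categorical survey
data containing questionnaire skip patterns.

## What it does

For a respondent-by-variable categorical table with per-variable
metadata (levels, ordinal ranks, layer, eligibility gate, exclusion
flag):

1. **Cleaning** — refusal answers → `MISSING`; skip-pattern gates →
   `INELIGIBLE`; expert-excluded variables dropped. Analysis is
   available-case: each statistic uses rows complete on exactly the
   variables involved.
2. **Structure learning** — Max-Min Hill-Climbing (MMHC): MMPC
   skeleton discovery with stratified G² conditional-independence
   tests (α = 0.05, conditioning sets ≤ 3), then BIC hill climbing
   restricted to the skeleton. Expert *layering* blacklists every arc
   from a care-experience variable into a socio-demographic one.
3. **Bootstrap averaging** — the learner re-runs on row resamples
   (default 200); an arc's *strength* is its presence fraction, its
   *direction* the majority orientation. The consensus network keeps
   arcs above an L1-CDF-estimated (or fixed) threshold.
4. **Parameters & queries** — per-node CPTs by maximum likelihood
   (optional pseudocount); exact conditional probabilities by
   enumeration within a connected component; component summary
   ("separate networks", isolated variables).
5. **Export** — DAG JSON, arc-strength TSV, DOT and GraphML with
   |Spearman ρ| arc weights and engagement-class colours.

A seeded synthetic generator (`default_ihps_model`) emulates a 2014
survey of 25,530 older adults in 11 countries — planted DAG with 19
components (largest: 8 variables), skip-pattern ineligibility (28.4%
chronic-care, 42.6% specialist-care, 97.5%/85.5% single-country
items), and 0.04–2.1% random missingness — so the entire pipeline runs
and is validated with no external data.

## Worked example

```python
from engagenet import (GeneratorConfig, default_ihps_model, sample_survey,
                       fit_cpts, query, components)

model = default_ihps_model()
table = sample_survey(model, GeneratorConfig(n_respondents=25_530, seed=1))
fitted = fit_cpts(table, model.analysis_dag(), model.meta)

print(query(fitted, ("CC_Feasible_plan", "Yes"), {"CC_Written_plan": "Yes"}))
print(query(fitted, ("CC_Feasible_plan", "Yes"), {"CC_Written_plan": "No"}))
print(components(model.analysis_dag()).n_networks)
```

prints

```
0.8347826086956522
0.4781766093697337
19
```

— a respondent whose professionals provided a written care plan has an
83.5% estimated probability of having a treatment plan they can carry
out in daily life, versus 47.8% without one (the planted values are
82.7% and 47.9%; the gap is binomial sampling error at this cohort
size), and the planted graph decomposes into 19 separate networks.
The scripts in `examples/` walk through each capability end to end;
`python examples/04_bootstrap_averaging.py` shows arc strengths and
the consensus network on a 9-variable subproblem.

A thin CLI mirrors the stages:

```bash
engagenet simulate --n 25530 --seed 1 --out data.csv --meta meta.json
engagenet clean    --in data.csv --meta meta.json --out clean.csv --report report.tsv
engagenet average  --in clean.csv --meta meta.json --nboot 200 --seed 1 \
                   --out avg.json --arcs arcs.tsv
engagenet fit      --in clean.csv --meta meta.json --dag avg.json --out fitted.json
engagenet query    --model fitted.json --target "CC_Feasible_plan=Yes" \
                   --given "CC_Written_plan=Yes"
```

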