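# Methods

`engagenet` implements a discrete Bayesian-network analysis of
categorical patient-engagement survey data, together with a synthetic
survey generator carrying a planted ground truth against which every
pipeline stage is validated.

## Model

A survey of `p` categorical variables is modelled as a Bayesian
network: a directed acyclic graph (DAG) `G` over the variables plus,
for each variable `X` with parent set `Pa(X)`, a conditional
probability table (CPT) `P(X | Pa(X))`. The joint distribution
factorises as `P(X₁,…,Xₚ) = Π P(Xᵢ | Pa(Xᵢ))`. Arcs encode conditional
dependence, not causation: the data are observational and
cross-sectional, and arc directions in an averaged network are
consensus orientations, nothing stronger.

Expert knowledge enters in two config-driven forms only:

* a **variable-exclusion ledger** (administrative, redundant,
  country-specific or unharmonizable items never reach modelling), and
* **layering / blacklisting**: layer-1 variables (country, sex, age
  band, education — socio-demographics and health-system descriptors)
  may not receive arcs from layer-2 care-experience variables. Every
  ordered pair (layer-2 → layer-1) is blacklisted; nothing is
  whitelisted.

## Missingness and ineligibility

Two sentinels are distinguished. `MISSING` is refusal-type
non-response ("don't know", "not sure", "refused", "decline to
answer", recoded case-insensitively). `INELIGIBLE` is structural:
the questionnaire skip pattern never asked the question (no specialist
seen, no chronic condition, single-country items). Eligibility is a
per-variable *gate* — a boolean expression over other columns; rows
failing the gate become INELIGIBLE, rows whose gate inputs are MISSING
become MISSING (eligibility undetermined).

Analysis uses **available-case (test-wise) deletion**: every
contingency table and every local score uses exactly the rows complete
on the variables involved, with INELIGIBLE treated like MISSING by
default (a config switch can promote INELIGIBLE to an explicit level).
Rationale: items asked in a single country are ~97% ineligible;
listwise deletion would discard essentially the whole sample, whereas
available-case analysis lets such items join the network through their
~600 observed rows. A pair of items observed on disjoint row sets is
*untestable*: it is reported as such and yields no edge, which is also
how structurally disconnected single-country items stay disconnected.

## Independence tests

The skeleton-discovery test is the stratified G² (log-likelihood
ratio) test: `G² = 2 Σ O ln(O/E)` summed within each configuration of
the conditioning set, with `E` from within-stratum margins and
`0·ln 0 := 0`. `G²` equals `2N` times the conditional mutual
information in nats, which the test suite verifies against an
independent entropy-based oracle. Degrees of freedom default to
`(|X|−1)(|Y|−1)·Π|Z|`; an adjusted-df mode drops structurally empty
rows/columns per stratum. Pearson X² is available by flag. α = 0.05,
two-tailed, everywhere, with no multiple-testing correction inside the
constraint phase (canonical behaviour for this algorithm family).
Descriptive statistics use Spearman's rank correlation on mid-ranks
(levels without a rank, e.g. "Not applicable" on a frequency scale,
are excluded) and one-way ANOVA for ordinal-coded comparisons.

## Structure learning (MMHC)

Learning is the hybrid Max-Min Hill-Climbing scheme:

1. **MMPC** per target `T`: the forward phase repeatedly admits the
   candidate maximising the *minimum* association (1 − p, ties by
   larger statistic) over conditioning subsets of the current
   candidate-parents-children set (size ≤ `max_cond`, default 3), and
   permanently dismisses any candidate found independent given some
   tested subset; it stops when the best max-min association is
   non-significant. The backward phase prunes members independent
   given a subset of the rest. An edge survives only with AND-symmetry
   (`X ∈ PC(T)` and `T ∈ PC(X)`). Pairs blacklisted in both directions
   are never tested.
2. **Hill climbing** from the empty graph, restricted to skeleton
   edges: the single best strictly-score-improving move among arc
   additions (not blacklisted, acyclic), deletions and reversals is
   applied until a local optimum. The score is the decomposable BIC
   for discrete networks, `Σ N(x,pa)·ln(N(x,pa)/N(pa)) −
   (ln n)/2 · q·(k−1)` per family on the rows complete on that family
   (BDeu with equivalent sample size 1 by flag). Ties break by gain,
   then lexicographic (from, to), then move type add < reverse <
   delete, so a run is bit-for-bit reproducible.

α, the score family and `max_cond` are not dictated by the analysis
this package systematises; the defaults mirror the canonical
implementation of the algorithm and are all exposed in `RunConfig` and
logged per run.

## Bootstrap averaging

Arc stability is assessed by nonparametric bootstrap (default 200
replicates; the heavy validation suite uses 50 for runtime, a
documented flag): rows are resampled with replacement to the original
`n`, the learner re-run identically, and each unordered pair's
**strength** is its presence fraction across replicates; **direction**
is the orientation fraction among presence replicates. The consensus
network keeps pairs with strength strictly above a threshold, orients
by majority (exact ties: lexicographic, flagged), never emits a
blacklisted orientation (flipped if the legal direction was ever
observed, else dropped), and repairs any directed cycle by removing
the weakest included arc *on a cycle* (ties: smaller direction
confidence, then lexicographic). Dropping only on-cycle arcs is
deliberate: removing an off-cycle arc cannot restore acyclicity.

The default threshold is estimated from the strength distribution: the
cut minimising the L1 distance between the empirical CDF of strengths
and the ideal noise-free CDF in which strengths are exactly 0 or 1.
Candidate cuts are midpoints between consecutive distinct observed
strengths, so the estimate separates clusters strictly; if all
strengths are equal the common value minus machine epsilon is returned
(flagged) so that strict `>` admits every arc. A fixed threshold
(e.g. 0.5) is available.

## Parameters and queries

CPTs are maximum-likelihood estimates on family-complete rows,
`P̂(x|pa) = (N(x,pa)+c)/(N(pa)+c·k)` with uniform pseudocount `c`
(default 0). Parent configurations never observed are flagged
`no_data` (uniform fallback when smoothed). Queries are exact:
the joint over the target's connected component is assembled by factor
broadcasting, evidence axes sliced, the rest marginalised. Evidence
outside the component is ignored because the joint factorises across
components; components here never exceed a dozen or so variables, so
enumeration is well within budget. "Separate networks" are connected
components (ignoring direction) with ≥ 2 variables; isolated variables
are reported separately.

## The synthetic generator

The generator emulates the structure of a 2014 multi-country health
policy survey of adults 55+: 25,530 respondents in 11 countries with
the published per-country sample sizes, layer-1 demographics (country;
sex at 57.4% female; a 4-level age band — the pipeline is
discrete-only, so age enters as an ordinal band; college education at
the published per-country rates), and 67 layer-2/layer-1 analysis
variables whose planted graph has 19 connected components — one of 8
variables, eight of 4, six of 3 and four of 2 (66 connected variables)
— plus one isolated Sweden-only engagement item. The three components
documented in the source material (the chronic-illness-care chain
`CC_Instruction → {CC_Written_plan, Healthy_diet}`,
`CC_Written_plan → CC_Feasible_plan → CC_Helpful_plan`; the
specialist-care chain `SP_Rx_choice → SP_Involvement →
SP_What_matters → CC_confidence`; and `CC_contacted →
CC_DR_for_question`) are planted as published; the membership of the
remaining sixteen components is a fixed, documented fabrication — only
the size multiset is a modelling target.

Sampling proceeds in topological order from the planted CPTs; gate
predicates then mask structurally unasked cells to INELIGIBLE
(chronic-care items 28.4%, specialist-care items 42.6%, the
Netherlands-only follow-up block 97.5%, the Sweden-only item 85.5%),
and eligible cells are independently replaced by MISSING at per-item
rates between 0.04% and 2.1%. Everything is deterministic given the
seed (one `numpy` generator drives sampling and masking in a fixed
order).

Deliberate deviations from the emulated survey's printed ineligibility
column, both forced by learnability under available-case analysis:
the plan-helpfulness item is gated on chronic-care eligibility (28.4%)
rather than on having a feasible plan (which would fix its parent's
value among all jointly observed rows and make the planted arc
formally unrecoverable), and the confidence item shares the
Netherlands gate of its parent (97.5% vs the printed 97.2%) so the
pair is jointly observed on ~640 rows.

The headline planted probabilities are
`P(CC_Feasible_plan=Yes | CC_Written_plan=Yes) = 0.827` and
`P(... | CC_Written_plan=No) = 0.479`; `P(CC_Written_plan=Yes)` is
calibrated so the marginal share with a feasible plan among eligible
respondents is ≈ 0.595 (42.6% of the full cohort). All other planted
CPTs are strong dependencies — typically a total-variation distance of
≥ 0.25 between parent configurations — chosen so that arcs which
survived a 200-replicate bootstrap in the emulated analysis are
reliably recoverable at n ≈ 25,530. Where printed per-country rates
are used (college education), the published values override the
strength target.

What the generator does **not** emulate: complex survey design and
weights, per-country marginals beyond the cited rates, informative
missingness (missingness is independent of the latent response),
response-order effects, and any continuous measurement. Passing tests
therefore demonstrate correctness of the algorithms under a
well-specified discrete factorised truth — not robustness to the
messiness of real survey microdata.

## Numerical and performance notes

* Counting kernels (joint counts, stratified G²/X²) are
  numba-compiled over an int8 code matrix (sentinels = −1), scanned
  rarest-observed-column first; chi-square p-values use the
  regularised incomplete gamma directly. The pure-numpy DataFrame
  implementations in `citests` are the reference path; a test asserts
  both paths agree to 1e-10.
* Bootstrap replicates are substantially more expensive to learn on
  than the original table: resampling noise inflates null
  associations, roughly doubling the variance of test statistics, so
  canonical MMPC admits many more transient candidates per target.
  This is inherent to bootstrapping constraint-based learners, not a
  defect of the data.
* Hill climbing accepts a move only if its gain exceeds 1e-9, guarding
  against floating-point ties producing non-terminating loops.
* CPT rows must sum to 1 within 1e-9; query normalisation is asserted
  to the same tolerance.
* Validation problem sizes: component-level checks run at n in the
  thousands; full-pipeline recovery runs once at the emulated cohort
  size (n = 25,530) with 50 bootstrap replicates.

## Known limitations

* No whitelist support beyond validation (the emulated analysis used
  none); no tabu search, restarts, or approximate inference; no
  imputation; no survey weights.
* The significance-threshold estimator assumes a roughly bimodal
  strength distribution; on tiny replicate counts it can sit inside a
  diffuse cluster (the fixed-threshold mode is the remedy).
* With available-case deletion, families mixing variables of very
  different eligibility use different effective sample sizes; BIC
  penalties are per-family and not jointly normalised across
  families.
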