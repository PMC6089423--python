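"""Synthetic multi-country patient-engagement survey generator.

The packaged ground-truth model emulates the structure of the 2014
multi-country health-policy survey of older adults the pipeline is
designed for: 25,530 respondents across 11 countries, layer-1
socio-demographics (country, sex, age band, college education), layer-2
care-experience items, questionnaire skip patterns that leave large
blocks of respondents structurally INELIGIBLE (specialist-care items
42.6%, chronic-care items 28.4%, single-country items 97.5% / 85.5%),
and small per-item random missingness (0.1–2.1%).

The planted dependency graph over the 67 analysis variables has 19
connected components of sizes {8, 4 x 8, 3 x 6, 2 x 4} (66 connected
variables) plus one isolated engagement item (``SP_Family_involved``).
Every downstream stage — cleaning, independence testing, MMHC structure
learning, bootstrap averaging, CPT fitting and queries — is tested
against this planted truth. Component membership outside the three
documented engagement components is a fabricated-but-fixed layout; only
the size multiset is a modelling target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gates import Gate
from .metadata import VariableMeta, meta_index
from .sentinels import INELIGIBLE, MISSING

YES_NO = ("Yes", "No")
FREQ5 = ("Always", "Often", "Sometimes", "Rarely or never", "Not applicable")
FREQ4 = ("Always", "Often", "Sometimes", "Rarely or never")
#: "Not applicable" carries no rank: it is dropped from rank correlations.
#: Ranks increase with *infrequency* so they follow the listed order.
FREQ5_RANKS = {"Always": 1, "Often": 2, "Sometimes": 3, "Rarely or never": 4}
TALK3 = ("Yes", "No", "No doctor visit")

COUNTRIES = (
    "Australia", "Canada", "France", "Germany", "Netherlands", "New Zealand",
    "Norway", "Sweden", "Switzerland", "United Kingdom", "United States",
)
#: Per-country sample sizes of the emulated survey (total 25,530).
COUNTRY_N = (3310, 5269, 1500, 928, 1000, 750, 1000, 7206, 1812, 1000, 1755)
#: Per-country share with at least some college education.
COLLEGE_BY_COUNTRY = (
    0.564, 0.530, 0.491, 0.452, 0.252, 0.535, 0.513, 0.406, 0.285, 0.354, 0.632,
)

DEFAULT_N = 25_530


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class CPT:
    """Conditional probability table of one node given its DAG parents.

    ``table`` has one row per parent configuration (row-major over
    ``parents``, first parent varying slowest) and one column per level.
    """

    var: str
    levels: tuple[str, ...]
    parents: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        expected = int(np.prod([len(p) for p in self.parent_levels], initial=1))
        table = np.asarray(self.table, dtype=float)
        if table.shape != (expected, len(self.levels)):
            raise ModelError(
                f"{self.var}: CPT shape {table.shape} != ({expected}, {len(self.levels)})"
            )
        if np.any(table < 0) or np.any(np.abs(table.sum(axis=1) - 1.0) > 1e-9):
            raise ModelError(f"{self.var}: CPT rows must be probabilities summing to 1")
        object.__setattr__(self, "table", table)

    def row(self, assignment: dict[str, str]) -> np.ndarray:
        """Probability row for one fully-specified parent assignment."""
        idx = self.config_index(
            tuple(assignment[p] for p in self.parents)
        )
        return self.table[idx]

    def config_index(self, parent_values: tuple[str, ...]) -> int:
        idx = 0
        for value, levels in zip(parent_values, self.parent_levels):
            idx = idx * len(levels) + levels.index(value)
        return idx

    def configs(self):
        """Iterate (parent-assignment dict, probability row) pairs."""
        import itertools

        for values in itertools.product(*self.parent_levels) if self.parents else [()]:
            yield dict(zip(self.parents, values)), self.table[self.config_index(values)]


@dataclass
class GroundTruthModel:
    """Planted generator: DAG + CPTs + eligibility gates + missingness."""

    dag: nx.DiGraph
    cpts: dict[str, CPT]
    meta: list[VariableMeta]
    missing_rates: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return [m.name for m in self.meta]

    def analysis_dag(self) -> nx.DiGraph:
        """Planted graph restricted to non-excluded analysis variables."""
        keep = [m.name for m in self.meta if not m.excluded]
        return self.dag.subgraph(keep).copy()

    def sampling_order(self) -> list[str]:
        """Topological order including gate-reference precedence edges."""
        order_graph = self.dag.copy()
        for m in self.meta:
            if m.gate is not None:
                for ref in m.gate.variables:
                    if ref != m.name:
                        order_graph.add_edge(ref, m.name)
        try:
            return list(nx.topological_sort(order_graph))
        except nx.NetworkXUnfeasible as exc:
            raise ModelError("cyclic eligibility: gates and arcs form a cycle") from exc

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        index = meta_index(self.meta)
        if set(self.dag.nodes) != set(index):
            raise ModelError("DAG nodes and metadata variables differ")
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ModelError("planted graph has a directed cycle")
        for var, cpt in self.cpts.items():
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.dag.predecessors(var))):
                raise ModelError(f"{var}: CPT parents disagree with DAG")
            if cpt.levels != index[var].levels:
                raise ModelError(f"{var}: CPT levels disagree with metadata")
        missing_cpts = set(index) - set(self.cpts)
        if missing_cpts:
            raise ModelError(f"variables without CPTs: {sorted(missing_cpts)}")
        for u, v in self.dag.edges:
            if index[u].layer == 2 and index[v].layer == 1:
                raise ModelError(f"layer-2 variable {u} is a parent of layer-1 {v}")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise ModelError(f"{name}: missing rate {rate} outside [0, 1)")
        self.sampling_order()  # raises on circular eligibility


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling knobs: cohort size and seed."""

    n_respondents: int = DEFAULT_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")


# ---------------------------------------------------------------------
# Packaged default model
# ---------------------------------------------------------------------


def _rows(*rows: tuple[float, ...]) -> np.ndarray:
    return np.array(rows, dtype=float)


def _yes(*p_yes: float) -> np.ndarray:
    return np.array([[p, 1.0 - p] for p in p_yes], dtype=float)


def default_ihps_model() -> GroundTruthModel:
    """The packaged ground-truth survey model.

    Returns the fixed model described in the module docstring. Planted
    dependencies are strong (typical total-variation distance between
    parent configurations >= 0.25) so that structure recovery at the
    emulated cohort size is reliable; the feasible-plan CPT plants the
    documented conditional probabilities 0.827 / 0.479 given a written
    plan / no written plan.
    """
    spec: list[dict] = []

    def add(name, levels, parents=(), table=None, *, layer=2, gate=None,
            ordinal=False, ranks=None, missing=0.0, excluded=False,
            reason=None, engagement=None, color=None):
        spec.append(dict(
            name=name, levels=tuple(levels), parents=tuple(parents),
            table=table, layer=layer, gate=gate, ordinal=ordinal,
            ranks=ranks, missing=missing, excluded=excluded, reason=reason,
            engagement=engagement, color=color,
        ))

    # --- layer-1 socio-demographics ----------------------------------
    country_p = np.array(COUNTRY_N, dtype=float) / sum(COUNTRY_N)
    add("Country", COUNTRIES, table=country_p[None, :], layer=1)
    add("Sex", ("Female", "Male"), table=_rows((0.574, 0.426)), layer=1)
    add("Age_band", ("55-59", "60-64", "65-74", "75+"),
        table=_rows((0.28, 0.26, 0.28, 0.18)), layer=1, ordinal=True)
    add("College", YES_NO, parents=("Country",),
        table=_yes(*COLLEGE_BY_COUNTRY), layer=1)

    # --- eligibility-gate auxiliaries (kept in the table, excluded
    # from structure learning) ----------------------------------------
    gate_reason = "eligibility-gate auxiliary (administrative)"
    add("in_chronic_care", YES_NO, table=_yes(0.716),
        excluded=True, reason=gate_reason)
    add("saw_specialist", YES_NO, table=_yes(0.574),
        excluded=True, reason=gate_reason)
    # Netherlands-only specialist follow-up block: 2.5% of the cohort.
    add("nl_specialist_followup", YES_NO, parents=("saw_specialist",),
        table=_yes(0.025 / 0.574, 0.0), excluded=True, reason=gate_reason)
    # Sweden-only family-involvement item: 14.5% of the cohort.
    add("sweden_specialist", YES_NO, parents=("saw_specialist",),
        table=_yes(0.145 / 0.574, 0.0), excluded=True, reason=gate_reason)
    # Unharmonizable spending item, excluded by the expert ledger.
    add("Healthcare_spending", ("Low", "Mid", "High"),
        table=_rows((0.35, 0.40, 0.25)), excluded=True,
        reason="not harmonizable across countries")

    cc = "in_chronic_care == 'Yes'"
    sp = "saw_specialist == 'Yes'"
    nl = "nl_specialist_followup == 'Yes'"
    sw = "sweden_specialist == 'Yes'"

    # --- component 1 (8 nodes): chronic-illness-care engagement ------
    add("CC_Instruction", YES_NO, table=_yes(0.48), gate=cc, missing=0.013)
    add("CC_Written_plan", YES_NO, parents=("CC_Instruction",),
        table=_yes(0.50, 0.18), gate=cc, missing=0.013)
    # Planted headline probabilities: feasible plan given written plan.
    add("CC_Feasible_plan", YES_NO, parents=("CC_Written_plan",),
        table=_yes(0.827, 0.479), gate=cc, missing=0.012,
        engagement="shared decision-making", color="red")
    add("CC_Helpful_plan", ("Not at all", "Only a little", "Some", "A lot"),
        parents=("CC_Feasible_plan",),
        table=_rows((0.02, 0.06, 0.24, 0.68), (0.10, 0.25, 0.40, 0.25)),
        gate=cc, ordinal=True, missing=0.017,
        engagement="self-care and autonomy", color="orange")
    add("Healthy_diet", TALK3, parents=("CC_Instruction",),
        table=_rows((0.80, 0.15, 0.05), (0.45, 0.45, 0.10)), missing=0.005)
    add("Exercise", TALK3, parents=("CC_Instruction",),
        table=_rows((0.78, 0.17, 0.05), (0.42, 0.48, 0.10)), missing=0.005)
    add("Mental", YES_NO, parents=("CC_Instruction",),
        table=_yes(0.38, 0.12), missing=0.005)
    add("Stress_sources", TALK3, parents=("Healthy_diet",),
        table=_rows((0.55, 0.40, 0.05), (0.25, 0.65, 0.10), (0.05, 0.15, 0.80)),
        missing=0.007)

    # --- component 2 (4): specialist-care engagement chain -----------
    add("SP_Rx_choice", FREQ5, table=_rows((0.52, 0.20, 0.09, 0.11, 0.08)),
        gate=sp, ordinal=True, ranks=dict(FREQ5_RANKS), missing=0.012,
        engagement="shared decision-making", color="red")
    add("SP_Involvement", FREQ5, parents=("SP_Rx_choice",),
        table=_rows(
            (0.75, 0.13, 0.05, 0.04, 0.03),
            (0.35, 0.40, 0.13, 0.08, 0.04),
            (0.15, 0.30, 0.35, 0.15, 0.05),
            (0.08, 0.15, 0.25, 0.45, 0.07),
            (0.15, 0.10, 0.10, 0.15, 0.50),
        ),
        gate=sp, ordinal=True, ranks=dict(FREQ5_RANKS), missing=0.014,
        engagement="shared decision-making", color="red")
    add("SP_What_matters", FREQ5, parents=("SP_Involvement",),
        table=_rows(
            (0.70, 0.18, 0.06, 0.04, 0.02),
            (0.30, 0.45, 0.15, 0.07, 0.03),
            (0.12, 0.28, 0.40, 0.15, 0.05),
            (0.06, 0.12, 0.25, 0.50, 0.07),
            (0.12, 0.12, 0.12, 0.14, 0.50),
        ),
        gate=nl, ordinal=True, ranks=dict(FREQ5_RANKS), missing=0.001,
        engagement="critical self-knowledge", color="green")
    add("CC_confidence",
        ("Very confident", "Confident", "Not very confident", "Not at all confident"),
        parents=("SP_What_matters",),
        table=_rows(
            (0.70, 0.24, 0.05, 0.01),
            (0.35, 0.50, 0.12, 0.03),
            (0.15, 0.45, 0.30, 0.10),
            (0.05, 0.25, 0.40, 0.30),
            (0.20, 0.30, 0.30, 0.20),
        ),
        gate=nl, ordinal=True,
        ranks={"Very confident": 1, "Confident": 2,
               "Not very confident": 3, "Not at all confident": 4},
        missing=0.003)

    # --- components 3..9 (4 nodes each) -------------------------------
    # Country/age/education and self-rated health.
    health_offset = (0.12, 0.06, -0.04, -0.10, 0.05, 0.09, 0.03, -0.02,
                     0.15, -0.08, -0.15)
    rows = []
    for off in health_offset:
        for age_idx in range(4):
            good = min(max(0.58 + off - 0.11 * age_idx, 0.05), 0.90)
            fair = min(max(0.14 - off / 2 + 0.08 * age_idx, 0.05), 0.80)
            rows.append((good, 1.0 - good - fair, fair))
    add("Self_rated_health", ("Excellent/Very good", "Good", "Fair/Poor"),
        parents=("Country", "Age_band"), table=np.array(rows),
        ordinal=True,
        ranks={"Excellent/Very good": 1, "Good": 2, "Fair/Poor": 3},
        missing=0.002)

    add("Walking_difficulty", YES_NO, table=_yes(0.22), missing=0.003)
    add("Caregiver_role", YES_NO, parents=("Sex", "Walking_difficulty"),
        table=_yes(0.34, 0.62, 0.18, 0.42), missing=0.004)
    add("Home_help", YES_NO, parents=("Walking_difficulty",),
        table=_yes(0.55, 0.12), missing=0.004)

    add("Regular_Dr",
        ("Regular doctor", "Regular place", "No regular doctor/place"),
        table=_rows((0.78, 0.14, 0.08)), missing=0.001)
    add("Wait_GP", ("Same day", "2-5 days", "6+ days"),
        parents=("Regular_Dr",),
        table=_rows((0.45, 0.40, 0.15), (0.30, 0.40, 0.30), (0.12, 0.33, 0.55)),
        ordinal=True, missing=0.006)
    add("After_hours", YES_NO, parents=("Regular_Dr",),
        table=_yes(0.62, 0.45, 0.20), missing=0.008)
    add("ER_visit", YES_NO, parents=("After_hours",),
        table=_yes(0.18, 0.44), missing=0.004)

    add("High_BP", YES_NO, table=_yes(0.41), missing=0.004)
    add("Heart_disease", YES_NO, parents=("High_BP",),
        table=_yes(0.27, 0.065), missing=0.006)
    add("BP_check", YES_NO, parents=("High_BP",),
        table=_yes(0.93, 0.61), missing=0.003)
    add("Cholesterol_check", YES_NO, parents=("BP_check",),
        table=_yes(0.82, 0.38), missing=0.003)

    add("Diabetes", YES_NO, table=_yes(0.136), missing=0.005)
    add("Foot_exam", YES_NO, parents=("Diabetes",),
        table=_yes(0.64, 0.09), missing=0.006)
    add("Eye_exam", YES_NO, parents=("Diabetes",),
        table=_yes(0.76, 0.37), missing=0.006)
    add("HbA1c_test", YES_NO, parents=("Diabetes",),
        table=_yes(0.81, 0.12), missing=0.007)

    add("Insurance_extra", YES_NO, table=_yes(0.47), missing=0.009)
    add("Cost_skipped_care", YES_NO, parents=("Insurance_extra",),
        table=_yes(0.07, 0.33), missing=0.004)
    add("Cost_skipped_meds", YES_NO, parents=("Cost_skipped_care",),
        table=_yes(0.52, 0.06), missing=0.004)
    add("Cost_no_dentist", YES_NO, parents=("Cost_skipped_care",),
        table=_yes(0.61, 0.14), missing=0.0004)

    add("Hospitalized", YES_NO, table=_yes(0.17), missing=0.002)
    add("Discharge_plan", YES_NO, parents=("Hospitalized",),
        table=_yes(0.71, 0.28), missing=0.011)
    add("Med_review", YES_NO, parents=("Discharge_plan",),
        table=_yes(0.69, 0.31), missing=0.009)
    add("Readmission", YES_NO, parents=("Hospitalized",),
        table=_yes(0.29, 0.04), missing=0.003)

    # --- ten small components (six of 3, four of 2) --------------------
    add("Smoker", YES_NO, table=_yes(0.13), missing=0.002)
    add("Lung_disease", YES_NO, parents=("Smoker",),
        table=_yes(0.34, 0.08), missing=0.004)
    add("Stroke", YES_NO, parents=("Smoker",),
        table=_yes(0.17, 0.05), missing=0.002)

    add("Pain_joint", YES_NO, table=_yes(0.44), missing=0.003)
    add("Pain_limits", YES_NO, parents=("Pain_joint",),
        table=_yes(0.58, 0.12), missing=0.005)
    add("Pain_treatment", YES_NO, parents=("Pain_limits",),
        table=_yes(0.66, 0.24), missing=0.005)

    add("Vision_problem", YES_NO, table=_yes(0.19), missing=0.003)
    add("Hearing_problem", YES_NO, table=_yes(0.23), missing=0.003)
    add("Falls", YES_NO, parents=("Vision_problem", "Hearing_problem"),
        table=_yes(0.52, 0.31, 0.30, 0.10), missing=0.004)

    add("EOL_discussion", YES_NO, table=_yes(0.36), missing=0.012)
    add("EOL_plan", YES_NO, parents=("EOL_discussion",),
        table=_yes(0.63, 0.18), missing=0.013)
    add("EOL_proxy", YES_NO, parents=("EOL_plan",),
        table=_yes(0.72, 0.30), missing=0.011)

    add("GP_checkup", YES_NO, table=_yes(0.68), missing=0.002)
    add("Flu_shot", YES_NO, parents=("GP_checkup",),
        table=_yes(0.71, 0.34), missing=0.002)
    add("Pneumonia_vaccine", YES_NO, parents=("GP_checkup",),
        table=_yes(0.49, 0.17), missing=0.004)

    add("Num_meds", ("0-1", "2-4", "5+"), table=_rows((0.38, 0.41, 0.21)),
        ordinal=True, missing=0.002)
    add("Med_side_effects", YES_NO, parents=("Num_meds",),
        table=_yes(0.06, 0.17, 0.41), missing=0.005)
    add("Med_error", YES_NO, parents=("Num_meds",),
        table=_yes(0.02, 0.08, 0.24), missing=0.005)

    add("CC_contacted", YES_NO, table=_yes(0.19), gate=cc, missing=0.007,
        engagement="critical self-knowledge", color="green")
    add("CC_DR_for_question", YES_NO, parents=("CC_contacted",),
        table=_yes(0.85, 0.58), gate=cc, missing=0.021,
        engagement="mixed", color="purple")

    add("Wait_specialist", ("Under 1 month", "1-2 months", "2+ months"),
        table=_rows((0.49, 0.31, 0.20)), ordinal=True, missing=0.008)
    add("Coordination_gap", YES_NO, parents=("Wait_specialist",),
        table=_yes(0.12, 0.27, 0.46), missing=0.006)

    add("Sleep_problem", YES_NO, table=_yes(0.30), missing=0.003)
    add("Daytime_fatigue", YES_NO, parents=("Sleep_problem",),
        table=_yes(0.57, 0.16), missing=0.004)

    add("Income_adequacy", ("Comfortable", "Enough", "Struggling"),
        table=_rows((0.42, 0.41, 0.17)), ordinal=True, missing=0.015)
    add("Financial_stress", YES_NO, parents=("Income_adequacy",),
        table=_yes(0.08, 0.24, 0.67), missing=0.009)

    # --- isolated engagement item (Sweden only) ------------------------
    add("SP_Family_involved", FREQ4, table=_rows((0.45, 0.25, 0.15, 0.15)),
        gate=sw, ordinal=True, missing=0.005,
        engagement="self-care and autonomy", color="orange")

    return _assemble(spec)


def _assemble(spec: list[dict]) -> GroundTruthModel:
    dag = nx.DiGraph()
    cpts: dict[str, CPT] = {}
    meta: list[VariableMeta] = []
    missing_rates: dict[str, float] = {}
    level_map = {s["name"]: s["levels"] for s in spec}
    for s in spec:
        name = s["name"]
        dag.add_node(name)
        for parent in s["parents"]:
            dag.add_edge(parent, name)
        cpts[name] = CPT(
            var=name,
            levels=s["levels"],
            parents=s["parents"],
            parent_levels=tuple(level_map[p] for p in s["parents"]),
            table=np.asarray(s["table"], dtype=float),
        )
        meta.append(VariableMeta(
            name=name,
            levels=s["levels"],
            layer=s["layer"],
            ordinal=s["ordinal"],
            ordinal_ranks=s["ranks"],
            gate=Gate(s["gate"]) if s["gate"] else None,
            excluded=s["excluded"],
            reason=s["reason"],
            engagement_class=s["engagement"],
            color=s["color"],
        ))
        missing_rates[name] = float(s["missing"])
    return GroundTruthModel(dag=dag, cpts=cpts, meta=meta,
                            missing_rates=missing_rates)


# ---------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------


def sample_survey(model: GroundTruthModel,
                  config: GeneratorConfig | None = None,
                  **kwargs) -> pd.DataFrame:
    """Draw a synthetic survey table from a planted model.

    Respondents are sampled variable-by-variable in topological order
    from the planted CPTs; gated items are then masked to INELIGIBLE
    where their eligibility predicate fails, and eligible responses are
    independently replaced by MISSING at the per-variable rates.
    Deterministic given the config seed.
    """
    if config is None:
        config = GeneratorConfig(**kwargs)
    n = config.n_respondents
    rng = np.random.default_rng(config.seed)
    order = model.sampling_order()
    index = meta_index(model.meta)

    codes: dict[str, np.ndarray] = {}
    for name in order:
        cpt = model.cpts[name]
        if cpt.parents:
            cfg = np.zeros(n, dtype=np.int64)
            for parent, levels in zip(cpt.parents, cpt.parent_levels):
                cfg = cfg * len(levels) + codes[parent]
            probs = cpt.table[cfg]
        else:
            probs = np.broadcast_to(cpt.table[0], (n, len(cpt.levels)))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        codes[name] = np.minimum(
            (u[:, None] >= cum).sum(axis=1), len(cpt.levels) - 1
        ).astype(np.int64)

    columns = {
        name: np.asarray(index[name].levels, dtype=object)[codes[name]]
        for name in model.variables
    }
    table = pd.DataFrame(columns, columns=model.variables)

    # Skip-pattern ineligibility from the latent gate values.
    for m in model.meta:
        if m.gate is not None:
            passed, _ = m.gate.evaluate(table)
            col = table[m.name].to_numpy(copy=True)
            col[~passed] = INELIGIBLE
            table[m.name] = col

    # Random missingness among eligible responses (drawn in sampling
    # order so the table is reproducible independent of column order).
    for name in order:
        rate = model.missing_rates.get(name, 0.0)
        if rate <= 0:
            continue
        col = table[name].to_numpy(copy=True)
        eligible = col != INELIGIBLE
        hit = rng.random(n) < rate
        col[eligible & hit] = MISSING
        table[name] = col
    return table


def empirical_cpt_check(table: pd.DataFrame,
                        model: GroundTruthModel) -> pd.DataFrame:
    """Compare planted CPTs with empirical conditional frequencies.

    Frequencies are computed on rows where the variable and all its
    parents are eligible and non-missing. Returns one row per
    (variable, parent configuration, level) with the planted and
    empirical probabilities and their absolute error (NaN where the
    configuration was never observed).
    """
    missing_vars = set(model.variables) - set(table.columns)
    if missing_vars:
        raise ModelError(f"table lacks model variables: {sorted(missing_vars)}")
    records = []
    for name in model.variables:
        cpt = model.cpts[name]
        family = (name, *cpt.parents)
        sub = table[list(family)]
        ok = np.ones(len(sub), dtype=bool)
        for col in family:
            values = sub[col].to_numpy()
            ok &= (values != MISSING) & (values != INELIGIBLE)
        sub = sub[ok]
        for assignment, row in cpt.configs():
            mask = np.ones(len(sub), dtype=bool)
            for parent, value in assignment.items():
                mask &= sub[parent].to_numpy() == value
            n_config = int(mask.sum())
            child = sub[name].to_numpy()[mask]
            for level, p in zip(cpt.levels, row):
                emp = float((child == level).mean()) if n_config else float("nan")
                records.append({
                    "variable": name,
                    "parent_config": ";".join(
                        f"{k}={v}" for k, v in assignment.items()) or "(root)",
                    "level": level,
                    "planted": float(p),
                    "empirical": emp,
                    "abs_error": abs(emp - p) if n_config else float("nan"),
                    "n": n_config,
                })
    return pd.DataFrame.from_records(records)
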