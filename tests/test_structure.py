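"""Structure learning against enumeration and planted-truth oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from engagenet import (ConstraintSet, EncodedTable, LearnConfig, hill_climb,
                       layer_blacklist, local_score, mmhc, mmpc, score_dag)
from engagenet.metadata import VariableMeta
from engagenet.structure import Skeleton, StructureError


def binary_meta(names):
    return [VariableMeta(name=n, levels=("0", "1")) for n in names]


def encode(data: dict[str, np.ndarray]) -> EncodedTable:
    table = pd.DataFrame({k: v.astype(str) for k, v in data.items()})
    return EncodedTable.from_frame(table, binary_meta(table.columns))


def sample_chain(rng, n, p_flip=0.1):
    """A -> B -> C with strong copy-ish CPTs."""
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < p_flip, 1 - a, a)
    c = np.where(rng.random(n) < p_flip, 1 - b, b)
    return {"A": a, "B": b, "C": c}


class TestLayerBlacklist:
    def test_enumerated_pairs(self):
        meta = [
            VariableMeta(name="Country", levels=("x",), layer=1),
            VariableMeta(name="Sex", levels=("x",), layer=1),
            VariableMeta(name="A", levels=("x",), layer=2),
            VariableMeta(name="B", levels=("x",), layer=2),
        ]
        cs = layer_blacklist(meta)
        assert cs.blacklist == {
            ("A", "Country"), ("A", "Sex"), ("B", "Country"), ("B", "Sex"),
        }
        assert not cs.whitelist

    def test_single_layer_means_no_constraints(self):
        meta = [VariableMeta(name=n, levels=("x",), layer=1) for n in "AB"]
        assert not layer_blacklist(meta).blacklist

    def test_overlapping_white_and_blacklist_rejected(self):
        with pytest.raises(StructureError):
            ConstraintSet(blacklist={("A", "B")}, whitelist={("A", "B")})


class TestMMPC:
    def test_chain_skeleton_without_shortcut(self):
        rng = np.random.default_rng(101)
        enc = encode(sample_chain(rng, 10_000))
        skel = mmpc(enc)
        assert skel.edges == {frozenset("AB"), frozenset("BC")}

    def test_independent_variables_mostly_empty(self):
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            enc = encode({
                "A": rng.integers(0, 2, 5000),
                "B": rng.integers(0, 2, 5000),
            })
            empty += not mmpc(enc).edges
        assert empty >= 94

    def test_deterministic_copy_edge_found(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 500)
        enc = encode({"A": a, "B": a.copy()})
        assert mmpc(enc).edges == {frozenset("AB")}

    def test_blacklisted_both_ways_pair_never_tested_in(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 2000)
        enc = encode({"A": a, "B": a.copy()})
        cs = ConstraintSet(blacklist={("A", "B"), ("B", "A")})
        assert not mmpc(enc, cs).edges

    def test_untestable_pair_yields_no_edge(self):
        # disjoint observation supports, as with single-country items
        a = np.array(["0", "1"] * 50 + ["MISSING"] * 100)
        b = np.array(["MISSING"] * 100 + ["0", "1"] * 50)
        table = pd.DataFrame({"A": a, "B": b})
        enc = EncodedTable.from_frame(table, binary_meta(["A", "B"]))
        skel = mmpc(enc)
        assert not skel.edges
        assert ("A", "B") in skel.untestable


class TestEncodedPathAgreesWithReferencePath:
    """Compiled counting kernels match the numpy DataFrame implementation."""

    def test_ci_test_matches_dataframe_g2(self, model):
        from engagenet import GeneratorConfig, clean, contingency, g2_test, sample_survey
        from engagenet.metadata import analysis_variables

        table = clean(sample_survey(model, GeneratorConfig(3000, seed=9)),
                      model.meta)
        meta = analysis_variables(model.meta)
        enc = EncodedTable.from_frame(table, meta)
        cases = [
            ("CC_Written_plan", "CC_Feasible_plan", ()),
            ("SP_Rx_choice", "SP_Involvement", ()),
            ("Country", "Self_rated_health", ("Age_band",)),
            ("Healthy_diet", "Stress_sources", ("CC_Instruction", "Exercise")),
        ]
        for x, y, z in cases:
            stat, df, p, n_used = enc.ci_test(
                enc.index[x], enc.index[y], tuple(enc.index[c] for c in z))
            ref = g2_test(contingency(table, x, y, list(z), meta=meta))
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert df == ref.df
            assert p == pytest.approx(ref.p_value, abs=1e-12)
            assert n_used == ref.n_used


class TestLocalScore:
    def test_closed_form_uniform_root(self):
        data = {"A": np.array([0, 1] * 50)}
        enc = encode(data)
        score = local_score(enc, "A")
        expected = 100 * math.log(0.5) - math.log(100) / 2
        assert score == pytest.approx(expected, abs=1e-9)
        assert score == pytest.approx(-71.62, abs=0.01)

    def test_true_parent_raises_score(self):
        rng = np.random.default_rng(19)
        a = rng.integers(0, 2, 1000)
        enc = encode({"A": a, "B": a.copy()})
        assert local_score(enc, "B", ["A"]) > local_score(enc, "B")

    def test_independent_parent_usually_penalized(self):
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            enc = encode({
                "A": rng.integers(0, 2, 500),
                "B": rng.integers(0, 2, 500),
            })
            worse += local_score(enc, "B", ["A"]) < local_score(enc, "B")
        assert worse >= 95

    def test_empty_family_scores_neg_infinity(self):
        table = pd.DataFrame({"A": ["MISSING"] * 10, "B": ["0"] * 10})
        enc = EncodedTable.from_frame(table, binary_meta(["A", "B"]))
        assert local_score(enc, "A") == float("-inf")


def all_three_node_dags():
    """All 25 labelled DAGs on three nodes."""
    nodes = ["A", "B", "C"]
    pairs = list(itertools.permutations(nodes, 2))
    dags = []
    for arcs in itertools.chain.from_iterable(
        itertools.combinations(pairs, k) for k in range(4)
    ):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        if len(arcs) == len(set(frozenset(a) for a in arcs)) and \
                nx.is_directed_acyclic_graph(g):
            dags.append(g)
    return dags


def test_exactly_25_three_node_dags():
    assert len(all_three_node_dags()) == 25


class TestHillClimb:
    def test_chain_reaches_enumeration_optimum(self):
        rng = np.random.default_rng(23)
        enc = encode(sample_chain(rng, 10_000))
        dag = mmhc(enc)
        best = max(score_dag(enc, g) for g in all_three_node_dags())
        assert score_dag(enc, dag) == pytest.approx(best, abs=1e-9)

    def test_empty_skeleton_returns_empty_graph(self):
        rng = np.random.default_rng(29)
        enc = encode({"A": rng.integers(0, 2, 200),
                      "B": rng.integers(0, 2, 200)})
        skel = Skeleton(nodes=["A", "B"], edges=set())
        dag = hill_climb(enc, skel)
        assert dag.number_of_edges() == 0

    def test_never_worse_than_empty_graph(self):
        for seed in range(5):
            rng = np.random.default_rng(3000 + seed)
            enc = encode(sample_chain(rng, 500, p_flip=0.4))
            skel = mmpc(enc)
            dag = hill_climb(enc, skel)
            empty = sum(local_score(enc, n) for n in enc.names)
            assert score_dag(enc, dag) >= empty - 1e-9


class TestMMHC:
    def test_blacklist_respected_over_many_seeds(self, model):
        """No blacklisted arc ever appears in learned DAGs."""
        from engagenet import GeneratorConfig, clean, sample_survey
        from engagenet.metadata import analysis_variables

        meta = model.meta
        constraints = layer_blacklist(meta)
        analysis = analysis_variables(meta)
        sub_names = [m.name for m in analysis
                     if m.name in {"Country", "College", "Age_band",
                                   "Self_rated_health", "Sex",
                                   "Caregiver_role", "Walking_difficulty",
                                   "Home_help"}]
        sub_meta = [m for m in analysis if m.name in sub_names]
        for seed in range(10):
            table = clean(
                sample_survey(model, GeneratorConfig(1500, seed=seed)), meta
            )[sub_names]
            dag = mmhc(table, sub_meta, constraints)
            assert not (set(dag.edges) & constraints.blacklist)
            assert nx.is_directed_acyclic_graph(dag)

    def test_small_sample_robustness(self):
        rng = np.random.default_rng(31)
        enc = encode(sample_chain(rng, 50))
        dag = mmhc(enc)  # information-starved: sparse, but no crash
        assert nx.is_directed_acyclic_graph(dag)

    def test_arcs_lie_within_skeleton(self):
        rng = np.random.default_rng(37)
        enc = encode(sample_chain(rng, 5000))
        skel = mmpc(enc)
        dag = hill_climb(enc, skel)
        for u, v in dag.edges:
            assert skel.has_edge(u, v)

    def test_learned_graph_reproducible(self):
        rng = np.random.default_rng(41)
        data = sample_chain(rng, 3000)
        d1 = mmhc(encode(data))
        d2 = mmhc(encode(data))
        assert sorted(d1.edges) == sorted(d2.edges)
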