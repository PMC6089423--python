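"""Bootstrap averaging: counting, threshold, consensus construction."""

import networkx as nx
import numpy as np
import pytest

from engagenet import (ConstraintSet, arc_strengths, averaged_network,
                       bootstrap_networks, significance_threshold)
from engagenet.averaging import ArcStrengthTable, AveragingError


def dag(*arcs, nodes=("A", "B", "C")):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(arcs)
    return g


class TestArcStrengths:
    def test_counting_oracle(self):
        dags = (
            [dag(("A", "B")) for _ in range(120)]
            + [dag(("B", "A")) for _ in range(40)]
            + [dag() for _ in range(40)]
        )
        st = arc_strengths(dags)
        assert st.strength("A", "B") == pytest.approx(0.8)
        assert st.direction("A", "B") == pytest.approx(0.75)
        assert st.direction("B", "A") == pytest.approx(0.25)

    def test_extremes(self):
        everywhere = [dag(("A", "B")) for _ in range(200)]
        st = arc_strengths(everywhere)
        assert st.strength("A", "B") == 1.0
        assert st.strength("A", "C") == 0.0

    def test_strengths_are_exact_multiples(self):
        rng = np.random.default_rng(3)
        dags = [dag(("A", "B")) if rng.random() < 0.4 else dag()
                for _ in range(50)]
        st = arc_strengths(dags)
        for a, b in st.pairs():
            assert (st.strength(a, b) * st.n_boot) == pytest.approx(
                round(st.strength(a, b) * st.n_boot))

    def test_direction_fractions_sum_to_one(self):
        dags = [dag(("A", "B"))] * 3 + [dag(("B", "A"))] * 2
        st = arc_strengths(dags)
        assert st.direction("A", "B") + st.direction("B", "A") == 1.0

    def test_presence_counts_conserved(self):
        rng = np.random.default_rng(9)
        dags = []
        for _ in range(30):
            g = dag()
            if rng.random() < 0.5:
                g.add_edge("A", "B")
            if rng.random() < 0.5:
                g.add_edge("C", "B")
            dags.append(g)
        st = arc_strengths(dags)
        assert sum(st.direction_counts.values()) == sum(
            g.number_of_edges() for g in dags)

    def test_inconsistent_node_sets_rejected(self):
        with pytest.raises(AveragingError):
            arc_strengths([dag(), dag(nodes=("A", "B"))])


class TestSignificanceThreshold:
    def test_separable_case_admits_exactly_strong_arcs(self):
        values = [1.0] * 5 + [0.0] * 20
        t, degenerate = significance_threshold(values)
        assert not degenerate
        assert 0.0 < t < 1.0
        assert sum(v > t for v in values) == 5

    def test_all_equal_flagged_and_all_admitted(self):
        t, degenerate = significance_threshold([1.0, 1.0, 1.0])
        assert degenerate
        assert all(v > t for v in [1.0, 1.0, 1.0])

    def test_bimodal_cut_falls_between_clusters(self):
        values = [0.9, 0.95, 1.0, 0.05, 0.1]
        t, _ = significance_threshold(values)
        assert 0.1 < t < 0.9

    def test_matches_l1_grid_bruteforce(self):
        rng = np.random.default_rng(21)
        values = np.round(rng.random(30), 2)

        def l1(level, vals):
            grid = np.unique(np.concatenate(([0.0], np.unique(vals), [1.0])))
            widths = np.diff(grid)
            ecdf = np.array([(vals <= g).mean() for g in grid[:-1]])
            return float((np.abs(ecdf - level) * widths).sum())

        t, _ = significance_threshold(values)
        best = min(l1((values <= c).mean(), values)
                   for c in np.linspace(0, 1, 1001))
        assert l1((values <= t).mean(), values) == pytest.approx(best, abs=1e-6)


class TestAveragedNetwork:
    def make_strengths(self, counts, n_boot):
        nodes = sorted({x for k in counts for x in k})
        return ArcStrengthTable(nodes=nodes, n_boot=n_boot,
                                direction_counts=dict(counts))

    def test_unanimous_arcs_pass_through(self):
        st = self.make_strengths({("A", "B"): 200, ("B", "C"): 200}, 200)
        avg = averaged_network(st, threshold=0.5)
        assert sorted(avg.dag.edges) == [("A", "B"), ("B", "C")]

    def test_threshold_one_is_empty_by_strictness(self):
        st = self.make_strengths({("A", "B"): 200}, 200)
        avg = averaged_network(st, threshold=1.0)
        assert avg.dag.number_of_edges() == 0

    def test_majority_direction_wins(self):
        st = self.make_strengths({("A", "B"): 120, ("B", "A"): 80}, 200)
        avg = averaged_network(st, threshold=0.5)
        assert list(avg.dag.edges) == [("A", "B")]

    def test_exact_tie_goes_lexicographic_and_flagged(self):
        st = self.make_strengths({("B", "A"): 100, ("A", "B"): 100}, 200)
        avg = averaged_network(st, threshold=0.5)
        assert list(avg.dag.edges) == [("A", "B")]
        assert avg.tie_orientations == [("A", "B")]

    def test_blacklisted_orientation_flipped_when_possible(self):
        st = self.make_strengths({("A", "B"): 150, ("B", "A"): 50}, 200)
        cs = ConstraintSet(blacklist={("A", "B")})
        avg = averaged_network(st, threshold=0.5, constraints=cs)
        assert list(avg.dag.edges) == [("B", "A")]
        assert avg.flipped_for_blacklist == [("A", "B")]

    def test_cycle_repair_drops_weakest(self):
        st = self.make_strengths({
            ("A", "B"): 200, ("B", "C"): 190, ("C", "A"): 150,
        }, 200)
        avg = averaged_network(st, threshold=0.5)
        assert nx.is_directed_acyclic_graph(avg.dag)
        assert avg.dropped_for_cycles == [("C", "A")]
        assert sorted(avg.dag.edges) == [("A", "B"), ("B", "C")]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(33)
        counts = {}
        for i, (a, b) in enumerate([("A", "B"), ("B", "C"), ("A", "C"),
                                    ("C", "D"), ("B", "D")]):
            counts[(a, b)] = int(rng.integers(0, 101))
        st = self.make_strengths(counts, 100)
        previous = None
        for t in np.linspace(0, 1, 21):
            arcs = {frozenset(e) for e in averaged_network(st, t).dag.edges}
            if previous is not None:
                assert arcs <= previous
            previous = arcs


class TestBootstrap:
    def test_replicate_count_and_determinism(self):
        rng = np.random.default_rng(55)
        a = rng.integers(0, 2, 800)
        b = np.where(rng.random(800) < 0.1, 1 - a, a)
        import pandas as pd

        from engagenet import EncodedTable
        from engagenet.metadata import VariableMeta

        table = pd.DataFrame({"A": a.astype(str), "B": b.astype(str)})
        meta = [VariableMeta(name=n, levels=("0", "1")) for n in "AB"]
        enc = EncodedTable.from_frame(table, meta)
        d1 = bootstrap_networks(enc, meta, n_boot=10, seed=4)
        d2 = bootstrap_networks(enc, meta, n_boot=10, seed=4)
        assert len(d1) == 10
        assert [sorted(g.edges) for g in d1] == [sorted(g.edges) for g in d2]
        d3 = bootstrap_networks(enc, meta, n_boot=1, seed=9)
        assert len(d3) == 1
        assert nx.is_directed_acyclic_graph(d3[0])

    def test_true_arcs_outscore_noise_on_planted_model(self, model):
        """Mean strength of planted arcs far exceeds mean of non-arcs."""
        from engagenet import GeneratorConfig, clean, sample_survey
        from engagenet.metadata import analysis_variables
        from engagenet.structure import layer_blacklist

        names = ["CC_Instruction", "CC_Written_plan", "CC_Feasible_plan",
                 "Healthy_diet", "Mental", "Diabetes", "Smoker"]
        meta = model.meta
        table = clean(sample_survey(model, GeneratorConfig(8000, seed=13)),
                      meta)[names]
        sub_meta = [m for m in analysis_variables(meta) if m.name in names]
        dags = bootstrap_networks(table, sub_meta, layer_blacklist(sub_meta),
                                  n_boot=20, seed=2)
        st = arc_strengths(dags)
        truth = {frozenset(e) for e in model.analysis_dag().subgraph(names).edges}
        strengths_true = [st.strength(*sorted(p)) for p in truth]
        all_pairs = {
            frozenset((a, b))
            for i, a in enumerate(names) for b in names[i + 1:]
        }
        strengths_noise = [
            st.strength(*sorted(p)) for p in all_pairs - truth
        ]
        assert np.mean(strengths_true) - np.mean(strengths_noise) >= 0.3
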