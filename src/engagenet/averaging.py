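"""Bootstrap model averaging: arc strengths, threshold, consensus DAG.

Structure-learning output on survey data is unstable under resampling,
so arcs are assessed by nonparametric bootstrap: rows are resampled
with replacement to the original sample size (200 replicates by
default), the learner is re-run with identical settings, and each arc's
*strength* is the fraction of replicate networks containing the edge in
either direction. The *direction* confidence of an orientation is the
fraction of presence-replicates with that orientation. The averaged
(consensus) network keeps arcs whose strength strictly exceeds a
significance threshold and orients each by its majority direction.

The inclusion threshold can be fixed (e.g. 0.5) or estimated: the
estimator picks the cut minimising the L1 distance between the
empirical CDF of the observed strengths and the ideal noise-free CDF in
which every strength is exactly 0 or 1. Candidate cuts are midpoints
between consecutive distinct observed strengths, so the returned
threshold separates strength clusters strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .encode import EncodedTable
from .metadata import VariableMeta
from .structure import ConstraintSet, LearnConfig, mmhc


class AveragingError(ValueError):
    pass


def bootstrap_networks(enc_or_table, meta: Sequence[VariableMeta] | None = None,
                       constraints: ConstraintSet | None = None,
                       config: LearnConfig | None = None,
                       n_boot: int = 200, seed: int = 0,
                       include_original: bool = False
                       ) -> list[nx.DiGraph]:
    """Learn one network per bootstrap resample of the rows.

    Deterministic given the seed. Individual replicate failures are
    tolerated (and logged on the result's ``failures`` attribute-free
    return: they simply raise) up to 10% of replicates; beyond that the
    run aborts.
    """
    if n_boot < 1:
        raise AveragingError("n_boot must be >= 1")
    if isinstance(enc_or_table, EncodedTable):
        enc = enc_or_table
    else:
        if meta is None:
            raise AveragingError("metadata required to encode a raw table")
        enc = EncodedTable.from_frame(enc_or_table, meta)
    rng = np.random.default_rng(seed)
    dags: list[nx.DiGraph] = []
    failures: list[tuple[int, str]] = []
    for b in range(n_boot):
        idx = rng.integers(0, enc.n_rows, enc.n_rows)
        try:
            dags.append(mmhc(enc.resample(idx), meta, constraints, config))
        except Exception as exc:  # noqa: BLE001 - replicate-level tolerance
            failures.append((b, str(exc)))
            if len(failures) > 0.10 * n_boot:
                raise AveragingError(
                    f"more than 10% of bootstrap replicates failed; "
                    f"first failures: {failures[:3]}"
                ) from exc
    if include_original:
        dags.append(mmhc(enc, meta, constraints, config))
    return dags


@dataclass
class ArcStrengthTable:
    """Per-pair bootstrap presence and per-orientation fractions."""

    nodes: list[str]
    n_boot: int
    #: ordered pair -> number of replicates containing that orientation
    direction_counts: dict[tuple[str, str], int]

    def pair_count(self, a: str, b: str) -> int:
        return (self.direction_counts.get((a, b), 0)
                + self.direction_counts.get((b, a), 0))

    def strength(self, a: str, b: str) -> float:
        return self.pair_count(a, b) / self.n_boot

    def direction(self, a: str, b: str) -> float:
        """Fraction of presence-replicates oriented a -> b."""
        present = self.pair_count(a, b)
        if present == 0:
            return 0.0
        return self.direction_counts.get((a, b), 0) / present

    def pairs(self) -> list[tuple[str, str]]:
        seen = {tuple(sorted(k)) for k in self.direction_counts}
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": a, "to": b,
                "strength": self.strength(a, b),
                "direction": self.direction(a, b),
            }
            for a, b in self.pairs()
        ] + [
            {
                "from": b, "to": a,
                "strength": self.strength(a, b),
                "direction": self.direction(b, a),
            }
            for a, b in self.pairs()
        ]
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"]
                            ).sort_values(["from", "to"]).reset_index(drop=True)


def arc_strengths(dags: Sequence[nx.DiGraph]) -> ArcStrengthTable:
    """Exact presence counting over a list of bootstrap networks."""
    if not dags:
        raise AveragingError("empty network list")
    nodes = sorted(dags[0].nodes)
    counts: dict[tuple[str, str], int] = {}
    for dag in dags:
        if sorted(dag.nodes) != nodes:
            raise AveragingError("networks have inconsistent node sets")
        for u, v in dag.edges:
            counts[(u, v)] = counts.get((u, v), 0) + 1
    return ArcStrengthTable(nodes=nodes, n_boot=len(dags),
                            direction_counts=counts)


def significance_threshold(strengths: ArcStrengthTable | Sequence[float],
                           ) -> tuple[float, bool]:
    """L1-optimal inclusion threshold for arc strengths.

    Returns ``(threshold, degenerate)``; ``degenerate`` flags the
    all-strengths-equal case, where the common value minus machine
    epsilon is returned so every arc is admitted under strict ``>``.
    """
    if isinstance(strengths, ArcStrengthTable):
        values = np.array([strengths.strength(a, b)
                           for a, b in strengths.pairs()])
    else:
        values = np.asarray(list(strengths), dtype=float)
    if values.size == 0:
        raise AveragingError("no candidate pairs")
    uniq = np.unique(values)
    if uniq.size == 1:
        return float(uniq[0]) - np.finfo(float).eps * max(1.0, abs(uniq[0])), True
    # Empirical CDF of strengths evaluated over [0, 1]; the ideal CDF
    # is flat at F(t) on [0, 1). Evaluate the L1 distance for each
    # candidate cut (midpoints of consecutive distinct strengths).
    grid = np.unique(np.concatenate(([0.0], uniq, [1.0])))
    widths = np.diff(grid)
    # F on each interval [grid[i], grid[i+1])
    ecdf = np.array([(values <= g).mean() for g in grid[:-1]])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_l1 = None, np.inf
    for t in candidates:
        level = (values <= t).mean()
        l1 = float((np.abs(ecdf - level) * widths).sum())
        if l1 < best_l1 - 1e-12:
            best_l1, best_t = l1, float(t)
    return best_t, False


@dataclass
class AveragedNetwork:
    """Consensus DAG with per-arc strength and direction confidence."""

    dag: nx.DiGraph
    threshold: float
    strengths: ArcStrengthTable
    dropped_for_cycles: list[tuple[str, str]] = field(default_factory=list)
    flipped_for_blacklist: list[tuple[str, str]] = field(default_factory=list)
    tie_orientations: list[tuple[str, str]] = field(default_factory=list)

    def arc_frame(self) -> pd.DataFrame:
        frame = self.strengths.to_frame()
        included = {(u, v) for u, v in self.dag.edges}
        frame["included"] = [
            (u, v) in included for u, v in zip(frame["from"], frame["to"])
        ]
        return frame


def averaged_network(strengths: ArcStrengthTable,
                     threshold: float | None = None,
                     constraints: ConstraintSet | None = None
                     ) -> AveragedNetwork:
    """Build the consensus network at an inclusion threshold.

    Pairs are included iff strength > threshold (strictly), oriented by
    majority direction (exact ties go to the lexicographically smaller
    from-node and are flagged). Blacklisted orientations are flipped to
    the legal direction when it was ever observed, else dropped. If the
    oriented arcs contain directed cycles, the included arc with the
    smallest strength (ties: smallest direction confidence, then
    lexicographic) is removed repeatedly until acyclic.
    """
    constraints = constraints or ConstraintSet()
    if threshold is None:
        threshold, _ = significance_threshold(strengths)
    if not 0.0 <= threshold <= 1.0:
        raise AveragingError("threshold must lie in [0, 1]")
    dag = nx.DiGraph()
    dag.add_nodes_from(strengths.nodes)
    ties: list[tuple[str, str]] = []
    flipped: list[tuple[str, str]] = []
    arcs: list[tuple[str, str, float, float]] = []
    for a, b in strengths.pairs():
        s = strengths.strength(a, b)
        if s <= threshold:
            continue
        d_ab = strengths.direction(a, b)
        if d_ab > 0.5:
            u, v = a, b
        elif d_ab < 0.5:
            u, v = b, a
        else:
            u, v = min(a, b), max(a, b)
            ties.append((u, v))
        if constraints.forbids(u, v):
            if strengths.direction(v, u) > 0:
                flipped.append((u, v))
                u, v = v, u
            else:
                continue
        arcs.append((u, v, s, strengths.direction(u, v)))
    for u, v, *_ in arcs:
        dag.add_edge(u, v)
    dropped: list[tuple[str, str]] = []
    while not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        cycle_arcs = {(u, v) for u, v, *_ in cycle}
        weakest = min(
            (a for a in arcs if (a[0], a[1]) in cycle_arcs),
            key=lambda a: (a[2], a[3], a[0], a[1]),
        )
        dag.remove_edge(weakest[0], weakest[1])
        arcs.remove(weakest)
        dropped.append((weakest[0], weakest[1]))
    return AveragedNetwork(dag=dag, threshold=float(threshold),
                           strengths=strengths,
                           dropped_for_cycles=dropped,
                           flipped_for_blacklist=flipped,
                           tie_orientations=ties)
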