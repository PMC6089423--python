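"""Hybrid structure learning: layer blacklists, MMPC, BIC hill climbing.

The learner is Max-Min Hill-Climbing (MMHC): a constraint-based stage
(Max-Min Parents-and-Children) discovers each node's candidate
neighbour set with conditional independence tests, and a score-based
greedy search then selects and orients arcs, restricted to the learned
skeleton and to expert constraints.

Expert knowledge enters as *layering*: socio-demographic and
health-system variables (layer 1) may influence care-experience
variables (layer 2) but never the reverse, so every layer-2 → layer-1
arc is blacklisted. No arcs are whitelisted.

Defaults mirror the canonical discrete implementation of MMHC: G²
association test at alpha = 0.05, conditioning sets up to size 3, BIC
score, empty starting graph, no restarts. All tie-breaks are
deterministic, so a learned graph is reproducible bit-for-bit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .encode import EncodedTable
from .metadata import VariableMeta, meta_index

NEG_INF = float("-inf")


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden and required arcs (ordered pairs of variable names)."""

    blacklist: frozenset[tuple[str, str]] = frozenset()
    whitelist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))
        object.__setattr__(self, "whitelist", frozenset(self.whitelist))
        if self.blacklist & self.whitelist:
            raise StructureError("whitelist and blacklist overlap")
        wl = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(wl):
            raise StructureError("whitelisted arcs form a directed cycle")

    def forbids(self, u: str, v: str) -> bool:
        return (u, v) in self.blacklist

    def forbids_both(self, u: str, v: str) -> bool:
        return (u, v) in self.blacklist and (v, u) in self.blacklist


def layer_blacklist(meta: Sequence[VariableMeta]) -> ConstraintSet:
    """Forbid every arc from a layer-2 variable into a layer-1 variable.

    Only non-excluded (analysis) variables are constrained; intra-layer
    arcs are unconstrained and the whitelist is empty.
    """
    analysis = [m for m in meta if not m.excluded]
    lower = [m.name for m in analysis if m.layer == 1]
    upper = [m.name for m in analysis if m.layer == 2]
    black = {(u, v) for u in upper for v in lower}
    return ConstraintSet(blacklist=frozenset(black))


@dataclass
class Skeleton:
    """Undirected candidate structure from MMPC."""

    nodes: list[str]
    edges: set[frozenset[str]]
    neighbours: dict[str, set[str]] = field(init=False)
    untestable: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.neighbours = {n: set() for n in self.nodes}
        for edge in self.edges:
            a, b = tuple(edge)
            self.neighbours[a].add(b)
            self.neighbours[b].add(a)

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges


# ---------------------------------------------------------------------
# MMPC
# ---------------------------------------------------------------------


def _subsets(pool: Sequence[int], max_size: int, must_include: int | None = None
             ) -> Iterable[tuple[int, ...]]:
    rest = [p for p in pool if p != must_include]
    base = (must_include,) if must_include is not None else ()
    start = 0 if must_include is not None else 0
    for size in range(start, max_size - len(base) + 1):
        for combo in itertools.combinations(rest, size):
            yield tuple(sorted(base + combo))


def _assoc_key(p: float, stat: float) -> tuple[float, float]:
    # association = 1 - p, ties broken by larger statistic
    return (1.0 - p, stat)


def mmpc(enc: EncodedTable, constraints: ConstraintSet | None = None,
         alpha: float = 0.05, max_cond: int = 3,
         test: str = "g2") -> Skeleton:
    """Max-Min Parents-and-Children skeleton discovery.

    For each target the forward phase repeatedly admits the candidate
    whose *minimum* association with the target over all conditioning
    subsets of the current candidate set (up to ``max_cond``) is
    maximal, stopping when that max-min association is non-significant;
    candidates found independent given any tested subset are dismissed
    permanently. The backward phase removes admitted members that are
    independent of the target given some subset of the rest. The final
    skeleton keeps an edge only if each endpoint is in the other's set
    (AND symmetry). Pairs blacklisted in both directions are never
    tested; pairs with no jointly observed rows are untestable and
    yield no edge (they are listed on the returned skeleton).
    """
    if not 0 < alpha < 1:
        raise StructureError("alpha must be in (0, 1)")
    if enc.n_vars < 2:
        raise StructureError("need at least 2 variables")
    constraints = constraints or ConstraintSet()
    names = enc.names
    untestable: set[tuple[str, str]] = set()

    def _pc(t: int) -> set[int]:
        cand: dict[int, tuple[float, float]] = {}
        for x in range(enc.n_vars):
            if x == t or constraints.forbids_both(names[x], names[t]):
                continue
            stat, _, p, n_used = enc.ci_test(x, t, (), test)
            if n_used == 0:
                untestable.add(tuple(sorted((names[x], names[t]))))
                continue
            if p <= alpha:
                cand[x] = _assoc_key(p, stat)
        cpc: list[int] = []
        while cand:
            best = max(cand, key=lambda x: (cand[x], -x))
            if cand[best][0] < 1.0 - alpha:
                break
            del cand[best]
            cpc.append(best)
            # update min-assoc of the rest over subsets containing `best`
            for x in list(cand):
                for S in _subsets(cpc, max_cond, must_include=best):
                    stat, _, p, n_used = enc.ci_test(x, t, S, test)
                    if n_used == 0:
                        continue
                    key = _assoc_key(p, stat)
                    if key < cand[x]:
                        cand[x] = key
                    if p > alpha:
                        del cand[x]
                        break
        # backward: prune members independent given a subset of the rest
        pruned = True
        while pruned:
            pruned = False
            for x in list(cpc):
                others = [c for c in cpc if c != x]
                for S in _subsets(others, max_cond):
                    stat, _, p, n_used = enc.ci_test(x, t, S, test)
                    if n_used > 0 and p > alpha:
                        cpc.remove(x)
                        pruned = True
                        break
        return set(cpc)

    pc = {t: _pc(t) for t in range(enc.n_vars)}
    edges = {
        frozenset((names[a], names[b]))
        for a in range(enc.n_vars) for b in pc[a]
        if a in pc[b] and a < b
    }
    return Skeleton(nodes=list(names), edges=edges,
                    untestable=sorted(untestable))


# ---------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------


def local_score(enc: EncodedTable, node: str | int,
                parents: Iterable[str | int] = (),
                score_type: str = "bic") -> float:
    """Decomposable local network score of one family.

    BIC (default): Σ N(x, pa)·ln(N(x, pa)/N(pa)) − (ln n)/2 · q·(k−1)
    with k the node's level count, q the number of parent
    configurations and n the rows complete on the family. BDeu with
    equivalent sample size 1 is available. Families with no complete
    rows score −inf.
    """
    child = enc.index[node] if isinstance(node, str) else node
    pa = tuple(sorted(
        enc.index[p] if isinstance(p, str) else p for p in parents
    ))
    if child in pa:
        raise StructureError("parent set must exclude the node")
    counts, n_used = enc.family_counts(child, pa)
    if n_used == 0:
        return NEG_INF
    k = enc.card(child)
    q = counts.shape[0]
    if score_type == "bic":
        row_tot = counts.sum(axis=1, keepdims=True)
        mask = counts > 0
        loglik = float(
            (counts[mask] * np.log(
                counts[mask] / np.broadcast_to(row_tot, counts.shape)[mask]
            )).sum()
        )
        return loglik - 0.5 * math.log(n_used) * q * (k - 1)
    if score_type == "bdeu":
        ess = 1.0
        a_row, a_cell = ess / q, ess / (q * k)
        from scipy.special import gammaln
        row_tot = counts.sum(axis=1)
        return float(
            (gammaln(a_row) - gammaln(a_row + row_tot)).sum()
            + (gammaln(a_cell + counts) - gammaln(a_cell)).sum()
        )
    raise StructureError(f"unknown score {score_type!r}")


# ---------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------


def _creates_cycle(parents: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u -> v close a cycle, i.e. does v already reach u?"""
    children: dict[str, set[str]] = {n: set() for n in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    stack, seen = [v], {v}
    while stack:
        node = stack.pop()
        if node == u:
            return True
        for nxt in children[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def hill_climb(enc: EncodedTable, skeleton: Skeleton,
               constraints: ConstraintSet | None = None,
               score_type: str = "bic",
               score_tol: float = 1e-9) -> nx.DiGraph:
    """Greedy score-based search restricted to the skeleton.

    Starting from the empty graph, repeatedly apply the single best
    strictly-score-improving move among arc additions (along skeleton
    edges, not blacklisted), deletions and reversals, until a local
    optimum. Ties are broken by highest gain, then lexicographic
    (from, to), then move type (add < reverse < delete), so the result
    is deterministic.
    """
    constraints = constraints or ConstraintSet()
    nodes = sorted(skeleton.nodes)
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    cache: dict[tuple[str, frozenset[str]], float] = {}

    def fam(node: str, ps: set[str]) -> float:
        key = (node, frozenset(ps))
        if key not in cache:
            cache[key] = local_score(enc, node, ps, score_type)
        return cache[key]

    _type_rank = {"add": 0, "reverse": 1, "delete": 2}

    while True:
        best = None  # (gain, from, to, type, apply)
        current = {n: fam(n, parents[n]) for n in nodes}

        def consider(gain: float, u: str, v: str, kind: str) -> None:
            nonlocal best
            if not np.isfinite(gain) or gain <= score_tol:
                return
            key = (-gain, u, v, _type_rank[kind])
            if best is None or key < best[0]:
                best = (key, u, v, kind)

        arcs = [(u, v) for v in nodes for u in parents[v]]
        for edge in sorted(tuple(sorted(e)) for e in skeleton.edges):
            for u, v in (edge, edge[::-1]):
                if u in parents[v] or v in parents[u]:
                    continue
                if constraints.forbids(u, v):
                    continue
                if _creates_cycle(parents, u, v):
                    continue
                gain = fam(v, parents[v] | {u}) - current[v]
                consider(gain, u, v, "add")
        for u, v in sorted(arcs):
            gain = fam(v, parents[v] - {u}) - current[v]
            consider(gain, u, v, "delete")
            if not constraints.forbids(v, u):
                # reversal: remove u->v, add v->u; check acyclicity
                parents[v].discard(u)
                cyclic = _creates_cycle(parents, v, u)
                parents[v].add(u)
                if not cyclic:
                    gain = (
                        fam(v, parents[v] - {u}) - current[v]
                        + fam(u, parents[u] | {v}) - current[u]
                    )
                    consider(gain, u, v, "reverse")
        if best is None:
            break
        _, u, v, kind = best
        if kind == "add":
            parents[v].add(u)
        elif kind == "delete":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)

    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    for v, ps in parents.items():
        for u in ps:
            dag.add_edge(u, v)
    return dag


def score_dag(enc: EncodedTable, dag: nx.DiGraph,
              score_type: str = "bic") -> float:
    """Total decomposable score of a DAG (sum of family scores)."""
    return sum(
        local_score(enc, n, tuple(dag.predecessors(n)), score_type)
        for n in dag.nodes
    )


# ---------------------------------------------------------------------
# MMHC
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class LearnConfig:
    alpha: float = 0.05
    max_cond: int = 3
    test: str = "g2"
    score_type: str = "bic"


def mmhc(table_or_enc, meta: Sequence[VariableMeta] | None = None,
         constraints: ConstraintSet | None = None,
         config: LearnConfig | None = None) -> nx.DiGraph:
    """Max-Min Hill-Climbing: MMPC skeleton, then restricted hill climb.

    Accepts either a cleaned string table (with metadata) or an
    already-encoded table. The returned DAG is acyclic, respects the
    blacklist, and its arcs lie within the learned skeleton.
    """
    config = config or LearnConfig()
    if isinstance(table_or_enc, EncodedTable):
        enc = table_or_enc
    else:
        if meta is None:
            raise StructureError("metadata required to encode a raw table")
        enc = EncodedTable.from_frame(table_or_enc, meta)
    if constraints is None and meta is not None:
        constraints = layer_blacklist(meta)
    skeleton = mmpc(enc, constraints, config.alpha, config.max_cond,
                    config.test)
    return hill_climb(enc, skeleton, constraints, config.score_type)
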