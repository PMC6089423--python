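"""Parameter fitting, exact conditional queries, component summary.

Once a structure is chosen, each node's conditional probability table
is fitted by maximum likelihood on the rows complete on the node and
its parents (optionally with a uniform pseudocount for sparse
families). Queries are answered exactly by factor elimination
restricted to the connected component containing the target — evidence
in other components cannot alter the answer, since components are
mutually independent under the factorisation.

The component summary mirrors how such survey networks are reported:
"networks" are connected components with at least two variables
(ignoring arc direction); isolated variables are listed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .metadata import VariableMeta, meta_index
from .sentinels import INELIGIBLE, MISSING


class InferenceError(ValueError):
    pass


@dataclass
class NodeCPT:
    var: str
    levels: tuple[str, ...]
    parents: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    #: shape (n parent configs, n levels); rows sum to 1, or are uniform
    #: with the config listed in ``no_data`` when unobserved.
    table: np.ndarray
    n_used: int
    no_data: list[int] = field(default_factory=list)

    def config_index(self, assignment: Mapping[str, str]) -> int:
        """Row index of one fully-specified parent assignment."""
        idx = 0
        for parent, levels in zip(self.parents, self.parent_levels):
            idx = idx * len(levels) + levels.index(assignment[parent])
        return idx


@dataclass
class FittedNetwork:
    """DAG plus per-node CPTs; supports exact conditional queries."""

    dag: nx.DiGraph
    cpts: dict[str, NodeCPT]

    def __post_init__(self) -> None:
        for name, cpt in self.cpts.items():
            rows = cpt.table.sum(axis=1)
            observed = np.ones(len(rows), dtype=bool)
            observed[cpt.no_data] = False
            if np.any(np.abs(rows[observed] - 1.0) > 1e-9):
                raise InferenceError(f"{name}: CPT rows do not sum to 1")


def fit_cpts(table: pd.DataFrame, dag: nx.DiGraph,
             meta: Sequence[VariableMeta],
             pseudocount: float = 0.0) -> FittedNetwork:
    """Maximum-likelihood CPT estimation on an explicit DAG.

    P̂(x | pa) = (N(x, pa) + c) / (N(pa) + c·|levels|) with c the
    uniform pseudocount (default 0, pure MLE). Family counts use the
    rows complete on the family (sentinels deleted). Parent
    configurations never observed are flagged; with c > 0 they fall
    back to the uniform distribution.
    """
    if pseudocount < 0:
        raise InferenceError("pseudocount must be >= 0")
    index = meta_index(meta)
    missing = [n for n in dag.nodes if n not in table.columns]
    if missing:
        raise InferenceError(f"DAG nodes absent from table: {sorted(missing)}")
    cpts: dict[str, NodeCPT] = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.predecessors(node)))
        levels = index[node].levels
        parent_levels = tuple(index[p].levels for p in parents)
        family = (*parents, node)
        sub = table[list(family)]
        ok = np.ones(len(sub), dtype=bool)
        coded = {}
        for col in family:
            lv = index[col].levels
            lookup = {level: i for i, level in enumerate(lv)}
            codes = np.array(
                [lookup.get(v, -1) for v in sub[col].to_numpy().tolist()],
                dtype=np.int64,
            )
            coded[col] = codes
            ok &= codes >= 0
        n_used = int(ok.sum())
        dims = [len(index[c].levels) for c in family]
        flat = np.zeros(n_used, dtype=np.int64)
        for col, k in zip(family, dims):
            flat = flat * k + coded[col][ok]
        counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(
            -1, len(levels)
        ).astype(float)
        no_data = np.flatnonzero(counts.sum(axis=1) == 0).tolist()
        counts += pseudocount
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / row_tot
        # unobserved configs: uniform fallback, flagged
        probs[no_data] = 1.0 / len(levels)
        cpts[node] = NodeCPT(
            var=node, levels=levels, parents=parents,
            parent_levels=parent_levels, table=probs,
            n_used=n_used, no_data=no_data,
        )
    return FittedNetwork(dag=dag.copy(), cpts=cpts)


# ---------------------------------------------------------------------
# Exact queries
# ---------------------------------------------------------------------


def _component(dag: nx.DiGraph, node: str) -> set[str]:
    return nx.node_connected_component(dag.to_undirected(as_view=True), node)


def joint_distribution(fitted: FittedNetwork, nodes: Sequence[str]
                       ) -> np.ndarray:
    """Joint probability array over ``nodes`` (one axis per node)."""
    nodes = list(nodes)
    axis = {n: i for i, n in enumerate(nodes)}
    shape = [len(fitted.cpts[n].levels) for n in nodes]
    if int(np.prod(shape)) > 50_000_000:
        raise InferenceError("joint distribution too large to enumerate")
    joint = np.ones(shape, dtype=float)
    for name in nodes:
        cpt = fitted.cpts[name]
        dims = [len(lv) for lv in cpt.parent_levels] + [len(cpt.levels)]
        factor = cpt.table.reshape(dims)
        # broadcast factor over the full joint axes
        expand = [1] * len(nodes)
        for p, k in zip(cpt.parents, dims[:-1]):
            expand[axis[p]] = k
        expand[axis[name]] = dims[-1]
        order = [*cpt.parents, name]
        src = [axis[o] for o in order]
        # move factor axes into joint axis positions
        full = np.ones(expand, dtype=float)
        perm = np.argsort(src)
        factor_t = np.transpose(factor, perm)
        full[...] = factor_t.reshape(expand)
        joint = joint * full
    return joint


def query(fitted: FittedNetwork, target: tuple[str, str] | str,
          evidence: Mapping[str, str] | None = None) -> float | dict[str, float]:
    """Exact P(target | evidence) by enumeration within the component.

    ``target`` is either ``(variable, level)`` (returns a probability)
    or a variable name (returns the full conditional distribution).
    Evidence on variables outside the target's connected component is
    ignored: across components the joint distribution factorises, so
    such evidence cannot move the answer.
    """
    evidence = dict(evidence or {})
    tvar, tlevel = target if isinstance(target, tuple) else (target, None)
    if tvar not in fitted.cpts:
        raise InferenceError(f"unknown target variable {tvar!r}")
    for var, level in evidence.items():
        if var not in fitted.cpts:
            raise InferenceError(f"unknown evidence variable {var!r}")
        if level not in fitted.cpts[var].levels:
            raise InferenceError(f"unknown level {level!r} for {var!r}")
    comp = sorted(_component(fitted.dag, tvar))
    local_evidence = {k: v for k, v in evidence.items() if k in comp}
    joint = joint_distribution(fitted, comp)
    # slice evidence axes
    slicer: list[object] = [slice(None)] * len(comp)
    for var, level in local_evidence.items():
        i = comp.index(var)
        slicer[i] = fitted.cpts[var].levels.index(level)
    reduced = joint[tuple(slicer)]
    keep_axis = [n for n in comp if n not in local_evidence].index(tvar)
    margins = tuple(
        i for i in range(reduced.ndim) if i != keep_axis
    )
    dist = reduced.sum(axis=margins) if margins else reduced
    total = float(dist.sum())
    if total <= 0.0:
        raise InferenceError("impossible evidence (zero probability)")
    dist = dist / total
    levels = fitted.cpts[tvar].levels
    if tlevel is None:
        return {lv: float(p) for lv, p in zip(levels, dist)}
    if tlevel not in levels:
        raise InferenceError(f"unknown level {tlevel!r} for {tvar!r}")
    return float(dist[levels.index(tlevel)])


# ---------------------------------------------------------------------
# Component summary
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSummary:
    components: tuple[tuple[str, ...], ...]  # size-descending, incl. isolates
    isolated: tuple[str, ...]

    @property
    def networks(self) -> tuple[tuple[str, ...], ...]:
        """Components with >= 2 variables."""
        return tuple(c for c in self.components if len(c) >= 2)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.networks)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def n_variables_in_networks(self) -> int:
        return sum(self.sizes)


def components(dag: nx.DiGraph) -> ComponentSummary:
    """Connected components of the structure, ignoring arc direction."""
    undirected = dag.to_undirected(as_view=True)
    comps = [tuple(sorted(c)) for c in nx.connected_components(undirected)]
    comps.sort(key=lambda c: (-len(c), c))
    isolated = tuple(c[0] for c in comps if len(c) == 1)
    return ComponentSummary(components=tuple(comps), isolated=isolated)
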