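"""Serialization: survey CSV, DAG JSON, arcs TSV, DOT and GraphML.

All artifacts are plain text and round-trip structurally:
``read(write(x))`` recovers the same node and arc sets. Graph exports
carry a visual arc weight equal to the absolute Spearman rank
correlation between the endpoint variables (ordinal-coded,
pairwise-complete) and node colours from the engagement-class metadata,
so rendered networks read like the conventional figures in this
literature.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .averaging import AveragedNetwork
from .citests import TestError, spearman
from .inference import FittedNetwork, NodeCPT
from .metadata import VariableMeta, meta_index

MAX_PENWIDTH = 8.0


# -- survey table ------------------------------------------------------

def write_survey(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_survey(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


# -- DAG JSON ----------------------------------------------------------

def dag_to_json(dag: nx.DiGraph) -> str:
    payload = {
        "nodes": sorted(dag.nodes),
        "arcs": sorted([u, v] for u, v in dag.edges),
    }
    return json.dumps(payload, indent=1)


def dag_from_json(text: str) -> nx.DiGraph:
    payload = json.loads(text)
    dag = nx.DiGraph()
    dag.add_nodes_from(payload["nodes"])
    dag.add_edges_from(tuple(arc) for arc in payload["arcs"])
    return dag


def write_dag(dag: nx.DiGraph, path: str | Path) -> None:
    Path(path).write_text(dag_to_json(dag))


def read_dag(path: str | Path) -> nx.DiGraph:
    return dag_from_json(Path(path).read_text())


# -- arcs TSV ----------------------------------------------------------

def write_arcs(avg: AveragedNetwork, path: str | Path) -> None:
    avg.arc_frame().to_csv(path, sep="\t", index=False)


def read_arcs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- arc weights / node colours ---------------------------------------

def _arc_weight(table: pd.DataFrame | None, meta, u: str, v: str
                ) -> float | None:
    if table is None or meta is None:
        return None
    index = meta_index(meta)
    mu, mv = index.get(u), index.get(v)
    if not (mu and mv and mu.ordinal and mv.ordinal):
        return None
    try:
        return abs(spearman(table, u, v, meta).statistic)
    except TestError:
        return None


# -- DOT ---------------------------------------------------------------

def to_dot(dag: nx.DiGraph, table: pd.DataFrame | None = None,
           meta: Sequence[VariableMeta] | None = None,
           name: str = "network") -> str:
    """Emit Graphviz DOT; arc penwidth scales with |Spearman rho|."""
    index = meta_index(meta) if meta else {}
    lines = [f'digraph "{name}" {{']
    for node in sorted(dag.nodes):
        attrs = []
        m = index.get(node)
        if m is not None and m.color:
            attrs.append(f'fillcolor="{m.color}"')
            attrs.append('style="filled"')
        if m is not None and m.engagement_class:
            attrs.append(f'tooltip="{m.engagement_class}"')
        attr_text = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f'  "{node}"{attr_text};')
    for u, v in sorted(dag.edges):
        weight = _arc_weight(table, meta, u, v)
        if weight is None:
            lines.append(f'  "{u}" -> "{v}";')
        else:
            pen = max(weight * MAX_PENWIDTH, 0.1)
            lines.append(
                f'  "{u}" -> "{v}" [penwidth={pen:.3f}, rho={weight:.4f}];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*(\[[^\]]*\])?\s*;')


def from_dot(text: str) -> nx.DiGraph:
    """Parse the DOT subset emitted by :func:`to_dot`."""
    dag = nx.DiGraph()
    for line in text.splitlines():
        edge = _DOT_EDGE.match(line)
        if edge:
            dag.add_edge(edge.group(1), edge.group(2))
            continue
        node = _DOT_NODE.match(line)
        if node:
            dag.add_node(node.group(1))
    return dag


# -- GraphML -----------------------------------------------------------

def write_graphml(dag: nx.DiGraph, path: str | Path,
                  table: pd.DataFrame | None = None,
                  meta: Sequence[VariableMeta] | None = None) -> None:
    g = nx.DiGraph()
    index = meta_index(meta) if meta else {}
    for node in sorted(dag.nodes):
        attrs = {}
        m = index.get(node)
        if m is not None and m.color:
            attrs["color"] = m.color
        if m is not None and m.engagement_class:
            attrs["engagement_class"] = m.engagement_class
        g.add_node(node, **attrs)
    for u, v in sorted(dag.edges):
        weight = _arc_weight(table, meta, u, v)
        if weight is None:
            g.add_edge(u, v)
        else:
            g.add_edge(u, v, rho=float(weight))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.DiGraph(nx.read_graphml(path))


def export_network(net: AveragedNetwork | nx.DiGraph, path: str | Path,
                   fmt: str = "dot",
                   table: pd.DataFrame | None = None,
                   meta: Sequence[VariableMeta] | None = None) -> None:
    """Write a network in DOT, GraphML or DAG-JSON form."""
    dag = net.dag if isinstance(net, AveragedNetwork) else net
    if fmt == "dot":
        Path(path).write_text(to_dot(dag, table, meta))
    elif fmt == "graphml":
        write_graphml(dag, path, table, meta)
    elif fmt == "json":
        write_dag(dag, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


# -- fitted network JSON ----------------------------------------------

def fitted_to_json(fitted: FittedNetwork) -> str:
    payload = {
        "nodes": sorted(fitted.dag.nodes),
        "arcs": sorted([u, v] for u, v in fitted.dag.edges),
        "cpts": {
            name: {
                "levels": list(cpt.levels),
                "parents": list(cpt.parents),
                "parent_levels": [list(lv) for lv in cpt.parent_levels],
                "table": [[float(p) for p in row] for row in cpt.table],
                "n_used": cpt.n_used,
                "no_data": list(cpt.no_data),
            }
            for name, cpt in sorted(fitted.cpts.items())
        },
    }
    return json.dumps(payload, indent=1)


def fitted_from_json(text: str) -> FittedNetwork:
    import numpy as np

    payload = json.loads(text)
    dag = nx.DiGraph()
    dag.add_nodes_from(payload["nodes"])
    dag.add_edges_from(tuple(arc) for arc in payload["arcs"])
    cpts = {
        name: NodeCPT(
            var=name,
            levels=tuple(d["levels"]),
            parents=tuple(d["parents"]),
            parent_levels=tuple(tuple(lv) for lv in d["parent_levels"]),
            table=np.array(d["table"], dtype=float),
            n_used=int(d["n_used"]),
            no_data=list(d["no_data"]),
        )
        for name, d in payload["cpts"].items()
    }
    return FittedNetwork(dag=dag, cpts=cpts)
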