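"""Network import/export: GraphML (via networkx) and DOT text.

Node attributes carry the variable kind and tier when a schema is given;
edge attributes carry bootstrap strength/direction when an arc-strength
table is given.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph import DirectedGraph
from .model import CohortSchema

__all__ = ["write_graphml", "read_graphml", "write_dot", "read_dot"]


def _annotated(graph: DirectedGraph, schema: CohortSchema | None,
               strengths: pd.DataFrame | None) -> nx.DiGraph:
    g = graph.to_networkx()
    if schema is not None:
        for node in g.nodes:
            if node in schema:
                spec = schema[node]
                g.nodes[node]["kind"] = spec.kind
                g.nodes[node]["tier"] = spec.tier
    if strengths is not None:
        lookup = {(r["from"], r["to"]): (float(r["strength"]), float(r["direction"]))
                  for _, r in strengths.iterrows()}
        for u, v in g.edges:
            if (u, v) in lookup:
                g.edges[u, v]["strength"], g.edges[u, v]["direction"] = lookup[(u, v)]
    return g


def write_graphml(graph: DirectedGraph, path: str | Path,
                  schema: CohortSchema | None = None,
                  strengths: pd.DataFrame | None = None) -> Path:
    path = Path(path)
    nx.write_graphml(_annotated(graph, schema, strengths), path)
    return path


def read_graphml(path: str | Path) -> DirectedGraph:
    return DirectedGraph.from_networkx(nx.read_graphml(Path(path)))


def write_dot(graph: DirectedGraph, path: str | Path,
              schema: CohortSchema | None = None,
              strengths: pd.DataFrame | None = None) -> Path:
    """Plain-text DOT writer (node kind/tier and edge strengths as attrs)."""
    g = _annotated(graph, schema, strengths)
    lines = ["digraph network {"]
    for node, attrs in g.nodes(data=True):
        attr_txt = ", ".join(f'{k}="{v}"' for k, v in attrs.items())
        lines.append(f'  "{node}"' + (f" [{attr_txt}]" if attr_txt else "") + ";")
    for u, v, attrs in g.edges(data=True):
        attr_txt = ", ".join(f'{k}="{val:.3f}"' if isinstance(val, float) else f'{k}="{val}"'
                             for k, val in attrs.items())
        lines.append(f'  "{u}" -> "{v}"' + (f" [{attr_txt}]" if attr_txt else "") + ";")
    lines.append("}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path

_DOT_EDGE = re.compile(r'^\s*"?([^"\s]+)"?\s*->\s*"?([^"\s\[;]+)"?\s*(?:\[[^\]]*\])?\s*;?\s*$')
_DOT_NODE = re.compile(r'^\s*"?([^"\s\[;]+)"?\s*(?:\[[^\]]*\])?\s*;?\s*$')


def read_dot(path: str | Path) -> DirectedGraph:
    """Minimal DOT reader for files produced by :func:`write_dot`."""
    nodes: list[str] = []
    edges: set[tuple[str, str]] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("digraph", "graph", "}", "//", "#")):
            continue
        m = _DOT_EDGE.match(line)
        if m:
            u, v = m.group(1), m.group(2)
            for name in (u, v):
                if name not in nodes:
                    nodes.append(name)
            edges.add((u, v))
            continue
        m = _DOT_NODE.match(line)
        if m and m.group(1) not in nodes:
            nodes.append(m.group(1))
    return DirectedGraph(tuple(nodes), frozenset(edges))
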