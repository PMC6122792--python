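"""Directed acyclic graphs over cohort variables and pure-graph reasoning.

A Bayesian network's structure is a DAG whose nodes are study variables and
whose edges point from "parent" to "child".  The structure alone supports a
surprising amount of reasoning -- Markov blankets, d-separation (graphical
conditional independence), and the factorization of the joint distribution
into local conditionals -- none of which needs fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "CyclicGraphError",
    "DirectedGraph",
    "markov_blanket",
    "d_separated",
    "factorization",
    "max_in_degree",
]


class CyclicGraphError(ValueError):
    """Raised when an operation requires acyclicity and the graph has a cycle."""


@dataclass
class DirectedGraph:
    """A directed graph with named nodes; edges are (parent, child) pairs.

    Node order is preserved (it drives the canonical factorization order);
    edge insertion order is irrelevant.  Acyclicity is *checked*, not
    enforced at construction, so intermediate states during structure search
    may be built freely and validated with :meth:`is_acyclic`.
    """

    nodes: tuple[str, ...] = ()
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self.edges = frozenset(tuple(e) for e in self.edges)
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")
            if u == v:
                raise ValueError(f"self-loop on {u!r}")

    # -- basic accessors ---------------------------------------------------
    def parents(self, node: str) -> set[str]:
        self._check_node(node)
        return {u for (u, v) in self.edges if v == node}

    def children(self, node: str) -> set[str]:
        self._check_node(node)
        return {v for (u, v) in self.edges if u == node}

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def _check_node(self, node: str) -> None:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")

    # -- edits (return new graphs; DirectedGraph is value-like) ------------
    def with_edge(self, u: str, v: str) -> "DirectedGraph":
        return DirectedGraph(self.nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "DirectedGraph":
        if (u, v) not in self.edges:
            raise KeyError(f"edge ({u!r}, {v!r}) not in graph")
        return DirectedGraph(self.nodes, self.edges - {(u, v)})

    # -- structure ---------------------------------------------------------
    def is_acyclic(self) -> bool:
        try:
            self.topological_order()
        except CyclicGraphError:
            return False
        return True

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises :class:`CyclicGraphError` on a cycle.

        Ties are broken by node order, so the result is deterministic.
        """
        indeg = {n: 0 for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in sorted(self.edges):
            indeg[v] += 1
            children[u].append(v)
        ready = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            ready.sort(key=self.nodes.index)
        if len(order) != len(self.nodes):
            raise CyclicGraphError("graph contains a directed cycle")
        return order

    def ancestors(self, node: str) -> set[str]:
        self._check_node(node)
        return nx.ancestors(self.to_networkx(), node)

    def descendants(self, node: str) -> set[str]:
        self._check_node(node)
        return nx.descendants(self.to_networkx(), node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        return cls(tuple(g.nodes), frozenset(g.edges))

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)


def markov_blanket(graph: DirectedGraph, node: str) -> set[str]:
    """Parents, children, and co-parents of children of ``node``.

    Conditional on its Markov blanket a node is independent of every other
    variable in the network, so the blanket is the set of variables with a
    *direct* statistical association with the node.
    """
    graph._check_node(node)
    parents = graph.parents(node)
    children = graph.children(node)
    co_parents: set[str] = set()
    for child in children:
        co_parents |= graph.parents(child)
    return (parents | children | co_parents) - {node}


def d_separated(
    graph: DirectedGraph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    conditioning: Iterable[str] = (),
) -> bool:
    """True iff every path between ``set_a`` and ``set_b`` is blocked.

    Standard d-separation semantics: chains and forks are blocked when the
    middle node is conditioned on; colliders are blocked unless the collider
    or one of its descendants is conditioned on.  Implemented via the
    moralized-ancestral-graph reachability algorithm (networkx).
    """
    a, b, c = set(set_a), set(set_b), set(conditioning)
    if a & b or a & c or b & c:
        raise ValueError("d-separation query sets must be disjoint")
    if not a or not b:
        raise ValueError("both endpoint sets must be nonempty")
    for n in a | b | c:
        graph._check_node(n)
    return nx.is_d_separator(graph.to_networkx(), a, b, c)


def factorization(graph: DirectedGraph) -> str:
    """Canonical product-of-conditionals string for the joint distribution.

    Nodes appear in schema (node) order; parentless nodes render as
    ``P(node)``, others as ``P(node|parent1,parent2,...)`` with parents in
    node order.  E.g. an edgeless two-node graph gives ``"P(A)⋅P(B)"``.
    """
    if not graph.is_acyclic():
        raise CyclicGraphError("factorization requires an acyclic graph")
    order = {n: i for i, n in enumerate(graph.nodes)}
    terms = []
    for node in graph.nodes:
        pa = sorted(graph.parents(node), key=order.__getitem__)
        terms.append(f"P({node}|{','.join(pa)})" if pa else f"P({node})")
    return "⋅".join(terms)


def max_in_degree(graph: DirectedGraph) -> int:
    """Largest parent-set size over all nodes (0 for an edgeless graph)."""
    return max((len(graph.parents(n)) for n in graph.nodes), default=0)
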