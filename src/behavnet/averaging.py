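"""Bootstrap model averaging: arc strengths and the consensus network.

A single learned structure can sit at a local optimum; resampling the
cohort and re-learning B structures measures how stable each edge is.  For
every unordered variable pair the *arc strength* is the fraction of
bootstrap structures containing the edge in either orientation, and the
*direction strength* is, among those, the fraction oriented a given way.
The averaged (consensus) network keeps arcs whose strength clears a
significance threshold estimated from the strength distribution itself,
oriented by majority direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .graph import DirectedGraph
from .learning import Blacklist, ScoreEngine, hill_climb
from .model import CohortSchema

__all__ = [
    "bootstrap_structures",
    "arc_strengths",
    "significance_threshold",
    "averaged_network",
    "AveragedNetwork",
]

logger = logging.getLogger(__name__)


@dataclass
class AveragedNetwork:
    """Consensus graph with the threshold and strength table that built it."""

    graph: DirectedGraph
    threshold: float
    strengths: pd.DataFrame
    replicates: int


def bootstrap_structures(
    data: pd.DataFrame,
    B: int,
    blacklist: Blacklist | None = None,
    seed: int = 0,
    schema: CohortSchema | None = None,
    restarts: int = 0,
    resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    progress_every: int = 50,
) -> list[DirectedGraph]:
    """Learn ``B`` structures, each on an n-row resample drawn with replacement.

    Replicate ``r`` uses the RNG substream seeded ``(seed, r)``, so any
    prefix of the run is reproducible independently of ``B``.  ``resampler``
    overrides the row-index draw (mainly for tests: an identity resampler
    makes B=1 equal a plain hill climb on the original data).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(data)
    graphs: list[DirectedGraph] = []
    for r in range(B):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, r])
        idx = resampler(rng, n) if resampler is not None else rng.integers(0, n, size=n)
        resample = data.iloc[np.asarray(idx)].reset_index(drop=True)
        graphs.append(
            hill_climb(resample, blacklist=blacklist, schema=schema,
                       seed=int(rng.integers(0, 2**31 - 1)), restarts=restarts)
        )
        if progress_every and (r + 1) % progress_every == 0:
            logger.info("bootstrap replicate %d/%d", r + 1, B)
    return graphs


def arc_strengths(graphs: Sequence[DirectedGraph]) -> pd.DataFrame:
    """Edge-stability table over a set of learned structures.

    One row per ordered pair (from, to): ``strength`` is the fraction of
    graphs containing the undirected edge, ``direction`` the fraction of
    those oriented from->to (0 when the edge never occurs).
    """
    if not graphs:
        raise ValueError("need at least one graph")
    nodes = graphs[0].nodes
    node_set = set(nodes)
    for g in graphs[1:]:
        if set(g.nodes) != node_set:
            raise ValueError("all graphs must share one node set")
    B = len(graphs)
    directed_counts: dict[tuple[str, str], int] = {}
    for g in graphs:
        for e in g.edges:
            directed_counts[e] = directed_counts.get(e, 0) + 1
    rows = []
    for u, v in combinations(nodes, 2):
        n_uv = directed_counts.get((u, v), 0)
        n_vu = directed_counts.get((v, u), 0)
        occur = n_uv + n_vu
        strength = occur / B
        rows.append({"from": u, "to": v, "strength": strength,
                     "direction": n_uv / occur if occur else 0.0})
        rows.append({"from": v, "to": u, "strength": strength,
                     "direction": n_vu / occur if occur else 0.0})
    return pd.DataFrame(rows)


def significance_threshold(strengths: Sequence[float]) -> float:
    """Data-driven arc-strength threshold.

    An ideal, perfectly stable bootstrap would put every arc strength at 0
    (noise arcs) or 1 (true arcs).  For each candidate threshold t (the
    distinct observed strengths) the empirical CDF of the strengths is
    compared, in L1 distance, with the idealized two-point CDF that puts
    mass F(t-) at 0 and 1 - F(t-) at 1; the minimizing t is returned, ties
    broken toward the larger t.
    """
    values = np.asarray(list(strengths), dtype=float)
    if values.size == 0:
        raise ValueError("empty strength list")
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("strengths must lie in [0, 1]")
    candidates = np.unique(values)
    best_t, best_l1 = None, np.inf
    for t in candidates:
        mass_at_zero = float(np.mean(values < t))
        l1 = _l1_to_two_point(values, mass_at_zero)
        if l1 < best_l1 - 1e-12 or (abs(l1 - best_l1) <= 1e-12 and (best_t is None or t > best_t)):
            best_t, best_l1 = float(t), l1
    return best_t


def _l1_to_two_point(values: np.ndarray, mass_at_zero: float) -> float:
    """Exact integral over [0, 1] of |F_hat(x) - G(x)| where G jumps
    ``mass_at_zero`` at 0 and the rest at 1."""
    points = np.unique(np.concatenate([[0.0], values, [1.0]]))
    total = 0.0
    for left, right in zip(points[:-1], points[1:]):
        f_hat = float(np.mean(values <= left))
        total += abs(f_hat - mass_at_zero) * (right - left)
    return total


def averaged_network(
    graphs: Sequence[DirectedGraph],
    threshold_override: float | None = None,
) -> AveragedNetwork:
    """Build the consensus network from bootstrap structures.

    Keeps undirected edges with strength >= threshold (estimated from the
    strength distribution unless overridden) and orients each by majority
    direction.  Exact 50/50 direction ties take the orientation that keeps
    the graph acyclic, then the lexicographically smaller one.  If majority
    orientation still produces a cycle (possible when averaging), the
    weakest edge on each residual cycle is dropped and logged.
    """
    table = arc_strengths(graphs)
    nodes = graphs[0].nodes
    und = table[table["from"] < table["to"]]
    if threshold_override is not None:
        threshold = float(threshold_override)
    else:
        threshold = significance_threshold(und["strength"].to_numpy())

    keep = und[(und["strength"] >= threshold) & (und["strength"] > 0.0)]
    keep = keep.sort_values(["strength", "from", "to"], ascending=[False, True, True])

    lookup = {(r["from"], r["to"]): r["direction"] for _, r in table.iterrows()}
    strength_of = {(r["from"], r["to"]): r["strength"] for _, r in table.iterrows()}
    graph = DirectedGraph(nodes, frozenset())
    for _, row in keep.iterrows():
        u, v = row["from"], row["to"]
        d_uv = lookup[(u, v)]
        if d_uv > 0.5:
            edge = (u, v)
        elif d_uv < 0.5:
            edge = (v, u)
        else:
            edge = (u, v) if graph.with_edge(u, v).is_acyclic() else (v, u)
        graph = graph.with_edge(*edge)

    graph = _repair_cycles(graph, strength_of)
    return AveragedNetwork(graph, threshold, table, len(graphs))


def _repair_cycles(graph: DirectedGraph, strength_of: dict) -> DirectedGraph:
    import networkx as nx

    while not graph.is_acyclic():
        cycle = nx.find_cycle(graph.to_networkx())
        weakest = min(cycle, key=lambda e: (strength_of.get((e[0], e[1]), 0.0), e))
        logger.warning("cycle repair: dropping weakest edge %s -> %s", *weakest)
        graph = graph.without_edge(*weakest)
    return graph
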