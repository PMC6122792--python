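"""Bootstrap averaging: strengths, threshold selection, consensus graph."""

import numpy as np
import pandas as pd
import pytest

import behavnet as bn
from behavnet.averaging import _l1_to_two_point


def threshold_oracle(values):
    """Direct numeric L1 integration over a dense grid, scanning candidates."""
    values = np.asarray(values, dtype=float)
    grid = np.linspace(0.0, 1.0, 20001)[:-1]
    f_hat = np.searchsorted(np.sort(values), grid, side="right") / values.size
    best_t, best_l1 = None, np.inf
    for t in np.unique(values):
        mass0 = np.mean(values < t)
        l1 = np.trapezoid(np.abs(f_hat - mass0), grid) + np.abs(f_hat[-1] - mass0) * (1.0 - grid[-1])
        if l1 < best_l1 - 1e-9 or (abs(l1 - best_l1) <= 1e-9 and (best_t is None or t > best_t)):
            best_t, best_l1 = float(t), l1
    return best_t


def _graphs(*edge_sets, nodes=("A", "B", "C")):
    return [bn.DirectedGraph(nodes, frozenset(es)) for es in edge_sets]


class TestArcStrengths:
    def test_identical_graphs(self):
        graphs = _graphs(*[{("A", "B")}] * 5)
        tab = bn.arc_strengths(graphs)
        row = tab[(tab["from"] == "A") & (tab["to"] == "B")].iloc[0]
        assert row["strength"] == 1.0 and row["direction"] == 1.0

    def test_split_directions(self):
        graphs = _graphs(*([{("A", "B")}] * 3 + [{("B", "A")}] * 3))
        tab = bn.arc_strengths(graphs)
        ab = tab[(tab["from"] == "A") & (tab["to"] == "B")].iloc[0]
        ba = tab[(tab["from"] == "B") & (tab["to"] == "A")].iloc[0]
        assert ab["strength"] == ba["strength"] == 1.0
        assert ab["direction"] == ba["direction"] == 0.5

    def test_hand_counted_mixture(self):
        tab = bn.arc_strengths(_graphs({("A", "B")}, {("A", "B")}, set()))
        ab = tab[(tab["from"] == "A") & (tab["to"] == "B")].iloc[0]
        assert ab["strength"] == pytest.approx(2 / 3)
        assert ab["direction"] == 1.0

    def test_direction_complementarity_and_edge_count_identity(self, cohort333, schema, blacklist):
        graphs = bn.bootstrap_structures(cohort333, 20, blacklist, seed=5, schema=schema)
        tab = bn.arc_strengths(graphs)
        occupied = tab[tab["strength"] > 0]
        pair_dir = occupied.set_index(["from", "to"])["direction"]
        for (u, v), d in pair_dir.items():
            assert d + pair_dir[(v, u)] == pytest.approx(1.0)
        mean_edges = np.mean([len(g.edges) for g in graphs])
        assert (tab["strength"] * tab["direction"]).sum() == pytest.approx(mean_edges)

    def test_inconsistent_node_sets_rejected(self):
        g1 = bn.DirectedGraph(("A", "B"))
        g2 = bn.DirectedGraph(("A", "C"))
        with pytest.raises(ValueError):
            bn.arc_strengths([g1, g2])


class TestSignificanceThreshold:
    def test_perfectly_separated(self):
        t = bn.significance_threshold([1.0, 1.0, 0.0, 0.0])
        assert 0.0 < t <= 1.0
        kept = [s for s in [1.0, 1.0, 0.0, 0.0] if s >= t]
        assert kept == [1.0, 1.0]

    def test_mixed_vector_matches_integration_oracle(self):
        values = [1.0, 0.95, 0.6, 0.1, 0.05]
        t = bn.significance_threshold(values)
        assert t == pytest.approx(threshold_oracle(values))
        kept = sorted(s for s in values if s >= t)
        oracle_kept = sorted(s for s in values if s >= threshold_oracle(values))
        assert kept == oracle_kept

    def test_all_equal_tie_rule_keeps_arcs(self):
        t = bn.significance_threshold([0.7] * 6)
        assert t == pytest.approx(0.7)  # largest candidate; 0.7 >= t so all retained

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            k = int(rng.integers(2, 30))
            values = np.round(rng.choice([0.0, 1.0, rng.random()], size=k,
                                         p=[0.4, 0.3, 0.3]) * rng.random(k), 3)
            values = np.clip(values, 0.0, 1.0)
            assert bn.significance_threshold(values) == pytest.approx(threshold_oracle(values))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bn.significance_threshold([])


class TestAveragedNetwork:
    def test_identical_bootstrap_graphs_reproduce_graph(self):
        graphs = _graphs(*[{("A", "B"), ("B", "C")}] * 10)
        avg = bn.averaged_network(graphs)
        assert avg.graph.edges == frozenset({("A", "B"), ("B", "C")})

    def test_threshold_above_one_empties_graph(self):
        graphs = _graphs(*[{("A", "B")}] * 4)
        avg = bn.averaged_network(graphs, threshold_override=1.01)
        assert avg.graph.edges == frozenset()

    def test_monotone_pruning(self, cohort333, schema, blacklist):
        graphs = bn.bootstrap_structures(cohort333, 25, blacklist, seed=8, schema=schema)
        edge_sets = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            edge_sets.append(bn.averaged_network(graphs, threshold_override=thr).graph.edges)
        for lower, higher in zip(edge_sets[:-1], edge_sets[1:]):
            undirected = lambda es: {frozenset(e) for e in es}
            assert undirected(higher) <= undirected(lower)

    def test_output_always_acyclic(self, cohort333, schema, blacklist):
        graphs = bn.bootstrap_structures(cohort333, 25, blacklist, seed=8, schema=schema)
        avg = bn.averaged_network(graphs)
        assert avg.graph.is_acyclic()

    def test_direction_tie_broken_toward_acyclicity(self):
        # A<->B split 50/50, B->C and C->A always present: orienting A->B
        # would close a cycle, so the tie must resolve to B->A
        graphs = _graphs(
            {("A", "B"), ("B", "C"), ("C", "A")},
            {("B", "A"), ("B", "C"), ("C", "A")},
        )
        avg = bn.averaged_network(graphs, threshold_override=0.9)
        assert avg.graph.is_acyclic()


class TestBootstrap:
    def test_identity_resample_equals_plain_hill_climb(self, cohort333, schema, blacklist):
        identity = lambda rng, n: np.arange(n)
        [g] = bn.bootstrap_structures(cohort333, 1, blacklist, seed=1, schema=schema,
                                      resampler=identity)
        direct = bn.hill_climb(cohort333, blacklist, schema=schema)
        assert g.edges == direct.edges

    def test_deterministic_and_prefix_stable(self, cohort333, schema, blacklist):
        g5 = bn.bootstrap_structures(cohort333, 5, blacklist, seed=4, schema=schema)
        g3 = bn.bootstrap_structures(cohort333, 3, blacklist, seed=4, schema=schema)
        assert [g.edges for g in g5[:3]] == [g.edges for g in g3]

    def test_independent_columns_have_weak_strengths(self):
        rng = np.random.default_rng(44)
        data = pd.DataFrame({k: rng.normal(size=200) for k in "ABCD"})
        graphs = bn.bootstrap_structures(data, 100, seed=21)
        tab = bn.arc_strengths(graphs)
        assert (tab["strength"] < 0.5).all()
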