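import numpy as np
import pandas as pd
import pytest

import behavnet as bn


@pytest.fixture(scope="session")
def config():
    return bn.default_config("total_pa")


@pytest.fixture(scope="session")
def schema(config):
    return config.schema


@pytest.fixture(scope="session")
def truth(config):
    """Calibrated ground-truth network for the total-PA variant."""
    return bn.ground_truth_network("total_pa", seed=0)


@pytest.fixture(scope="session")
def study_graph():
    return bn.study_structure("total_pa")


@pytest.fixture(scope="session")
def cohort333(truth, schema):
    """One n=333 synthetic cohort (the study's sample size)."""
    return bn.sample_cohort(truth, 333, seed=1, schema=schema).data.astype(float)


@pytest.fixture(scope="session")
def cohort50k(truth, schema):
    return bn.sample_cohort(truth, 50_000, seed=2, schema=schema).data.astype(float)


@pytest.fixture(scope="session")
def blacklist(schema):
    return bn.Blacklist.from_schema(schema)


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.35) -> bn.DirectedGraph:
    """Random DAG on letter-named nodes via a random topological order."""
    names = tuple(f"n{i}" for i in range(n_nodes))
    order = rng.permutation(n_nodes)
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.add((names[order[i]], names[order[j]]))
    return bn.DirectedGraph(names, frozenset(edges))


def brute_force_d_separated(graph: bn.DirectedGraph, set_a, set_b, conditioning) -> bool:
    """Independent oracle: enumerate all undirected simple paths and apply
    the blocking rules exhaustively."""
    a, b, c = set(set_a), set(set_b), set(conditioning)
    parents = {n: graph.parents(n) for n in graph.nodes}
    children = {n: graph.children(n) for n in graph.nodes}
    desc = {n: graph.descendants(n) for n in graph.nodes}

    def neighbors(n):
        return parents[n] | children[n]

    def path_active(path) -> bool:
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            into_prev = prev in parents[node]
            into_next = nxt in parents[node]
            is_collider = into_prev and into_next
            if is_collider:
                if node not in c and not (desc[node] & c):
                    return False
            else:
                if node in c:
                    return False
        return True

    def any_active_path(start, targets) -> bool:
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nb in neighbors(node):
                if nb in path:
                    continue
                new_path = path + [nb]
                if nb in targets:
                    if path_active(new_path):
                        return True
                else:
                    stack.append((nb, new_path))
        return False

    return not any(any_active_path(x, b) for x in a)
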