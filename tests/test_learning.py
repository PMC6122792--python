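"""Local BIC scores and hill-climbing structure search."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import behavnet as bn
from behavnet.learning import ScoreEngine, SingularDesignError


def gaussian_bic_oracle(y: np.ndarray, x: np.ndarray | None) -> float:
    """Independent reimplementation: direct density evaluation of the OLS fit."""
    n = len(y)
    design = np.ones((n, 1)) if x is None else np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sigma2 = max(float(resid @ resid) / n, 1e-6)
    loglik = norm.logpdf(resid, 0.0, math.sqrt(sigma2)).sum()
    p = design.shape[1] + 1
    return float(loglik - 0.5 * p * math.log(n))


class TestLocalScore:
    def test_parentless_binary_closed_form(self):
        data = pd.DataFrame({"Y": [0.0, 0.0, 1.0, 1.0]})
        score = bn.local_score("Y", (), data)
        assert score.value == pytest.approx(4 * math.log(0.5) - 0.5 * math.log(4))

    def test_gaussian_scores_match_density_oracle(self):
        rng = np.random.default_rng(17)
        n = 80
        data = pd.DataFrame({
            "A": rng.normal(size=n),
            "B": rng.normal(size=n),
            "C": rng.normal(size=n),
            "D": rng.normal(size=n),
        })
        data["D"] += 2.0 * data["A"] - data["B"]
        for parents in [(), ("A",), ("A", "B"), ("A", "B", "C")]:
            got = bn.local_score("D", parents, data).value
            x = data[list(parents)].to_numpy() if parents else None
            assert got == pytest.approx(gaussian_bic_oracle(data["D"].to_numpy(), x), rel=1e-9)

    def test_logistic_score_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        n = 300
        a = (rng.random(n) < 0.4).astype(float)
        b = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 1.2 * a - 0.8 * b)))).astype(float)
        data = pd.DataFrame({"A": a, "B": b, "Y": y})
        got = bn.local_score("Y", ("A", "B"), data).value
        design = sm.add_constant(data[["A", "B"]])
        llf = sm.Logit(y, design).fit(disp=0).llf
        assert got == pytest.approx(llf - 0.5 * 3 * math.log(n), rel=1e-7)

    def test_network_score_is_sum_of_local_scores(self, cohort333, schema, study_graph):
        total = bn.network_score(study_graph, cohort333, schema)
        order = {n: i for i, n in enumerate(study_graph.nodes)}
        parts = sum(
            bn.local_score(node,
                           sorted(study_graph.parents(node), key=order.__getitem__),
                           cohort333, schema).value
            for node in study_graph.nodes
        )
        assert total == pytest.approx(parts, rel=1e-9)

    def test_score_decomposability_on_edge_deletion(self, cohort333, schema, study_graph):
        engine = ScoreEngine(cohort333, schema)
        edge = ("BMI", "loginsulin")
        before = bn.network_score(study_graph, cohort333, schema, engine=engine)
        after = bn.network_score(study_graph.without_edge(*edge), cohort333, schema, engine=engine)
        child_before = bn.local_score("loginsulin", ("BMI",), cohort333, schema).value
        child_after = bn.local_score("loginsulin", (), cohort333, schema).value
        assert after - before == pytest.approx(child_after - child_before, rel=1e-9)

    def test_collinear_parents_raise(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=50)
        data = pd.DataFrame({"A": a, "B": 2 * a, "Y": rng.normal(size=50)})
        with pytest.raises(SingularDesignError):
            bn.local_score("Y", ("A", "B"), data)

    def test_cg_restriction_enforced(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame({"X": rng.normal(size=50),
                             "Y": (rng.random(50) < 0.5).astype(float)})
        with pytest.raises(SingularDesignError):
            bn.local_score("Y", ("X",), data)


class TestBlacklist:
    def test_tier_rules(self, schema, blacklist):
        for child in ("Age", "Education", "TumorStage", "YrsDXRND", "Neighborhood"):
            assert all(blacklist.forbids(u, child) for u in schema.names if u != child)
        for sink in ("QOLp", "QOLm"):
            assert all(blacklist.forbids(sink, v) for v in schema.names if v != sink)

    def test_cg_rule(self, schema, blacklist):
        assert blacklist.forbids("BMI", "Depression")  # continuous -> binary
        assert not blacklist.forbids("Depression", "BMI")

    def test_extra_pairs(self, schema):
        bl = bn.Blacklist.from_schema(schema, extra=[("Smoke", "BMI")])
        assert bl.forbids("Smoke", "BMI")


def enumerate_dags(names):
    """All DAGs over ``names`` (exhaustive; use only for <= 4 nodes)."""
    pairs = [(u, v) for u in names for v in names if u != v]
    for bits in range(2 ** len(pairs)):
        edges = frozenset(p for i, p in enumerate(pairs) if bits >> i & 1)
        g = bn.DirectedGraph(tuple(names), edges)
        if g.is_acyclic():
            yield g


class TestHillClimb:
    def test_recovers_single_strong_edge_under_blacklist(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        data = pd.DataFrame({"A": a, "B": 5.0 * a + rng.normal(size=500)})
        bl = bn.Blacklist(frozenset({("B", "A")}))
        learned = bn.hill_climb(data, bl)
        assert learned.edges == frozenset({("A", "B")})
        # exhaustive check over the two admissible graphs
        engine = ScoreEngine(data)
        with_edge = bn.network_score(learned, data, engine=engine)
        empty = bn.network_score(bn.DirectedGraph(("A", "B")), data, engine=engine)
        assert with_edge > empty

    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({k: rng.normal(size=500) for k in "ABC"})
        learned = bn.hill_climb(data)
        assert learned.edges == frozenset()
        best = max(enumerate_dags("ABC"), key=lambda g: bn.network_score(g, data))
        assert best.edges == frozenset()

    def test_single_noise_column(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"X": rng.normal(size=100)})
        assert bn.hill_climb(data).edges == frozenset()

    def test_beats_empty_graph_and_respects_constraints(self, cohort333, schema, blacklist):
        learned = bn.hill_climb(cohort333, blacklist, schema=schema)
        assert learned.is_acyclic()
        assert all(not blacklist.forbids(u, v) for u, v in learned.edges)
        engine = ScoreEngine(cohort333, schema)
        assert (bn.network_score(learned, cohort333, schema, engine=engine)
                >= bn.network_score(bn.DirectedGraph(learned.nodes), cohort333, schema,
                                    engine=engine))

    def test_matches_exhaustive_search_on_small_problems(self):
        # spot-check; the full 100-trial version runs with the acceptance suite
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            data = _random_linear_data(rng, n_nodes=4, n=400)
            learned = bn.hill_climb(data, seed=trial, restarts=10)
            engine = ScoreEngine(data)
            learned_score = bn.network_score(learned, data, engine=engine)
            best_score = max(bn.network_score(g, data, engine=engine)
                             for g in enumerate_dags(data.columns))
            hits += learned_score >= best_score - 1e-6
        assert hits >= 18

    def test_deterministic(self, cohort333, schema, blacklist):
        g1 = bn.hill_climb(cohort333, blacklist, schema=schema, seed=3, restarts=2)
        g2 = bn.hill_climb(cohort333, blacklist, schema=schema, seed=3, restarts=2)
        assert g1.edges == g2.edges


def _random_linear_data(rng, n_nodes=4, n=400):
    names = [f"X{i}" for i in range(n_nodes)]
    data = {}
    for i, name in enumerate(names):
        mean = np.zeros(n)
        for j in range(i):
            if rng.random() < 0.5:
                mean = mean + rng.uniform(0.5, 1.5) * data[names[j]]
        data[name] = mean + rng.normal(size=n)
    return pd.DataFrame(data)
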