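"""Network comparison (BIC, Bayes factors) and logic-sampling propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import behavnet as bn
from behavnet.learning import VARIANCE_FLOOR


class TestNetworkBIC:
    def test_constant_column_hits_variance_floor(self):
        # direct density computation at the floored ML variance
        g = bn.DirectedGraph(("X",))
        data = pd.DataFrame({"X": [0.0, 0.0, 0.0, 0.0]})
        schema = bn.CohortSchema((bn.VariableSpec("X", "continuous"),))
        report = bn.network_bic(g, data, schema)
        expected_loglik = norm.logpdf(0.0, 0.0, math.sqrt(VARIANCE_FLOOR)) * 4
        assert report.logLik == pytest.approx(expected_loglik, rel=1e-9)
        assert report.k == 2
        assert report.bic == pytest.approx(expected_loglik - 0.5 * 2 * math.log(4), rel=1e-9)

    def test_empty_graph_bic_is_sum_of_single_node_bics(self, cohort333, schema):
        nodes = bn.study_structure().nodes
        empty = bn.DirectedGraph(nodes)
        total = bn.network_bic(empty, cohort333, schema).bic
        parts = sum(
            bn.network_bic(bn.DirectedGraph((n,)), cohort333[[n]], schema).bic for n in nodes
        )
        assert total == pytest.approx(parts, rel=1e-9)

    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            bn.BICReport("m", logLik=-100.0, k=3, n=50, bic=-50.0)

    def test_reporting_path_reproduces_printed_difference(self):
        # sanity arithmetic on the reporting path: two BIC scores of
        # -14483.5 and -14637.4 differ by 153.9
        n, k = 333, 50
        ll_ref = -14483.5 + 0.5 * k * math.log(n)
        ll_alt = -14637.4 + 0.5 * k * math.log(n)
        ref = bn.BICReport("ref", ll_ref, k, n, ll_ref - 0.5 * k * math.log(n))
        alt = bn.BICReport("alt", ll_alt, k, n, ll_alt - 0.5 * k * math.log(n))
        assert ref.bic - alt.bic == pytest.approx(153.9, abs=1e-9)


class TestIsolateAndCompare:
    def test_isolate_sleep1_removes_its_three_edges(self, study_graph):
        isolated = bn.isolate_node(study_graph, "Sleep1")
        removed = study_graph.edges - isolated.edges
        assert removed == {("Insomnia", "Sleep1"), ("Depression", "Sleep1"),
                           ("Sleep1", "Sleep2")}

    def test_isolate_sleep2_removes_two_in_three_out(self, study_graph):
        isolated = bn.isolate_node(study_graph, "Sleep2")
        removed = study_graph.edges - isolated.edges
        assert len(removed) == 5
        assert sum(1 for (u, v) in removed if v == "Sleep2") == 2
        assert sum(1 for (u, v) in removed if u == "Sleep2") == 3

    def test_isolating_isolated_node_is_identity(self, study_graph):
        once = bn.isolate_node(study_graph, "Sleep1")
        assert bn.isolate_node(once, "Sleep1").edges == once.edges
        # tumor stage is already isolated in the study graph
        assert bn.isolate_node(study_graph, "TumorStage").edges == study_graph.edges

    def test_unknown_node_rejected(self, study_graph):
        with pytest.raises(KeyError):
            bn.isolate_node(study_graph, "Nope")

    def test_compare_identical_networks_gives_zero_delta(self, cohort333, schema, study_graph):
        rep = bn.compare_networks(study_graph, study_graph, cohort333, schema)
        assert rep.delta_vs_reference == pytest.approx(0.0, abs=1e-9)
        assert rep.log_bayes_factor == rep.delta_vs_reference

    def test_deleting_true_edge_degrades_fit(self, cohort333, schema, study_graph):
        rep = bn.compare_networks(study_graph, study_graph.without_edge("BMI", "loginsulin"),
                                  cohort333, schema)
        assert rep.delta_vs_reference > 0

    def test_deleting_nonexistent_edge_errors(self, study_graph):
        with pytest.raises(KeyError):
            study_graph.without_edge("Age", "QOLm")


class TestPropagation:
    def test_vacuous_evidence_recovers_marginal(self, truth):
        vacuous = bn.Evidence.interval("BMI", -math.inf, math.inf)
        r = bn.propagate(truth, [vacuous], [vacuous], "QOLp",
                         min_accepted=30_000, seed=1)
        assert r.delta == pytest.approx(0.0, abs=0.3)
        assert r.mean_a == pytest.approx(66.2, abs=0.3)

    def test_marginally_independent_evidence_has_no_effect(self, truth):
        # neighborhood walkability has no edges: conditioning on it cannot
        # move physical quality of life
        high = bn.Evidence.quantile("Neighborhood", 0.75, 1.0)
        low = bn.Evidence.quantile("Neighborhood", 0.0, 0.25)
        r = bn.propagate(truth, [high], [low], "QOLp", min_accepted=30_000, seed=2)
        assert r.delta == pytest.approx(0.0, abs=0.4)

    def test_degenerate_query_rejected(self, truth):
        ev = bn.Evidence.interval("BMI", 30, math.inf)
        with pytest.raises(ValueError, match="degenerate"):
            bn.propagate(truth, [ev], [ev], "BMI")

    def test_unknown_variable_rejected(self, truth):
        with pytest.raises(KeyError):
            bn.propagate(truth, [bn.Evidence.interval("Nope", 0, 1)],
                         [bn.Evidence.interval("BMI", 0, 99)], "QOLp")

    def test_zero_acceptance_errors_with_advice(self, truth):
        impossible = bn.Evidence.interval("BMI", 1e6, 1e6 + 1)
        ok = bn.Evidence.interval("BMI", -math.inf, math.inf)
        with pytest.raises(RuntimeError, match="widen"):
            bn.propagate(truth, [impossible], [ok], "QOLp",
                         min_accepted=1000, batch=10_000, max_draws=30_000)

    def test_low_precision_flagged_at_draw_cap(self, truth):
        rare = bn.Evidence.interval("BMI", 45.0, math.inf)  # ~0.2% acceptance
        ok = bn.Evidence.interval("BMI", -math.inf, math.inf)
        r = bn.propagate(truth, [rare], [ok], "QOLp",
                         min_accepted=100_000, batch=20_000, max_draws=40_000)
        assert r.low_precision
        assert r.accepted_draws_a < 100_000

    def test_markov_blanket_evidence_screens_off_other_variables(self, truth):
        # clamp insulin's Markov blanket; adding evidence on a non-blanket
        # variable (depression) must not move the outcome mean
        blanket = [
            bn.Evidence.interval("BMI", 29.0, 33.0),
            bn.Evidence.interval("PA", 180.0, 330.0),
            bn.Evidence.interval("Age", 58.0, 68.0),
            bn.Evidence.interval("Sleep2", 42.0, 52.0),
        ]
        with_extra = blanket + [bn.Evidence.category("Depression", 1)]
        r = bn.propagate(truth, blanket, with_extra, "loginsulin",
                         min_accepted=10_000, seed=3)
        mc_noise = 4 * (r.sd_a / math.sqrt(r.accepted_draws_a)
                        + r.sd_b / math.sqrt(r.accepted_draws_b))
        assert abs(r.delta) < mc_noise

    def test_quantile_evidence_bounds_resolved_from_marginal(self, truth):
        bad = bn.Evidence.quantile("Sleep2", 0.75, 1.0)
        good = bn.Evidence.quantile("Sleep2", 0.0, 0.25)
        r = bn.propagate(truth, [bad], [good], "QOLm", min_accepted=20_000, seed=4)
        # worst-quartile sleep impairment is far worse for mental QoL
        assert r.delta > 20.0

    def test_preset_queries_well_formed(self):
        queries = bn.intervention_queries("total_pa")
        assert len(queries) == 9
        outcomes = [q.outcome for q in queries]
        assert outcomes.count("QOLp") == 3 and outcomes.count("QOLm") == 3
        assert "BMI" in outcomes and "loginsulin" in outcomes and "logcrp" in outcomes
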