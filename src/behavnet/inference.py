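"""Network comparison (BIC, Bayes factors) and evidence propagation.

Two networks fitted to the same cohort are compared by the rescaled BIC
``logLik - 0.5 * k * log(n)`` (higher is better); the log Bayes factor
between them is approximated by the BIC difference.  "What-if" intervention
queries are answered by logic sampling: ancestral (forward) sampling of the
joint, rejecting draws that fail the evidence, then summarizing the outcome
distribution under each of two evidence conditions.  This is observational
conditioning, not a do-operator intervention -- the distinction matters
when evidence variables have parents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .graph import DirectedGraph
from .learning import ScoreEngine, _graph_to_masks, _mask_to_indices
from .model import CohortSchema, FittedNetwork
from .study import OBESITY_THRESHOLD, PA_CUTPOINTS
from .synthetic import sample_cohort

__all__ = [
    "BICReport",
    "Evidence",
    "PropagationQuery",
    "PropagationResult",
    "network_bic",
    "isolate_node",
    "compare_networks",
    "propagate",
    "intervention_queries",
    "render_propagation_table",
]


@dataclass
class BICReport:
    """BIC accounting for one model, optionally relative to a reference."""

    model_label: str
    logLik: float
    k: int
    n: int
    bic: float
    delta_vs_reference: float | None = None
    log_bayes_factor: float | None = None

    def __post_init__(self) -> None:
        expected = self.logLik - 0.5 * self.k * math.log(self.n)
        if abs(self.bic - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("bic field inconsistent with logLik, k, n")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def network_bic(network: FittedNetwork | DirectedGraph, data: pd.DataFrame,
                schema: CohortSchema | None = None, label: str = "model",
                engine: ScoreEngine | None = None) -> BICReport:
    """Refit parameters for the structure on ``data`` and total up the BIC.

    Only the *structure* of ``network`` is used: each node's maximized
    local log-likelihood (ML variance for Gaussian nodes) and parameter
    count are recomputed on the data, so two structures are always compared
    on equal footing.
    """
    graph = network.graph if isinstance(network, FittedNetwork) else network
    if engine is None:
        engine = ScoreEngine(data[list(graph.nodes)], schema)
    masks = _graph_to_masks(graph, engine)
    loglik = 0.0
    k = 0
    for child, mask in enumerate(masks):
        parents = _mask_to_indices(mask)
        k_node = len(parents) + (1 if engine.is_binary[child] else 2)
        loglik += engine.score(child, mask) + 0.5 * k_node * engine.log_n
        k += k_node
    bic = loglik - 0.5 * k * math.log(engine.n)
    return BICReport(label, loglik, k, engine.n, bic)


def isolate_node(graph: DirectedGraph, node: str) -> DirectedGraph:
    """Remove every edge into or out of ``node`` (the node itself remains)."""
    graph._check_node(node)
    kept = frozenset((u, v) for (u, v) in graph.edges if node not in (u, v))
    return DirectedGraph(graph.nodes, kept)


def compare_networks(reference: DirectedGraph, alternative: DirectedGraph,
                     data: pd.DataFrame, schema: CohortSchema | None = None,
                     labels: tuple[str, str] = ("reference", "alternative")) -> BICReport:
    """BIC comparison of two structures on one cohort.

    Returns the alternative's report with ``delta_vs_reference`` =
    BIC(reference) - BIC(alternative); a positive value favors the
    reference, and equals the (approximate) log Bayes factor of reference
    over alternative.
    """
    if set(reference.nodes) != set(alternative.nodes):
        raise ValueError("networks must share one node set")
    engine = ScoreEngine(data[list(reference.nodes)], schema)
    ref = network_bic(reference, data, schema, labels[0], engine=engine)
    alt = network_bic(alternative, data, schema, labels[1], engine=engine)
    delta = ref.bic - alt.bic
    alt.delta_vs_reference = delta
    alt.log_bayes_factor = delta
    return alt


# -- evidence & propagation ------------------------------------------------

@dataclass(frozen=True)
class Evidence:
    """A predicate on one variable.

    * ``interval`` -- continuous variable in the half-open interval [lo, hi).
    * ``category`` -- binary variable equal to ``value`` (0 or 1).
    * ``quantile`` -- continuous variable between its marginal ``q_lo`` and
      ``q_hi`` quantiles (resolved against the unconditioned sampled
      population); q_lo = 0 / q_hi = 1 mean unbounded.
    """

    variable: str
    predicate: Literal["interval", "category", "quantile"]
    lo: float = -math.inf
    hi: float = math.inf
    value: int = 1

    def __post_init__(self) -> None:
        if self.predicate in ("interval", "quantile") and not self.lo < self.hi:
            raise ValueError(f"{self.variable}: need lo < hi")
        if self.predicate == "quantile" and not (0.0 <= self.lo and self.hi <= 1.0):
            raise ValueError(f"{self.variable}: quantile bounds must lie in [0, 1]")
        if self.predicate == "category" and self.value not in (0, 1):
            raise ValueError(f"{self.variable}: category value must be 0 or 1")

    @classmethod
    def interval(cls, variable: str, lo: float = -math.inf, hi: float = math.inf) -> "Evidence":
        return cls(variable, "interval", lo=lo, hi=hi)

    @classmethod
    def category(cls, variable: str, value: int) -> "Evidence":
        return cls(variable, "category", value=value)

    @classmethod
    def quantile(cls, variable: str, q_lo: float = 0.0, q_hi: float = 1.0) -> "Evidence":
        return cls(variable, "quantile", lo=q_lo, hi=q_hi)

    def resolve_bounds(self, marginal: np.ndarray) -> tuple[float, float]:
        if self.predicate == "interval":
            return self.lo, self.hi
        if self.predicate == "quantile":
            lo = -math.inf if self.lo <= 0.0 else float(np.quantile(marginal, self.lo))
            hi = math.inf if self.hi >= 1.0 else float(np.quantile(marginal, self.hi))
            return lo, hi
        return float(self.value), float(self.value)

    def describe(self) -> str:
        if self.predicate == "category":
            return f"{self.variable}={self.value}"
        if self.predicate == "quantile":
            lo = f"Q{self.lo:g}" if self.lo > 0 else ""
            hi = f"Q{self.hi:g}" if self.hi < 1 else ""
            return f"{self.variable} in [{lo},{hi})"
        return f"{self.variable} in [{self.lo:g},{self.hi:g})"


@dataclass(frozen=True)
class PropagationQuery:
    """A named pair of evidence conditions and an outcome variable."""

    name: str
    condition_a: tuple[Evidence, ...]
    condition_b: tuple[Evidence, ...]
    outcome: str


@dataclass
class PropagationResult:
    """Outcome summaries under two evidence conditions and their contrast."""

    outcome: str
    condition_a: tuple[Evidence, ...]
    condition_b: tuple[Evidence, ...]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    accepted_draws_a: int
    accepted_draws_b: int
    total_draws: int
    low_precision: bool = False
    name: str = ""

    @property
    def delta(self) -> float:
        return self.mean_b - self.mean_a

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "outcome": self.outcome,
            "condition_a": [e.describe() for e in self.condition_a],
            "condition_b": [e.describe() for e in self.condition_b],
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "delta": self.delta,
            "accepted_draws_a": self.accepted_draws_a,
            "accepted_draws_b": self.accepted_draws_b,
            "total_draws": self.total_draws,
            "low_precision": self.low_precision,
        }


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def propagate(
    network: FittedNetwork,
    condition_a: Sequence[Evidence],
    condition_b: Sequence[Evidence],
    outcome: str,
    min_accepted: int = 100_000,
    seed: int = 0,
    batch: int = 250_000,
    max_draws: int = 40_000_000,
    reference_draws: int = 200_000,
    name: str = "",
) -> PropagationResult:
    """Logic-sampling contrast of ``outcome`` under two evidence conditions.

    Forward-samples the full joint, rejecting draws that violate each
    condition's predicates (both conditions are screened against the same
    draw stream).  Quantile predicates are resolved against a dedicated
    unconditioned reference sample.  Sampling continues until both
    conditions reach ``min_accepted`` accepted draws or ``max_draws`` is
    hit, in which case the result is flagged ``low_precision``.
    """
    condition_a = tuple(condition_a)
    condition_b = tuple(condition_b)
    nodes = set(network.nodes)
    for ev in (*condition_a, *condition_b):
        if ev.variable not in nodes:
            raise KeyError(f"evidence variable {ev.variable!r} not in network")
        if ev.variable == outcome:
            raise ValueError(f"degenerate query: outcome {outcome!r} is an evidence variable")
    if outcome not in nodes:
        raise KeyError(f"outcome {outcome!r} not in network")

    needs_reference = any(
        ev.predicate == "quantile" for ev in (*condition_a, *condition_b)
    )
    bounds: dict[int, list[tuple[str, float, float]]] = {0: [], 1: []}
    reference = None
    if needs_reference:
        reference = sample_cohort(network, reference_draws, _derived_seed(seed, 7)).data
    for which, cond in ((0, condition_a), (1, condition_b)):
        for ev in cond:
            marginal = reference[ev.variable].to_numpy() if reference is not None else np.empty(0)
            lo, hi = ev.resolve_bounds(marginal)
            if ev.predicate == "category":
                bounds[which].append((ev.variable, lo - 0.5, hi + 0.5))
            else:
                bounds[which].append((ev.variable, lo, hi))

    acc: dict[int, list[np.ndarray]] = {0: [], 1: []}
    counts = [0, 0]
    total = 0
    batch_idx = 0
    while (counts[0] < min_accepted or counts[1] < min_accepted) and total < max_draws:
        draw = sample_cohort(network, batch, _derived_seed(seed, 100 + batch_idx)).data
        batch_idx += 1
        total += batch
        out_col = draw[outcome].to_numpy()
        for which in (0, 1):
            if counts[which] >= min_accepted:
                continue
            mask = np.ones(batch, dtype=bool)
            for var, lo, hi in bounds[which]:
                col = draw[var].to_numpy()
                mask &= (col >= lo) & (col < hi)
            accepted = out_col[mask]
            acc[which].append(accepted)
            counts[which] += accepted.size

    for which, cond in ((0, condition_a), (1, condition_b)):
        if counts[which] == 0:
            raise RuntimeError(
                f"no draws accepted for condition {[e.describe() for e in cond]}; "
                "widen the evidence predicates"
            )
    a = np.concatenate(acc[0]) if acc[0] else np.empty(0)
    b = np.concatenate(acc[1]) if acc[1] else np.empty(0)
    low_precision = counts[0] < min_accepted or counts[1] < min_accepted
    return PropagationResult(
        outcome=outcome,
        condition_a=condition_a,
        condition_b=condition_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        accepted_draws_a=counts[0],
        accepted_draws_b=counts[1],
        total_draws=total,
        low_precision=low_precision,
        name=name,
    )


def intervention_queries(variant: str = "total_pa") -> list[PropagationQuery]:
    """The shipped intervention-query presets (condition A -> condition B).

    Nine queries for the total-PA variant: raising total activity, moving
    from obese to non-obese BMI, improving sleep impairment from the worst
    to the best marginal quartile, and the combined BMI+sleep change, each
    against its downstream outcome.
    """
    lo_pa, hi_pa = PA_CUTPOINTS
    obese = Evidence.interval("BMI", OBESITY_THRESHOLD, math.inf)
    non_obese = Evidence.interval("BMI", -math.inf, OBESITY_THRESHOLD)
    bad_sleep = Evidence.quantile("Sleep2", 0.75, 1.0)
    good_sleep = Evidence.quantile("Sleep2", 0.0, 0.25)
    queries = []
    if variant == "total_pa":
        queries.append(PropagationQuery(
            "PA low to high -> BMI",
            (Evidence.interval("PA", -math.inf, lo_pa),),
            (Evidence.interval("PA", hi_pa, math.inf),),
            "BMI",
        ))
    for outcome in ("loginsulin", "logcrp", "QOLp", "QOLm"):
        queries.append(PropagationQuery(
            f"BMI obese to non-obese -> {outcome}", (obese,), (non_obese,), outcome))
    for outcome in ("QOLp", "QOLm"):
        queries.append(PropagationQuery(
            f"Sleep2 worst to best quartile -> {outcome}",
            (bad_sleep,), (good_sleep,), outcome))
    for outcome in ("QOLp", "QOLm"):
        queries.append(PropagationQuery(
            f"Sleep2 + BMI combined improvement -> {outcome}",
            (bad_sleep, obese), (good_sleep, non_obese), outcome))
    return queries


def render_propagation_table(results: Sequence[PropagationResult]) -> str:
    """Aligned text table of propagation contrasts."""
    rows = []
    for r in results:
        rows.append({
            "query": r.name or " & ".join(e.describe() for e in r.condition_b),
            "outcome": r.outcome,
            "A mean (SD)": f"{r.mean_a:.2f} ({r.sd_a:.2f})",
            "B mean (SD)": f"{r.mean_b:.2f} ({r.sd_b:.2f})",
            "delta (B-A)": f"{r.delta:+.3f}",
        })
    return pd.DataFrame(rows).to_string(index=False)
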