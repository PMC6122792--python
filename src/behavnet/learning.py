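"""Score-based DAG structure learning for mixed binary/continuous data.

The score is the network BIC in the "higher is better" rescaling
``logLik(M) - 0.5 * k * log(n)``, which decomposes into one term per node:
the maximized local log-likelihood (Gaussian for continuous children via
OLS, Bernoulli/logistic for binary children via Newton iterations) minus
the per-node parameter penalty.  Search is greedy hill climbing over
single-edge add/delete/reverse moves under a blacklist of forbidden
directions, starting from the empty graph, with optional random restarts.

The conditional-Gaussian restriction (binary children may not have
continuous parents) is enforced structurally, independent of the blacklist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import DirectedGraph
from .model import CohortSchema

__all__ = [
    "SingularDesignError",
    "Blacklist",
    "LocalScore",
    "local_score",
    "network_score",
    "hill_climb",
]

#: Absolute floor on the ML residual variance of a Gaussian local model,
#: used when a child is (numerically) an exact function of its parents.
VARIANCE_FLOOR = 1e-6

#: Logistic coefficients are capped at this magnitude during scoring; a fit
#: pushing against the cap indicates (quasi-)separation.
LOGISTIC_CAP = 30.0

#: A move must improve the score by more than this to be accepted.
IMPROVEMENT_TOL = 1e-6


class SingularDesignError(ValueError):
    """Raised when a local regression's design matrix is collinear."""


@dataclass(frozen=True)
class Blacklist:
    """Forbidden (parent, child) directions for structure learning."""

    forbidden: frozenset[tuple[str, str]] = frozenset()

    def forbids(self, parent: str, child: str) -> bool:
        return (parent, child) in self.forbidden

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.forbidden

    @classmethod
    def from_schema(cls, schema: CohortSchema, extra: Iterable[tuple[str, str]] = ()) -> "Blacklist":
        """Tier-derived blacklist: sinks have no children, roots no parents,
        and (CG restriction) binary children admit no continuous parents.
        ``extra`` adds explicit user-supplied pairs.
        """
        names = schema.names
        forbidden: set[tuple[str, str]] = set(tuple(p) for p in extra)
        for u in names:
            for v in names:
                if u == v:
                    continue
                if schema[u].tier == "outcome_sink":
                    forbidden.add((u, v))
                if schema[v].tier == "exogenous_root":
                    forbidden.add((u, v))
                if schema[u].kind == "continuous" and schema[v].kind == "binary":
                    forbidden.add((u, v))
        return cls(frozenset(forbidden))


@dataclass(frozen=True)
class LocalScore:
    """BIC contribution of one node given a parent set."""

    child: str
    parents: frozenset[str]
    value: float


def _infer_kinds(data: pd.DataFrame, schema: CohortSchema | None) -> dict[str, str]:
    if schema is not None:
        return {name: schema.kind(name) for name in data.columns if name in schema}
    kinds = {}
    for col in data.columns:
        values = data[col].to_numpy(dtype=float)
        kinds[col] = "binary" if np.isin(values, (0.0, 1.0)).all() else "continuous"
    return kinds


class ScoreEngine:
    """Cached per-node BIC scores over one dataset.

    Gaussian scores are computed from a precomputed Gram matrix (no pass
    over the rows per score); logistic scores aggregate rows into unique
    binary parent patterns before Newton iteration.  Results are cached by
    ``(child index, parent bitmask)``.
    """

    def __init__(self, data: pd.DataFrame, schema: CohortSchema | None = None):
        self.names: tuple[str, ...] = tuple(data.columns)
        self.index = {name: i for i, name in enumerate(self.names)}
        kinds = _infer_kinds(data, schema)
        self.is_binary = np.array([kinds[name] == "binary" for name in self.names])
        self.X = data.to_numpy(dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("data contains non-finite values")
        self.n = self.X.shape[0]
        self.log_n = math.log(self.n)
        z = np.hstack([np.ones((self.n, 1)), self.X])
        self.gram = z.T @ z
        self._cache: dict[tuple[int, int], float] = {}

    # -- local scores ------------------------------------------------------
    def score(self, child: int, mask: int) -> float:
        key = (child, mask)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        parents = _mask_to_indices(mask)
        if self.is_binary[child]:
            if any(not self.is_binary[p] for p in parents):
                raise SingularDesignError(
                    f"binary child {self.names[child]} cannot have continuous parents"
                )
            value = self._logistic_score(child, parents)
        else:
            value = self._gaussian_score(child, parents)
        self._cache[key] = value
        return value

    def _gaussian_score(self, child: int, parents: Sequence[int]) -> float:
        idx = [0] + [p + 1 for p in parents]
        a = self.gram[np.ix_(idx, idx)]
        b = self.gram[idx, child + 1]
        try:
            chol = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            raise SingularDesignError(
                f"collinear parent set {sorted(self.names[p] for p in parents)} "
                f"for child {self.names[child]}"
            ) from None
        beta = np.linalg.solve(chol.T, np.linalg.solve(chol, b))
        rss = max(float(self.gram[child + 1, child + 1] - beta @ b), 0.0)
        sigma2 = max(rss / self.n, VARIANCE_FLOOR)
        loglik = -0.5 * self.n * (math.log(2.0 * math.pi * sigma2)) - rss / (2.0 * sigma2)
        k = len(parents) + 2  # intercept, slopes, residual variance
        return loglik - 0.5 * k * self.log_n

    def _logistic_patterns(self, child: int, parents: Sequence[int]):
        y = self.X[:, child]
        if not parents:
            u = np.ones((1, 1))
            return u, np.array([float(self.n)]), np.array([float(y.sum())])
        p_cols = self.X[:, list(parents)]
        code = p_cols @ (2.0 ** np.arange(len(parents)))
        codes, inverse = np.unique(code, return_inverse=True)
        counts = np.bincount(inverse).astype(float)
        successes = np.bincount(inverse, weights=y)
        patterns = ((codes[:, None].astype(int) >> np.arange(len(parents))) & 1).astype(float)
        u = np.hstack([np.ones((len(codes), 1)), patterns])
        return u, counts, successes

    def _logistic_score(self, child: int, parents: Sequence[int]) -> float:
        u, counts, successes = self._logistic_patterns(child, parents)
        loglik, _, _ = _logistic_ml(u, counts, successes)
        k = len(parents) + 1
        return loglik - 0.5 * k * self.log_n

    # -- whole networks ----------------------------------------------------
    def graph_score(self, masks: Sequence[int]) -> float:
        return sum(self.score(c, m) for c, m in enumerate(masks))


def _mask_to_indices(mask: int) -> tuple[int, ...]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


def _logistic_ml(u: np.ndarray, counts: np.ndarray, successes: np.ndarray,
                 tol: float = 1e-8, max_iter: int = 60) -> tuple[float, np.ndarray, bool]:
    """Maximized Bernoulli log-likelihood of a logistic model on aggregated
    patterns.  Returns (loglik, beta, converged); coefficients are capped at
    ``LOGISTIC_CAP`` so (quasi-)separated fits terminate with ``converged``
    False rather than diverging.
    """
    if successes.sum() == 0.0 or (counts - successes).sum() == 0.0:
        beta = np.zeros(u.shape[1])
        beta[0] = LOGISTIC_CAP if successes.sum() > 0 else -LOGISTIC_CAP
        return 0.0, beta, True
    beta = np.zeros(u.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = u @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = u.T @ (successes - counts * p)
        if np.abs(grad).max() < tol:
            converged = True
            break
        w = counts * p * (1.0 - p)
        h = (u * w[:, None]).T @ u
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            break
        beta = np.clip(beta + step, -LOGISTIC_CAP, LOGISTIC_CAP)
    eta = u @ beta
    loglik = float(successes @ eta - counts @ np.logaddexp(0.0, eta))
    return loglik, beta, converged


def local_score(child: str, parents: Iterable[str], data: pd.DataFrame,
                schema: CohortSchema | None = None) -> LocalScore:
    """Public single-node BIC score; raises on collinear designs."""
    engine = ScoreEngine(data, schema)
    mask = 0
    for p in parents:
        mask |= 1 << engine.index[p]
    value = engine.score(engine.index[child], mask)
    return LocalScore(child, frozenset(parents), value)


def network_score(graph: DirectedGraph, data: pd.DataFrame,
                  schema: CohortSchema | None = None,
                  engine: ScoreEngine | None = None) -> float:
    """Network BIC = sum of local scores (score decomposability)."""
    if engine is None:
        engine = ScoreEngine(data, schema)
    masks = _graph_to_masks(graph, engine)
    return engine.graph_score(masks)


def _graph_to_masks(graph: DirectedGraph, engine: ScoreEngine) -> list[int]:
    masks = [0] * len(engine.names)
    for u, v in graph.edges:
        masks[engine.index[v]] |= 1 << engine.index[u]
    return masks


def _closure(masks: Sequence[int], d: int) -> np.ndarray:
    """Boolean reachability matrix R[u, v] = path u -> v (length >= 1)."""
    adj = np.zeros((d, d), dtype=bool)
    for v, mask in enumerate(masks):
        for u in _mask_to_indices(mask):
            adj[u, v] = True
    reach = adj.copy()
    for k in range(d):
        reach |= np.outer(reach[:, k], reach[k, :])
    return reach


def _has_other_path(masks: Sequence[int], u: int, v: int, d: int) -> bool:
    """Path u ~> v avoiding the direct edge u -> v (for reverse moves)."""
    children: list[list[int]] = [[] for _ in range(d)]
    for c, mask in enumerate(masks):
        for p in _mask_to_indices(mask):
            if not (p == u and c == v):
                children[p].append(c)
    stack, seen = [u], {u}
    while stack:
        node = stack.pop()
        for c in children[node]:
            if c == v:
                return True
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def _admissible_matrix(engine: ScoreEngine, blacklist: Blacklist | None) -> np.ndarray:
    d = len(engine.names)
    allowed = np.ones((d, d), dtype=bool)
    np.fill_diagonal(allowed, False)
    for u in range(d):
        for v in range(d):
            if u == v:
                continue
            if engine.is_binary[v] and not engine.is_binary[u]:
                allowed[u, v] = False  # CG restriction, structural
            elif blacklist is not None and blacklist.forbids(engine.names[u], engine.names[v]):
                allowed[u, v] = False
    return allowed


def _climb_from(engine: ScoreEngine, masks: list[int], allowed: np.ndarray,
                tol: float) -> tuple[list[int], float]:
    d = len(engine.names)
    local = [engine.score(c, masks[c]) for c in range(d)]

    def try_score(child: int, mask: int) -> float:
        try:
            return engine.score(child, mask)
        except SingularDesignError:
            return -math.inf

    while True:
        reach = _closure(masks, d)
        best_delta = tol
        best_move: tuple | None = None

        def consider(delta: float, move: tuple) -> None:
            nonlocal best_delta, best_move
            if delta <= tol:
                return
            if best_move is None or delta > best_delta + 1e-12 or (
                abs(delta - best_delta) <= 1e-12
                and _move_key(engine, move) < _move_key(engine, best_move)
            ):
                best_delta, best_move = delta, move

        for u in range(d):
            bit_u = 1 << u
            for v in range(d):
                if u == v:
                    continue
                if not masks[v] & bit_u:
                    if allowed[u, v] and not reach[v, u]:
                        consider(try_score(v, masks[v] | bit_u) - local[v], ("add", u, v))
                else:
                    consider(try_score(v, masks[v] & ~bit_u) - local[v], ("delete", u, v))
                    if allowed[v, u] and not _has_other_path(masks, u, v, d):
                        delta = (try_score(v, masks[v] & ~bit_u) - local[v]
                                 + try_score(u, masks[u] | (1 << v)) - local[u])
                        consider(delta, ("reverse", u, v))
        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            masks[v] |= 1 << u
        elif kind == "delete":
            masks[v] &= ~(1 << u)
        else:
            masks[v] &= ~(1 << u)
            masks[u] |= 1 << v
            local[u] = engine.score(u, masks[u])
        local[v] = engine.score(v, masks[v])
    return masks, engine.graph_score(masks)


def _move_key(engine: ScoreEngine, move: tuple) -> tuple:
    kind, u, v = move
    # Lexicographic (child, parent) tie-break for determinism.
    return (engine.names[v], engine.names[u], kind)


def _random_dag_masks(engine: ScoreEngine, allowed: np.ndarray,
                      rng: np.random.Generator) -> list[int]:
    d = len(engine.names)
    order = rng.permutation(d)
    masks = [0] * d
    p_edge = min(2.0 / max(d - 1, 1), 0.5)
    for i in range(d):
        for j in range(i + 1, d):
            u, v = int(order[i]), int(order[j])
            if allowed[u, v] and rng.random() < p_edge:
                masks[v] |= 1 << u
    return masks


def hill_climb(data: pd.DataFrame, blacklist: Blacklist | None = None,
               seed: int = 0, restarts: int = 0,
               schema: CohortSchema | None = None,
               tol: float = IMPROVEMENT_TOL,
               engine: ScoreEngine | None = None) -> DirectedGraph:
    """Greedy BIC hill climbing from the empty graph.

    Each step applies the best strictly-improving add/delete/reverse move
    that keeps the graph acyclic and blacklist-compliant; equal-scoring
    moves break ties lexicographically by (child, parent) name so the
    search is deterministic.  With ``restarts > 0`` the search is repeated
    from random admissible DAGs (seeded) and the best-scoring local optimum
    is returned.
    """
    if engine is None:
        engine = ScoreEngine(data, schema)
    allowed = _admissible_matrix(engine, blacklist)
    masks, best_score = _climb_from(engine, [0] * len(engine.names), allowed, tol)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        start = _random_dag_masks(engine, allowed, rng)
        cand, cand_score = _climb_from(engine, start, allowed, tol)
        if cand_score > best_score + 1e-12:
            masks, best_score = cand, cand_score
    edges = set()
    for v, mask in enumerate(masks):
        for u in _mask_to_indices(mask):
            edges.add((engine.names[u], engine.names[v]))
    return DirectedGraph(engine.names, frozenset(edges))
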