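"""Fit the local conditional distributions of a fixed DAG, with SEs.

Continuous children are fit by ordinary least squares (residual SD reported
with the unbiased n-p denominator); binary children by maximum-likelihood
logistic regression (Newton iterations, coefficients reported as log-odds
ratios).  The fitted network can then be rendered as a coefficient table
merging the estimates with bootstrap arc/direction strengths, mirroring the
usual "child, parent, strength, direction, estimate (SE)" reporting layout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .graph import DirectedGraph
from .model import CohortSchema, ConditionalDistribution, FittedNetwork
from .learning import SingularDesignError, _infer_kinds

__all__ = ["SeparationError", "fit_network", "coefficient_report", "render_coefficient_table"]


class SeparationError(ValueError):
    """Raised when a logistic fit is perfectly separated."""


def _fit_gaussian(node: str, y: np.ndarray, x: pd.DataFrame) -> ConditionalDistribution:
    design = sm.add_constant(x, has_constant="add")
    try:
        res = sm.OLS(y, design).fit()
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise SingularDesignError(f"{node}: singular design") from err
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularDesignError(f"{node}: collinear parents {list(x.columns)}")
    p = design.shape[1]
    resid_sd = float(np.sqrt(res.ssr / (len(y) - p)))
    resid_sd = max(resid_sd, 1e-6)  # exact-interpolation floor
    return ConditionalDistribution(
        child=node,
        parents=tuple(x.columns),
        form="linear_gaussian",
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in x.columns},
        residual_sd=resid_sd,
        coefficient_se={c: float(res.bse[c]) for c in x.columns},
        intercept_se=float(res.bse["const"]),
    )


def _fit_logistic(node: str, y: np.ndarray, x: pd.DataFrame, ridge: float) -> ConditionalDistribution:
    design = sm.add_constant(x, has_constant="add")
    if ridge > 0.0:
        return _fit_logistic_ridge(node, y, design, x.columns, ridge)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning) as err:
            raise SeparationError(f"perfect separation fitting node {node!r}") from err
        except np.linalg.LinAlgError as err:
            raise SingularDesignError(f"{node}: singular design") from err
    if np.abs(res.params.to_numpy()).max() > 20.0:
        raise SeparationError(f"perfect separation fitting node {node!r}")
    return ConditionalDistribution(
        child=node,
        parents=tuple(x.columns),
        form="logistic",
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in x.columns},
        coefficient_se={c: float(res.bse[c]) for c in x.columns},
        intercept_se=float(res.bse["const"]),
    )


def _fit_logistic_ridge(node: str, y: np.ndarray, design: pd.DataFrame,
                        parent_cols, ridge: float) -> ConditionalDistribution:
    """L2-penalized logistic fallback for degenerate (separated) data."""
    z = design.to_numpy(dtype=float)
    beta = np.zeros(z.shape[1])
    penalty = np.full(z.shape[1], ridge)
    penalty[0] = 0.0  # intercept unpenalized
    for _ in range(200):
        eta = z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = z.T @ (y - p) - penalty * beta
        if np.abs(grad).max() < 1e-8:
            break
        w = p * (1.0 - p)
        h = (z * w[:, None]).T @ z + np.diag(penalty)
        beta = beta + np.linalg.solve(h, grad)
    eta = z @ beta
    w = 1.0 / (1.0 + np.exp(-eta))
    h = (z * (w * (1 - w))[:, None]).T @ z + np.diag(penalty)
    bse = np.sqrt(np.diag(np.linalg.inv(h)))
    return ConditionalDistribution(
        child=node,
        parents=tuple(parent_cols),
        form="logistic",
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(parent_cols, beta[1:])},
        coefficient_se={c: float(s) for c, s in zip(parent_cols, bse[1:])},
        intercept_se=float(bse[0]),
    )


def fit_network(graph: DirectedGraph, data: pd.DataFrame,
                schema: CohortSchema | None = None, ridge: float = 0.0) -> FittedNetwork:
    """Fit every node's local distribution for a fixed structure.

    ``ridge`` > 0 switches binary nodes to an L2-penalized logistic fit,
    a fallback for user data where unpenalized ML separates.
    """
    missing = [n for n in graph.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"data is missing columns: {missing}")
    kinds = _infer_kinds(data[list(graph.nodes)], schema)
    order = {n: i for i, n in enumerate(graph.nodes)}
    locals_: dict[str, ConditionalDistribution] = {}
    for node in graph.nodes:
        parents = sorted(graph.parents(node), key=order.__getitem__)
        y = data[node].to_numpy(dtype=float)
        x = data[parents].astype(float)
        if kinds[node] == "binary":
            if any(kinds[p] != "binary" for p in parents):
                raise SingularDesignError(f"binary child {node} cannot have continuous parents")
            locals_[node] = _fit_logistic(node, y, x, ridge)
        else:
            locals_[node] = _fit_gaussian(node, y, x)
    return FittedNetwork(graph, locals_, n=len(data))


def coefficient_report(network: FittedNetwork, strengths: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per network edge: child, parent, strength, direction, estimate, se.

    ``strengths`` is an arc-strength table (from, to, strength, direction);
    edges absent from it get blank strengths with a warning.
    """
    lookup: dict[tuple[str, str], tuple[float, float]] = {}
    if strengths is not None:
        for _, r in strengths.iterrows():
            lookup[(r["from"], r["to"])] = (float(r["strength"]), float(r["direction"]))
    rows = []
    for child in network.nodes:
        dist = network.locals[child]
        for parent in dist.parents:
            if strengths is not None and (parent, child) not in lookup:
                warnings.warn(f"edge {parent}->{child} missing from strength table")
            strength, direction = lookup.get((parent, child), (np.nan, np.nan))
            rows.append({
                "child": child,
                "parent": parent,
                "strength": strength,
                "direction": direction,
                "estimate": dist.coefficients[parent],
                "se": dist.coefficient_se.get(parent, np.nan),
            })
    frame = pd.DataFrame(rows, columns=["child", "parent", "strength", "direction", "estimate", "se"])
    return frame.sort_values(["child", "parent"]).reset_index(drop=True)


def render_coefficient_table(report: pd.DataFrame) -> str:
    """Aligned text rendering of a coefficient report."""
    if report.empty:
        return "(no edges)"
    shown = report.copy()
    shown["estimate (se)"] = [
        f"{e:.3f} ({s:.3f})" if np.isfinite(s) else f"{e:.3f}"
        for e, s in zip(shown["estimate"], shown["se"])
    ]
    cols = ["child", "parent", "strength", "direction", "estimate (se)"]
    return shown[cols].to_string(index=False, na_rep="", float_format=lambda v: f"{v:.2f}")
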