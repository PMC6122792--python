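"""Variable schemas, local conditional distributions, and fitted networks.

The joint density of a conditional linear Gaussian (CG) Bayesian network
factors into one local model per node: a linear-Gaussian regression for each
continuous node (slopes for continuous parents, additive 0/1 shifts for
binary parents) and a logistic regression for each binary node (whose
parents must all be binary, the CG restriction).  Parentless log-scale count
variables may instead use a log-normal marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .graph import DirectedGraph

__all__ = [
    "VariableSpec",
    "CohortSchema",
    "ConditionalDistribution",
    "FittedNetwork",
    "log_likelihood",
]

Kind = Literal["binary", "continuous"]
Tier = Literal["exogenous_root", "behavior", "outcome_sink"]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class VariableSpec:
    """One study variable: its name, measurement kind, causal tier and units.

    ``tier`` drives the structure-learning blacklists: ``exogenous_root``
    variables (demographics, clinical history) may have no parents and
    ``outcome_sink`` variables (quality-of-life scores) may have no
    children.  ``transform="natural_log"`` marks variables stored on the
    natural-log scale of the raw assay (the biomarkers).
    """

    name: str
    kind: Kind
    tier: Tier = "behavior"
    transform: Literal["none", "natural_log"] = "none"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.tier not in ("exogenous_root", "behavior", "outcome_sink"):
            raise ValueError(f"{self.name}: unknown tier {self.tier!r}")
        if self.transform == "natural_log" and self.kind != "continuous":
            raise ValueError(f"{self.name}: natural_log transform requires a continuous variable")


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of variables defining one cohort table layout."""

    variables: tuple[VariableSpec, ...]
    network_variant: Literal["total_pa", "mvpa_sedentary"] = "total_pa"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique within a schema")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def kind(self, name: str) -> Kind:
        return self[name].kind

    def binary_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind == "binary")

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind == "continuous")


@dataclass
class ConditionalDistribution:
    """Local model of one node given its parents.

    * ``linear_gaussian`` -- continuous child; mean = intercept + sum of
      coefficient * parent value; Gaussian residual with ``residual_sd``.
    * ``logistic`` -- binary child with binary parents only; coefficients
      are log-odds ratios.
    * ``log_normal`` -- parentless continuous child whose log is Gaussian
      with mean ``intercept`` and sd ``residual_sd`` (used for skewed,
      strictly positive variables such as monthly drink counts).
    """

    child: str
    parents: tuple[str, ...]
    form: Literal["linear_gaussian", "logistic", "log_normal"]
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    residual_sd: float | None = None
    coefficient_se: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        if set(self.coefficients) != set(self.parents):
            raise ValueError(f"{self.child}: coefficients must cover exactly the parents")
        if self.form in ("linear_gaussian", "log_normal"):
            if self.residual_sd is None or self.residual_sd <= 0:
                raise ValueError(f"{self.child}: residual_sd must be positive")
        if self.form == "log_normal" and self.parents:
            raise ValueError(f"{self.child}: log_normal form is only for parentless nodes")
        if self.form == "logistic" and self.residual_sd is not None:
            raise ValueError(f"{self.child}: logistic form has no residual_sd")

    # -- evaluation --------------------------------------------------------
    def linear_predictor(self, parent_values: Mapping[str, np.ndarray]) -> np.ndarray:
        if not self.parents:
            return np.array(self.intercept, dtype=float)
        eta = np.full(np.asarray(parent_values[self.parents[0]]).shape, float(self.intercept))
        for p in self.parents:
            eta += self.coefficients[p] * np.asarray(parent_values[p], dtype=float)
        return eta

    def log_density(self, child_values: np.ndarray, parent_values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Pointwise log density/mass of the child given its parents."""
        y = np.asarray(child_values, dtype=float)
        if self.parents:
            eta = self.linear_predictor(parent_values)
        else:
            eta = np.full(y.shape, self.intercept)
        if self.form == "linear_gaussian":
            s2 = self.residual_sd**2
            return -0.5 * (LOG_2PI + math.log(s2)) - (y - eta) ** 2 / (2.0 * s2)
        if self.form == "log_normal":
            if np.any(y <= 0):
                raise ValueError(f"{self.child}: log_normal density requires positive values")
            ly = np.log(y)
            s2 = self.residual_sd**2
            return -0.5 * (LOG_2PI + math.log(s2)) - (ly - eta) ** 2 / (2.0 * s2) - ly
        # logistic: Bernoulli with mean expit(eta)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"{self.child}: binary child values must be 0/1")
        # log p = y*eta - log(1+exp(eta)), numerically stable via logaddexp
        return y * eta - np.logaddexp(0.0, eta)


@dataclass
class FittedNetwork:
    """A DAG plus one local conditional distribution per node."""

    graph: DirectedGraph
    locals: dict[str, ConditionalDistribution]
    n: int = 0

    def __post_init__(self) -> None:
        if set(self.locals) != set(self.graph.nodes):
            raise ValueError("every node needs exactly one local distribution")
        for node, dist in self.locals.items():
            if dist.child != node:
                raise ValueError(f"local distribution for {node!r} labelled {dist.child!r}")
            if set(dist.parents) != self.graph.parents(node):
                raise ValueError(f"{node}: local parents do not match graph parents")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.graph.nodes

    def parameter_count(self) -> int:
        """Free parameters: intercept + slopes (+ residual variance) per node."""
        k = 0
        for dist in self.locals.values():
            k += 1 + len(dist.parents)
            if dist.form in ("linear_gaussian", "log_normal"):
                k += 1
        return k


def log_likelihood(network: FittedNetwork, data: pd.DataFrame) -> float:
    """Log joint density of ``data`` under the network, summed over rows.

    The joint factors into local terms, so the result is the sum over nodes
    of the local log density of the node's column given its parents'
    columns.  All node columns must be present and finite.
    """
    missing = [n for n in network.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"data is missing columns: {missing}")
    total = 0.0
    for node in network.nodes:
        dist = network.locals[node]
        y = data[node].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ValueError(f"non-finite values in column {node!r}")
        pv = {p: data[p].to_numpy(dtype=float) for p in dist.parents}
        total += float(dist.log_density(y, pv).sum())
    return total
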