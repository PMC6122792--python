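"""Synthetic cohort generation calibrated to published summary tables.

No individual-level data are distributed with the package, so every
downstream stage (structure learning, averaging, fitting, comparison,
propagation) is exercised on synthetic cohorts drawn from a ground-truth
conditional-Gaussian network.  The generative model is pinned down in two
steps:

1. The network *structure* and the *edge coefficients* are taken from the
   published averaged network and its regression-coefficient table.
2. The free local parameters -- intercepts and residual SDs -- are derived
   so that every variable's implied marginal matches its published mean/SD
   (continuous) or prevalence (binary).  For linear-Gaussian nodes this is
   closed-form for the intercept and a Monte-Carlo pilot estimate of the
   explained variance for the residual; for logistic nodes the intercept is
   solved by one-dimensional root finding on the pilot parent joint.

Sampling is ancestral (topological order), with a dedicated RNG substream
per node derived by stably hashing the node name, so the draw for one
variable never depends on which other variables exist.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .graph import DirectedGraph
from .model import CohortSchema, ConditionalDistribution, FittedNetwork
from .study import MarginalTarget, study_coefficients, study_marginals, study_schema, study_structure

__all__ = [
    "CalibrationError",
    "GroundTruthConfig",
    "SyntheticCohort",
    "default_config",
    "derive_intercepts_and_residuals",
    "ground_truth_network",
    "sample_cohort",
    "simulate",
    "validate_marginals",
    "write_cohort",
    "read_cohort",
]

#: Fraction of the target variance kept as a residual-variance floor.
RESIDUAL_VARIANCE_FLOOR = 0.01

#: Pilot-simulation size used to estimate explained variances (>= 50,000).
PILOT_DRAWS = 100_000


class CalibrationError(ValueError):
    """Raised when a node's marginal target cannot be met by calibration."""


@dataclass
class GroundTruthConfig:
    """Everything needed to build the generative ground-truth network."""

    variant: Literal["total_pa", "mvpa_sedentary"]
    structure: DirectedGraph
    coefficients: dict[tuple[str, str], float]
    target_marginals: dict[str, MarginalTarget]
    n: int = 333
    seed: int = 0

    def __post_init__(self) -> None:
        for parent, child in self.structure.edges:
            if (parent, child) not in self.coefficients:
                raise ValueError(f"edge ({parent}, {child}) has no coefficient")
        for node in self.structure.nodes:
            if node not in self.target_marginals:
                raise ValueError(f"node {node} has no target marginal")

    @property
    def schema(self) -> CohortSchema:
        return study_schema(self.variant)

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "n": self.n,
            "seed": self.seed,
            "nodes": len(self.structure.nodes),
            "edges": len(self.structure.edges),
        }


@dataclass
class SyntheticCohort:
    """A complete simulated cohort plus the provenance needed to re-create it."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)


def default_config(variant: str = "total_pa", n: int = 333, seed: int = 0) -> GroundTruthConfig:
    """The study-calibrated ground-truth configuration for a variant."""
    return GroundTruthConfig(
        variant=variant,
        structure=study_structure(variant),
        coefficients=study_coefficients(variant),
        target_marginals=study_marginals(variant),
        n=n,
        seed=seed,
    )


def _node_substream(seed: int, node: str, purpose: str = "sample") -> np.random.Generator:
    """Deterministic per-node RNG; stable under adding/removing other nodes."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(purpose.encode()), zlib.crc32(node.encode())])


def _target_raw_mean(t: MarginalTarget) -> float:
    """Mean of the variable on its observation scale."""
    if t.family == "bernoulli":
        return t.mean
    if t.family == "log_normal":
        return float(np.exp(t.mean + 0.5 * t.sd**2))
    return t.mean


def derive_intercepts_and_residuals(
    config: GroundTruthConfig, n_pilot: int = PILOT_DRAWS
) -> FittedNetwork:
    """Calibrate intercepts and residual SDs so marginals hit their targets.

    Walks the DAG in topological order keeping a pilot sample of every
    already-calibrated node.  Linear-Gaussian intercepts are
    ``target mean - sum(coef * parent target mean)``; residual variance is
    the target variance minus the pilot-estimated variance of the linear
    predictor (floored at ``RESIDUAL_VARIANCE_FLOOR`` of the target
    variance).  Logistic intercepts are solved so the pilot-implied marginal
    prevalence matches the target to 1e-4.
    """
    if n_pilot < 50_000:
        raise ValueError("pilot simulation needs at least 50,000 draws")
    schema = config.schema
    order = {n: i for i, n in enumerate(schema.names)}
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(b"calibration")])
    pilot: dict[str, np.ndarray] = {}
    locals_: dict[str, ConditionalDistribution] = {}

    for node in config.structure.topological_order():
        target = config.target_marginals[node]
        parents = tuple(sorted(config.structure.parents(node), key=order.__getitem__))
        coefs = {p: config.coefficients[(p, node)] for p in parents}
        kind = schema.kind(node)

        if kind == "binary":
            if parents:
                eta_parents = sum(coefs[p] * pilot[p] for p in parents)

                def prevalence_gap(a: float) -> float:
                    return float(np.mean(expit(a + eta_parents))) - target.mean

                intercept = float(brentq(prevalence_gap, -30.0, 30.0, xtol=1e-6))
            else:
                intercept = float(logit(target.mean))
                eta_parents = 0.0
            dist = ConditionalDistribution(node, parents, "logistic", intercept, coefs)
            pilot[node] = (rng.random(n_pilot) < expit(intercept + eta_parents)).astype(float)
        elif target.family == "log_normal":
            if parents:
                raise CalibrationError(f"{node}: log-normal targets supported for root nodes only")
            dist = ConditionalDistribution(node, (), "log_normal", target.mean, {}, residual_sd=target.sd)
            pilot[node] = np.exp(target.mean + target.sd * rng.standard_normal(n_pilot))
        else:
            intercept = target.mean - sum(
                coefs[p] * _target_raw_mean(config.target_marginals[p]) for p in parents
            )
            if parents:
                eta = intercept + sum(coefs[p] * pilot[p] for p in parents)
                explained = float(np.var(eta))
            else:
                eta = np.full(n_pilot, intercept)
                explained = 0.0
            if explained >= target.variance:
                raise CalibrationError(
                    f"{node}: explained variance {explained:.4g} >= target variance "
                    f"{target.variance:.4g}; coefficients and marginals are inconsistent"
                )
            residual_var = max(target.variance - explained, RESIDUAL_VARIANCE_FLOOR * target.variance)
            dist = ConditionalDistribution(
                node, parents, "linear_gaussian", intercept, coefs, residual_sd=residual_var**0.5
            )
            pilot[node] = eta + dist.residual_sd * rng.standard_normal(n_pilot)
        locals_[node] = dist

    return FittedNetwork(config.structure, locals_, n=config.n)


@lru_cache(maxsize=8)
def ground_truth_network(
    variant: str = "total_pa", seed: int = 0, n_pilot: int = PILOT_DRAWS
) -> FittedNetwork:
    """Cached calibrated ground-truth network (treat the result as read-only)."""
    return derive_intercepts_and_residuals(default_config(variant, seed=seed), n_pilot=n_pilot)


def sample_cohort(
    network: FittedNetwork,
    n: int,
    seed: int,
    schema: CohortSchema | None = None,
    provenance: dict | None = None,
) -> SyntheticCohort:
    """Draw ``n`` subjects by ancestral sampling of the network.

    Deterministic given ``seed``; each node consumes its own RNG substream.
    Binary columns are 0/1 integers, continuous columns floats, ordered as
    in ``schema`` (or the network's node order).
    """
    columns: dict[str, np.ndarray] = {}
    for node in network.graph.topological_order():
        dist = network.locals[node]
        rng = _node_substream(seed, node)
        if dist.parents:
            eta = dist.linear_predictor({p: columns[p] for p in dist.parents})
        else:
            eta = np.full(n, float(dist.intercept))
        if dist.form == "logistic":
            columns[node] = (rng.random(n) < expit(eta)).astype(float)
        elif dist.form == "log_normal":
            columns[node] = np.exp(eta + dist.residual_sd * rng.standard_normal(n))
        else:
            columns[node] = eta + dist.residual_sd * rng.standard_normal(n)

    names = schema.names if schema is not None else network.graph.nodes
    frame = pd.DataFrame({name: columns[name] for name in names})
    if schema is not None:
        for name in schema.binary_names():
            frame[name] = frame[name].astype(np.int64)
    meta = {"seed": seed, "n": n, **(provenance or {})}
    return SyntheticCohort(frame, meta)


def simulate(config: GroundTruthConfig, n: int | None = None, seed: int | None = None) -> SyntheticCohort:
    """Calibrate (cached) and sample in one call."""
    network = ground_truth_network(config.variant, seed=config.seed)
    return sample_cohort(
        network,
        n if n is not None else config.n,
        seed if seed is not None else config.seed,
        schema=config.schema,
        provenance=config.summary(),
    )


def validate_marginals(cohort: SyntheticCohort | pd.DataFrame, config: GroundTruthConfig) -> pd.DataFrame:
    """Per-variable z-scores of the deviation of sample marginals from targets.

    The z-score compares the sample mean (or prevalence) with its target
    using the standard error implied by the target SD; any |z| > 4 is
    flagged.  Log-normal variables are validated on the log scale.
    """
    data = cohort.data if isinstance(cohort, SyntheticCohort) else cohort
    if len(data) == 0:
        raise ValueError("cohort is empty")
    n = len(data)
    rows = []
    for node in config.structure.nodes:
        t = config.target_marginals[node]
        values = data[node].to_numpy(dtype=float)
        if t.family == "bernoulli":
            observed = float(values.mean())
            se = (t.mean * (1.0 - t.mean) / n) ** 0.5
            z = (observed - t.mean) / se
            target = t.mean
        elif t.family == "log_normal":
            logs = np.log(values)
            observed = float(logs.mean())
            z = (observed - t.mean) / (t.sd / n**0.5)
            target = t.mean
        else:
            observed = float(values.mean())
            z = (observed - t.mean) / (t.sd / n**0.5)
            target = t.mean
        rows.append(
            {
                "variable": node,
                "family": t.family,
                "target_mean": target,
                "observed_mean": observed,
                "z": float(z),
                "flagged": bool(abs(z) > 4.0),
            }
        )
    return pd.DataFrame(rows)


# -- cohort file I/O -------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write the cohort CSV plus a ``<stem>.provenance.yaml`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(cohort.provenance, fh, sort_keys=True)
    return path


def read_cohort(path: str | Path, schema: CohortSchema | None = None) -> SyntheticCohort:
    """Read a cohort CSV (and its provenance sidecar when present)."""
    path = Path(path)
    data = pd.read_csv(path)
    bad = data.columns[~data.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        for col in bad:
            row = int(pd.to_numeric(data[col], errors="coerce").isna().idxmax())
            raise ValueError(f"non-numeric value in column {col!r}, row {row}")
    if schema is not None:
        missing = [v for v in schema.names if v not in data.columns]
        extra = [c for c in data.columns if c not in schema.names]
        if missing or extra:
            raise ValueError(f"schema mismatch: missing columns {missing}, unexpected columns {extra}")
        data = data[list(schema.names)]
    sidecar = path.with_suffix(".provenance.yaml")
    provenance = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = yaml.safe_load(fh) or {}
    return SyntheticCohort(data, provenance)
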