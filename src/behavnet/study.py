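"""Study-cohort description: schemas, ground-truth structures and targets.

The package ships a complete generative description of a cohort of 333
postmenopausal, overweight-or-obese breast-cancer survivors: 19 baseline
variables (demographics, clinical history, coping, neighborhood walkability,
sleep, depression/insomnia/arthritis status, BMI, physical activity,
log-scale fasting insulin and CRP, and SF-36 physical/mental quality of
life), the conditional-Gaussian network structure linking them, the
published regression coefficients on each edge, and the marginal
means/SDs/prevalences each variable should exhibit.

Two variants exist:

* ``total_pa`` -- physical activity enters as total accelerometer volume
  (counts/min/day) with parents age, sleep impairment and log-insulin.
* ``mvpa_sedentary`` -- total activity is deconstructed into
  moderate-to-vigorous activity (MVPA, min/day) and sedentary time
  (min/day); sedentary time has parents arthritis and MVPA, and age is an
  isolated node.

Biomarkers are stored on the natural-log scale of pg/mL (columns
``loginsulin``/``logcrp``) to avoid silent double transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .graph import DirectedGraph
from .model import CohortSchema, VariableSpec

__all__ = [
    "MarginalTarget",
    "study_schema",
    "study_structure",
    "study_coefficients",
    "study_marginals",
    "PA_CUTPOINTS",
    "OBESITY_THRESHOLD",
]

Variant = Literal["total_pa", "mvpa_sedentary"]

#: Named preset cut-points for the physical-activity intervention query
#: (counts/min/day): "low" activity < 270, "high" activity >= 380 (about a
#: 1-SD increase).
PA_CUTPOINTS = (270.0, 380.0)

#: BMI threshold (kg/m^2) separating overweight from obese.
OBESITY_THRESHOLD = 30.0


@dataclass(frozen=True)
class MarginalTarget:
    """Target marginal for one variable.

    ``family`` is ``"normal"`` (mean/sd), ``"bernoulli"`` (prevalence in
    ``mean``) or ``"log_normal"`` (mean/sd on the *log* scale).
    """

    family: Literal["normal", "bernoulli", "log_normal"]
    mean: float
    sd: float = 0.0

    @property
    def variance(self) -> float:
        if self.family == "bernoulli":
            return self.mean * (1.0 - self.mean)
        return self.sd**2


def _core_variables() -> list[VariableSpec]:
    V = VariableSpec
    return [
        V("TumorStage", "continuous", "exogenous_root", units="stage (1-3)"),
        V("YrsDXRND", "continuous", "exogenous_root", units="years"),
        V("Neighborhood", "continuous", "exogenous_root", units="NEWS walkability (0-6)"),
        V("Alcohol", "continuous", "behavior", units="drinks/month"),
        V("Coping", "continuous", "behavior", units="monitor-blunter (-16..16)"),
        V("Education", "continuous", "exogenous_root", units="college degree (0/1 proxy)"),
        V("Age", "continuous", "exogenous_root", units="years"),
        V("Smoke", "binary", "behavior", units="ever smoked"),
        V("Insomnia", "binary", "behavior", units="yes/no"),
        V("Depression", "binary", "behavior", units="yes/no"),
        V("Sleep1", "continuous", "behavior", units="PROMIS sleep disturbance"),
        V("Arthritis", "binary", "behavior", units="yes/no"),
        V("BMI", "continuous", "behavior", units="kg/m^2"),
        V("Sleep2", "continuous", "behavior", units="PROMIS sleep impairment"),
        V("QOLp", "continuous", "outcome_sink", units="SF-36 physical (0-100)"),
        V("QOLm", "continuous", "outcome_sink", units="SF-36 mental (0-100)"),
        V("loginsulin", "continuous", "behavior", "natural_log", units="ln pg/mL"),
        V("logcrp", "continuous", "behavior", "natural_log", units="ln pg/mL"),
    ]


def study_schema(variant: Variant = "total_pa") -> CohortSchema:
    """Cohort schema for the requested network variant (19 or 20 variables)."""
    variables = _core_variables()
    if variant == "total_pa":
        variables.append(VariableSpec("PA", "continuous", "behavior", units="counts/min/day"))
    elif variant == "mvpa_sedentary":
        variables.append(VariableSpec("MVPA", "continuous", "behavior", units="min/day"))
        variables.append(VariableSpec("Sedentary", "continuous", "behavior", units="min/day"))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return CohortSchema(tuple(variables), network_variant=variant)


_SHARED_EDGES: tuple[tuple[str, str], ...] = (
    ("Insomnia", "Depression"),
    ("Insomnia", "Sleep1"),
    ("Depression", "Sleep1"),
    ("Depression", "Arthritis"),
    ("Smoke", "BMI"),
    ("Depression", "Sleep2"),
    ("Sleep1", "Sleep2"),
    ("BMI", "QOLp"),
    ("Sleep2", "QOLp"),
    ("Arthritis", "QOLp"),
    ("Depression", "QOLm"),
    ("Sleep2", "QOLm"),
    ("BMI", "loginsulin"),
    ("BMI", "logcrp"),
)


def study_structure(variant: Variant = "total_pa") -> DirectedGraph:
    """The learned averaged-network structure for the requested variant."""
    schema = study_schema(variant)
    edges = list(_SHARED_EDGES)
    if variant == "total_pa":
        edges += [
            ("Arthritis", "BMI"),
            ("Age", "PA"),
            ("Sleep2", "PA"),
            ("loginsulin", "PA"),
        ]
    else:
        edges += [
            ("Arthritis", "Sedentary"),
            ("MVPA", "Sedentary"),
        ]
    return DirectedGraph(schema.names, frozenset(edges))


def study_coefficients(variant: Variant = "total_pa") -> dict[tuple[str, str], float]:
    """Published regression coefficient for every edge ``(parent, child)``.

    Binary children carry log-odds ratios; continuous children carry linear
    slopes (per unit of a continuous parent, additive shift for a binary
    parent).
    """
    shared = {
        ("Insomnia", "Depression"): 1.000,
        ("Insomnia", "Sleep1"): 10.641,
        ("Depression", "Sleep1"): 1.710,
        ("Depression", "Arthritis"): 0.704,
        ("Depression", "Sleep2"): 3.489,
        ("Sleep1", "Sleep2"): 0.665,
        ("BMI", "QOLp"): -0.689,
        ("Sleep2", "QOLp"): -0.921,
        ("Arthritis", "QOLp"): -7.439,
        ("Depression", "QOLm"): -7.029,
        ("Sleep2", "QOLm"): -1.060,
        ("BMI", "loginsulin"): 0.039,
        ("BMI", "logcrp"): 0.093,
    }
    if variant == "total_pa":
        return {
            **shared,
            ("Smoke", "BMI"): 1.157,
            ("Arthritis", "BMI"): 1.524,
            ("Age", "PA"): -4.563,
            ("Sleep2", "PA"): -1.905,
            ("loginsulin", "PA"): -43.926,
        }
    if variant == "mvpa_sedentary":
        return {
            **shared,
            ("Smoke", "BMI"): 1.196,
            ("Arthritis", "Sedentary"): -11.706,
            ("MVPA", "Sedentary"): -1.788,
        }
    raise ValueError(f"unknown variant {variant!r}")


def _blend_log_biomarker(obese: tuple[float, float], non_obese: tuple[float, float],
                         bmi_mean: float = 31.1, bmi_sd: float = 4.9) -> tuple[float, float]:
    """Marginal (mean, sd) of a log biomarker from obese/non-obese group stats.

    The published biomarker summaries are conditional on BMI >= 30 vs < 30;
    the marginal target blends them by the obesity prevalence implied by the
    untruncated Normal(bmi_mean, bmi_sd) BMI marginal (law of total
    mean/variance over the two BMI categories).
    """
    w = float(norm.sf(OBESITY_THRESHOLD, loc=bmi_mean, scale=bmi_sd))
    m1, s1 = obese
    m0, s0 = non_obese
    mean = w * m1 + (1.0 - w) * m0
    var = w * s1**2 + (1.0 - w) * s0**2 + w * (1.0 - w) * (m1 - m0) ** 2
    return mean, var**0.5


def _tumor_stage_moments() -> tuple[float, float]:
    # Stage distribution 48% / 35% / 17% for stages 1/2/3, treated as a
    # numeric 1-3 score.
    probs = {1: 0.48, 2: 0.35, 3: 0.17}
    mean = sum(k * p for k, p in probs.items())
    var = sum(k**2 * p for k, p in probs.items()) - mean**2
    return mean, var**0.5


def study_marginals(variant: Variant = "total_pa") -> dict[str, MarginalTarget]:
    """Target marginal distribution summaries for every schema variable."""
    ts_mean, ts_sd = _tumor_stage_moments()
    ins_mean, ins_sd = _blend_log_biomarker((6.29, 0.50), (5.99, 0.49))
    crp_mean, crp_sd = _blend_log_biomarker((15.28, 1.07), (14.56, 1.05))
    edu_p = 0.51
    targets = {
        "TumorStage": MarginalTarget("normal", ts_mean, ts_sd),
        "YrsDXRND": MarginalTarget("normal", 2.7, 2.0),
        "Neighborhood": MarginalTarget("normal", 3.1, 1.7),
        # Only the median (4 drinks/month) is published; log-normal with
        # log-sd 1.0 keeps the count positive and right-skewed.
        "Alcohol": MarginalTarget("log_normal", math.log(4.0), 1.0),
        "Coping": MarginalTarget("normal", 4.2, 3.5),
        # % with a college degree, carried as a continuous 0/1-scale proxy.
        "Education": MarginalTarget("normal", edu_p, (edu_p * (1 - edu_p)) ** 0.5),
        "Age": MarginalTarget("normal", 63.0, 6.9),
        "Smoke": MarginalTarget("bernoulli", 0.45),
        "Insomnia": MarginalTarget("bernoulli", 0.288),
        "Depression": MarginalTarget("bernoulli", 0.408),
        "Sleep1": MarginalTarget("normal", 50.5, 8.8),
        "Arthritis": MarginalTarget("bernoulli", 0.564),
        "BMI": MarginalTarget("normal", 31.1, 4.9),
        "Sleep2": MarginalTarget("normal", 46.9, 9.0),
        "QOLp": MarginalTarget("normal", 66.2, 18.7),
        "QOLm": MarginalTarget("normal", 73.6, 18.4),
        "loginsulin": MarginalTarget("normal", ins_mean, ins_sd),
        "logcrp": MarginalTarget("normal", crp_mean, crp_sd),
    }
    if variant == "total_pa":
        targets["PA"] = MarginalTarget("normal", 273.1, 108.6)
    elif variant == "mvpa_sedentary":
        # Log-normal matched to the printed mean 17.5 and SD 17.3 min/day.
        mvpa_mean, mvpa_sd = 17.5, 17.3
        s2 = math.log(1.0 + (mvpa_sd / mvpa_mean) ** 2)
        targets["MVPA"] = MarginalTarget("log_normal", math.log(mvpa_mean) - 0.5 * s2, s2**0.5)
        targets["Sedentary"] = MarginalTarget("normal", 471.0, 111.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return targets
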