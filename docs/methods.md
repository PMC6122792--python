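# Methods

## Model class

All networks are conditional linear Gaussian (CG): a DAG over mixed
binary/continuous variables in which every continuous node follows a linear
regression on its parents with homoscedastic Gaussian residuals (binary
parents enter as 0/1 additive shifts) and every binary node follows a
logistic regression whose parents must themselves be binary. The joint
density factorizes as `∏ᵢ Pr(Xᵢ | pa(Xᵢ))`. Networks with more than two
categories per discrete variable are out of scope; the binary case makes
the multinomial and logistic parameterizations coincide, and logistic form
is used throughout.

One extension beyond the two canonical forms: a *parentless* continuous
node may carry a log-normal marginal (`form="log_normal"`), used for
strictly positive, right-skewed variables — monthly alcohol drinks and
moderate-to-vigorous activity minutes — where a Gaussian would put
appreciable mass below zero. Its density includes the Jacobian term, and
sampling exponentiates a Gaussian draw.

## The study cohort and its two variants

The shipped schema describes a cohort of postmenopausal, overweight or
obese breast-cancer survivors (n = 333): demographics and clinical history
(age, education, tumor stage, years since diagnosis, neighborhood
walkability, coping), behaviors and symptoms (smoking, alcohol, insomnia,
depression, arthritis, two PROMIS sleep scores), BMI, log-scale fasting
insulin and CRP, SF-36 physical/mental quality of life, and physical
activity — either total accelerometer volume (`total_pa`, 19 variables) or
MVPA plus sedentary time (`mvpa_sedentary`, 20 variables). Biomarkers are
stored as natural logs of pg/mL (columns `loginsulin`, `logcrp`) so no
implicit transform can be applied twice; the published "log mg/L" CRP
group means (≈15.3) are only consistent with the pg/mL log scale
(ln 3.1 mg/L ≡ ln 3.1·10⁶ pg/mL ≈ 14.95), which is what the package uses.

Tier roles drive the structure-learning blacklist declaratively:
`outcome_sink` (QOLp, QOLm) nodes may have no children, `exogenous_root`
nodes (age, education, tumor stage, years since diagnosis, neighborhood)
no parents, and — the CG restriction — binary nodes may not have
continuous parents. These constraints are enforced structurally in the
search, independent of any user blacklist.

## Synthetic-data calibration

The ground-truth generator pins its free parameters to published summary
statistics in two steps, walking the DAG in topological order with a
Monte-Carlo pilot sample (100,000 draws; at least 50,000 required):

* **Linear-Gaussian nodes.** Intercept = target mean − Σ coef × parent
  target mean (a binary parent's mean is its prevalence). Residual
  variance = target variance − Var(linear predictor) estimated on the
  pilot sample, floored at 1% of the target variance; if the explained
  variance reaches the target variance the coefficients and marginals are
  inconsistent and calibration aborts naming the node.
* **Logistic nodes.** Intercept solved by Brent root finding so the
  pilot-implied marginal prevalence matches the target to 1e-4.

Choices worth knowing:

* The log-biomarker marginal targets blend the published obese/non-obese
  group means and SDs by the obesity prevalence implied by the untruncated
  Normal(31.1, 4.9) BMI marginal (law of total mean/variance). This choice
  reproduces the published conditional group means (log insulin 6.29/5.99,
  log CRP 15.28/14.56) to two decimals, which a direct use of either
  group's SD as the marginal SD would not.
* BMI is generated untruncated despite the overweight-only cohort: the
  untruncated moments reproduce the published BMI-by-category conditional
  means (31.5/30.5) to first order. An explicit truncation flag is not
  provided.
* Variables with no edges (tumor stage, years since diagnosis,
  neighborhood, education, alcohol, coping; smoke and insomnia as roots)
  are sampled independently from their marginals. Education's "% with a
  college degree" is carried as a continuous 0/1-scale proxy per the
  schema's typing; tumor stage becomes a numeric 1–3 score with moments
  from the published stage distribution. Alcohol's published summary is a
  median only (4 drinks/month); it fixes the log-normal's log-median and
  the log-SD is set to 1.0 as a realistic dispersion for monthly counts.
  MVPA's log-normal is moment-matched to mean 17.5, SD 17.3 min/day.
* The sleep-impairment local model (depression 3.489, sleep1 0.665) is the
  same in both variants; the total-activity variant's published
  coefficient table omits that row and the values are assumed to transfer.
* RNG design: cohort sampling gives each node its own substream derived by
  CRC-hashing the node name with the root seed, so adding or removing a
  variable never perturbs the draws of the others, and identical
  seed+config is bit-identical.

What the generator does *not* emulate: missing data, measurement error,
floor/ceiling effects in the 0–100 QoL scales, skewness in sleep scores,
and any residual dependence among the "isolated" variables. Passing tests
therefore demonstrate correctness of the pipeline under the stated
generative model, not robustness to real-data pathologies.

## Structure learning and scoring

The score is the rescaled BIC `logLik − ½·k·log n` (higher is better),
decomposed per node. Gaussian local scores use the ML variance (RSS/n) and
count intercept + slopes + variance as parameters; they are computed from
a precomputed Gram matrix via Cholesky solves, so a score costs microseconds
and collinear designs surface as errors naming the parent set. Logistic
local scores aggregate rows into unique binary parent patterns and run
Newton iterations (gradient tolerance 1e-8, coefficients capped at ±30 so
separated resamples terminate gracefully).

Hill climbing starts from the empty graph and greedily applies the best
add/delete/reverse move that keeps the graph acyclic and
blacklist-compliant, requiring an improvement > 1e-6 (floating-point
cycling guard); equal-scoring moves break ties lexicographically by
(child, parent) so the search is deterministic. Random restarts
(default 0) re-run from random admissible DAGs and keep the best local
optimum. A numerical note: the ML variance is floored at 1e-6 so constant
columns score finitely; reported residual SDs from `fit_network` use the
unbiased n−p denominator instead, while BIC computations always use the ML
variance — the two conventions are deliberate and kept consistent with the
scoring path.

Bootstrap averaging resamples n rows with replacement B times
(default 500), each replicate on its own `(seed, r)` RNG substream.
Arc strength counts the edge regardless of orientation; direction strength
is conditional on occurrence. The significance threshold scans the
distinct observed strengths and picks the t minimizing the L1 distance
between the strength ECDF and the idealized two-point CDF with mass
F(t⁻) at 0 and the rest at 1, ties toward larger t. Majority orientation
can in principle create directed cycles; exact 50/50 ties take the
acyclicity-preserving orientation, and any residual cycle is repaired by
dropping its weakest edge with a logged warning.

## Comparison and propagation

Network comparison refits both structures on the same data and reports
ΔBIC, which is also the reported log Bayes factor (an identity of the
reporting path, not an extra approximation step). Node isolation removes
all edges incident to a node, mirroring the "how much does this variable
matter" question.

Intervention queries use logic sampling: ancestral sampling of the full
joint in large vectorized batches, rejecting draws that violate each
condition's predicates, until both conditions reach the minimum accepted
draw count (default 100,000; results below it are flagged low-precision,
zero acceptance is an error). Interval evidence is half-open [lo, hi);
quantile evidence (e.g. "above the 75th percentile of sleep impairment")
resolves its cut-points against a dedicated unconditioned reference sample
of 200,000 draws. Joint conditions (sleep + BMI) condition jointly, not
sequentially. The published "5000 simulated datasets" is ambiguous between
datasets and draws; the default of ≥100,000 accepted draws per condition
keeps Monte-Carlo error well below the reporting precision. These are
observational conditionals; do-calculus truncated-factorization
interventions are deliberately out of scope and would differ whenever
evidence variables have parents.

## Known limitations

* The single known recovery gap: the combined sleep-plus-BMI contrast on
  mental quality of life. The published coefficients force a strong
  insomnia→sleep-disturbance→sleep-impairment/depression coupling, so
  conditioning on extreme sleep-impairment quartiles moves the posterior
  depression probability by ≈0.42 and the predicted mental-QoL gain lands
  ≈3–4 points above the published 23.3 (the sleep-only contrast lands just
  inside its band). No free generator parameter can reduce that coupling
  without contradicting a published coefficient or marginal; the
  corresponding acceptance test row is left failing by design.
* Absolute BICs depend on the realized cohort, so only BIC *differences*
  are recovered, not the published absolute scores.
* The threshold estimator sees the strengths of all unordered pairs
  (including never-occurring ones at 0), which matches the idealized
  two-point reference; feeding it only nonzero strengths would shift the
  ECDF and can move the threshold.

## Problem sizes used by the test suite

Cohorts of n = 333 (the study size) for learning/fitting; 50,000–200,000
rows for marginal validation; B = 500 bootstrap replicates for the
stability results (smaller B in quick demos); ≥100,000 accepted draws per
propagation condition; 50 seeded replicates for the BIC-recovery and
isolation-ordering statements and 200 for coefficient recovery.
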