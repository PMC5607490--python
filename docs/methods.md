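# Methods

## Model

`gomlife` implements a longitudinal Grade-of-Membership (GoM) model of
disease progression coupled to a Sullivan life table.  The data are
long-format categorical responses: subject *i* answers variable *j* (with
L_j ≥ 2 levels) at examinations t = 1..T on a semiannual grid (T = 21 covers
a 10-year horizon), plus a vital-status record giving the 6-month interval of
death or the last interval with known survival.

**Scores.**  Each subject carries a vector of K GoM scores
g_i(t) = (g_i1(t), …, g_iK(t)) ≥ 0 with Σ_k g_ik(t) = 1: a point on the
probability simplex expressing partial membership in K subtypes.  Subtypes
1..K−1 are *prognostic* (initial-presentation profiles); subtype K is the
*terminal* (severe, absorbing) endpoint.  K defaults to 4.

**Progression.**  Disease progression is deterministic given the intake
scores.  Each prognostic subtype k has a pure trajectory u_k(t) with
u_k(1) = e_k, and a subject's trajectory is the mixture
g_i(t) = Σ_k g_ik(1) u_k(t).  We parameterize the pure trajectories by
per-step upper-triangular row-stochastic *transfer matrices* P_t with
logistic (softmax) rows, u_k(t) = e_k P_1 … P_{t−1}.  This guarantees, by
construction: the vertex initial condition; simplex closure; no mass ever
moving from a higher-numbered to a lower-numbered subtype; a nondecreasing
terminal component (irreversibility); and contraction of any two composed
trajectories in total-variation distance (because each P_t is stochastic).
Free per-exam increments would give none of these for free.  At exam
resolution the scheme can represent arbitrary monotone terminal-approach
paths; cumulative conversion to the terminal subtype may remain below 100%.
No between-exam interpolation is defined — every computation lives on the
exam grid.

**Outcome probabilities.**  Each subtype has a response distribution λ_kj·
per variable, constant over examinations.  The probability that subject *i*
answers level *l* of variable *j* at exam *t* is the score-weighted mixture
Σ_k g_ik(t) λ_kjl.  Death is an auto-generated binary variable handled by
the same machinery: the 6-month death probability in interval *t* is
q_i(t) = Σ_k g_ik(t) λ_k,death, evaluated at the interval's starting exam.
Keeping death out of the user-supplied covariates separates the survival
likelihood from the item likelihoods while sharing the mixture algebra.
Disability is the top ("full-time care", FTC) level of the declared
disability variable (*equivalent institutional care* in the bundled preset).

**Weighted likelihood.**  Examination 1 is the only one at which scores span
the full range of the prognostic subtypes (later exams contract toward the
terminal vertex), so its item terms may carry a weight w1 ≥ 1:

    ℓ = Σ_i [ w1·Σ_{j∈exam 1} log p_ij1 + Σ_{t≥2} Σ_j log p_ijt
              + Σ_{t at risk} log(1−q_i(t)) + 1{death at t*} log q_i(t*) ]

Missing items are omitted (assumed absent at random); censored intervals
contribute nothing after censoring.  `select_exam1_weight` picks w1 from a
grid: each candidate is refit and the *unweighted* post-exam-1 log-likelihood
is compared with the w1 = 1 fit; the largest w1 whose deterioration (on the
AIC scale of 2 log-likelihood units) stays within a budget — default 2 units
per additional unit of w1 — is chosen.  The budget is a package choice; the
selection criterion's purpose is to limit the loss of fit for exams 2..T
while stabilizing the exam-1 score estimates.

## Estimation

Block-coordinate ascent on the weighted log-likelihood
(`LongitudinalGoM.fit`):

* **λ given scores** — EM sweeps.  Because g_i(t) is fixed, each response is
  a mixture observation; responsibilities are g_ik(t)λ_kjl / p and the
  M-step is the weighted level frequency.  Mortality λs update the same way
  with death/survival Bernoulli terms.
* **Initial scores given λ and trajectories** — since
  g_i(t) = g_i(1) U(t) with U(t) = P_1…P_{t−1}, every likelihood term is
  *linear* in g_i(1); each subject's block is a plain mixture likelihood in
  its initial scores and admits the classic monotone EM multiplicative
  update for mixture weights.
* **Transfer logits** — L-BFGS with an analytic adjoint gradient through the
  cumulative products U(t) and the softmax rows; a step is accepted only if
  the objective improves.

Each block is individually monotone, so the weighted log-likelihood never
decreases across accepted outer iterations (asserted in the test suite).
Random restarts (default 5) run a short burst of iterations; the best is
refined to convergence (relative log-likelihood change below `tol`).  Ties
go to the lowest restart index.  Mixture probabilities are floored at 1e−8
inside logarithms; initial scores are floored at 1e−8 and renormalized.
Chosen mortality λs can be clamped to zero via
`zero_mortality_subtypes` to reproduce parsimonious published fits; the
default leaves all λs free.

Latent subtypes are identified only up to a permutation of the prognostic
indices (the terminal index is pinned by the absorbing structure);
`align_prognostic_subtypes` matches fitted to reference columns by minimum
summed squared score differences (Hungarian assignment).

Single-examination prediction (`estimate_scores_single_exam`) maximizes the
exam-1 likelihood over the simplex with model parameters fixed, using the
same EM multiplicative update; a subtype-flat model yields the barycenter
with a warning.  Conditional λ estimation for held-out summary variables
(`fit_conditional_lambdas`) runs the λ-EM with all scores and trajectories
frozen, leaving the main model untouched.

## Life-table decomposition

Per subject, survival is the product of 6-month conditional survivals,
S(t) = Π_{s≤t}(1−q(s)) with S(0) = 1 at exam 1, and FTC prevalence is
π(t) = Σ_k g_k(t) λ_k,FTC.  Sullivan's method applies the prevalence to the
survival curve at each examination:

    TLE  = Δ Σ_{t=1..20} (S(t−1)+S(t))/2          (Δ = 0.5 years)
    DFLE = Δ Σ_{t=1..20} (F(t−1)+F(t))/2,   F(t) = S(t)(1−π(t))
    DLE  = TLE − DFLE

Person-years use the trapezoidal rule — the standard discretization when no
quadrature is prescribed; the choice shifts life expectancies by at most
Δ/2 and is isolated in `sullivan_decompose`.  Intake prevalence π(0) enters
the first trapezoid.  DLE is defined by subtraction, so TLE = DFLE + DLE
holds exactly.  Survival beyond exam 21 is censored: the grid truncates, no
extrapolated tail.  Group summaries report means with between-individual 95%
CIs (mean ± 1.96·SD/√n) and max/min/ratio rows whose ratio CI endpoints come
from the component CIs (low = max-low/min-high, high = max-high/min-low).

## Characterization and goodness of fit

Rational subgroups label each subject k when g_k(1) > 0.5 (at most one score
can exceed 1/2) and 0 otherwise.  Covariate salience compares each subtype's
λ distribution with the pooled marginal over all completed examinations
(each observation weighted equally): the Kullback–Leibler information
Σ_l λ_kjl log(λ_kjl/m_jl) (nats, 0·log 0 = 0) flags pairs above 0.50, and a
BIC statistic 2Δℓ − df·log n (df = (K−1)(L_j−1); subtype-specific λs refit
conditionally versus the shared marginal) must be positive for a severity
code.  Codes: H if the subtype's distribution stochastically dominates the
marginal (CDF everywhere ≤), L if dominated, M if neither dominates and
L_j ≥ 3 — a formalization of "the shift concentrates on intermediate
levels"; unordered variables stay uncoded because direction is undefined.
The same nested pair referred to χ²(df) gives the Wilks screening p-value;
covariates rank by ascending p, ties by descending KL.

Observed survival uses the product-limit estimator on the interval grid with
Greenwood variance; pointwise 95% bands are normal-scale, clipped to [0,1].
Simultaneous bands are equal-precision bands: the common critical value
solves the Miller–Siegmund boundary-crossing approximation over the observed
range of a(t) = nσ²(t)/(1+nσ²(t)), always exceeding the pointwise normal
quantile, so containment of the pointwise band is structural.  The band
method is isolated behind one function so a Hall–Wellner variant could be
swapped in.  Observed FTC rates among survivors use Wilson 95% intervals
(better small-sample behaviour than Wald); exams with no eligible survivors
are reported as gaps, never as zero.

## Synthetic cohorts

`generate_cohort` simulates from any model: intake scores from vertex point
masses plus a Dirichlet over the simplex, deterministic composed
trajectories, per-interval deaths from q_i(t), responses from the mixture
distributions, MCAR item missingness, and a truth record (true scores and
event intervals) for recovery tests.

The `predictors2_like` preset emulates the structure of a published
AD natural-history cohort: 229 subjects, 21 semiannual exams, 6 fixed + 73
time-varying covariates over 11 measurement domains, a 3-level equivalent-
institutional-care variable whose top level is FTC.  Parameters with public
values are encoded exactly — mortality λ = (0.006, 0, 0, 0.16), FTC
λ = (0, 0, 0, 0.832), trajectory terminal components (0.58, 0.99, 0.93)
solved to machine precision by choosing constant per-step transfer rates
(highest prognostic subtype first, small constant cross-flow 0.01 between
prognostic subtypes).  Unreported item λ tables are drawn once under a fixed
structural seed from a severity-graded family (Gaussian bumps over ordered
levels, centers increasing with subtype index) mixed with the uniform by a
`separation` weight.  Defaults and their calibration targets, chosen once:

| knob | default | rationale |
| --- | --- | --- |
| Dirichlet α | (0.55, 0.80, 0.35, 0.18) | reproduces the published subgroup mix (residual ≈ 40, vertex-dominant ≈ 60/90/29/10 at n = 229) |
| vertex masses | 10/229 at e₁, 3/229 at e₂ | vertex occupancy as published |
| missingness | 0.35 | MCAR stand-in for combined item + visit nonattendance, matching the ~119k available-data-point scale |
| separation | 0.78 | 35 of 79 covariates salient (max KL > 0.50), the published differentiation level |

What the generator does **not** emulate: instrument-level dependence between
items beyond the mixture, visit-schedule irregularities (the nominal 6-month
grid is assumed), informative missingness, and covariate-specific published
λ tables (unavailable).  Passing recovery tests therefore demonstrate that
the estimator inverts its own generative family at realistic size, sharpness
and censoring — not that it reproduces any particular clinical dataset.

## Problem sizes and numerical choices

Recovery runs fit n = 400–500 subjects with ~169 k observed data points;
the package's demonstration protocol uses exam-1 weight 2.0, 3 random
restarts of 10 burn-in iterations, and convergence tolerance 5e−7 on the
relative weighted log-likelihood (several hundred outer iterations).  The
recovered terminal-subtype mortality and FTC λs and the subtype-2 trajectory
endpoint are compared with their generating values within two Monte-Carlo
standard errors measured over five replicate generate-and-fit runs.
Model JSON round-trips are lossless for float64; cohort CSV round-trips are
exact; CLI CSV output is truncated to 6 significant digits (scores are
renormalized on load).

## Known limitations

* Joint maximum likelihood over per-subject scores and shared parameters
  carries the usual incidental-parameter small-sample bias; with ~350–500
  observations per subject it is within the Monte-Carlo noise above, but
  under-converged fits understate the terminal-subtype λs — tight tolerances
  matter more than restarts here.
* K is fixed by the user; no model-order selection is provided.
* No information-matrix standard errors for λ; uncertainty is carried at the
  life-expectancy level as between-individual variation.
* The exam-1 weight selection implements the stated *intent* of data-
  dependent weighting (limit post-exam-1 loss of fit) as a grid search with
  an AIC budget, not any particular published formula.
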