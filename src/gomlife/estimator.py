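"""Weighted maximum-likelihood fitting of the longitudinal GoM model.

`LongitudinalGoM` is a scikit-learn-style estimator: construct with
hyperparameters, call :meth:`fit` on a validated :class:`~gomlife.data_model.Cohort`,
and read the fitted parameters from trailing-underscore attributes.  Fitting is
block-coordinate ascent on the weighted log-likelihood:

* item and mortality lambdas: monotone EM sweeps with scores fixed,
* initial scores: monotone EM multiplicative updates (each subject's
  likelihood is a plain mixture in its initial scores),
* transfer-matrix logits of the pure trajectories: L-BFGS with an analytic
  adjoint gradient, accepted only when the objective improves.

Every accepted outer iteration therefore never decreases the weighted
log-likelihood.  Multiple random restarts are run briefly and the best one is
refined to convergence; ties go to the lowest restart index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _em
from .data_model import Cohort, SubtypeModel
from .trajectories import (
    PureTrajectorySet,
    cumulative_transfers,
    n_transfer_params,
    transfers_from_logits,
)


@dataclass
class EstimationConfig:
    """Tunable knobs for model fitting and exam-1 weight selection."""

    exam1_weight_grid: tuple = (1.0,)
    max_iterations: int = 200
    tol: float = 1e-5  # relative change of the weighted log-likelihood
    n_restarts: int = 5
    n_short_iterations: int = 15
    seed: int = 0
    prob_floor: float = 1e-8
    score_floor: float = 1e-8
    aic_budget_per_weight_unit: float = 2.0
    zero_mortality_subtypes: tuple = ()
    trajectory_maxiter: int = 10

    def __post_init__(self) -> None:
        if any(w < 1.0 for w in self.exam1_weight_grid):
            raise ValueError("exam-1 weights must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FitResult:
    """Outcome of :func:`fit_model`."""

    model: SubtypeModel
    initial_scores: np.ndarray  # (n, K)
    subjects: list
    weighted_log_likelihood: float
    unweighted_log_likelihood: float
    exam1_weight: float
    iteration_trace: np.ndarray
    converged: bool


class LongitudinalGoM(BaseEstimator):
    """Longitudinal Grade-of-Membership model with deterministic progression.

    Parameters
    ----------
    n_subtypes : number of subtypes K (last one terminal/absorbing), default 4.
    exam1_weight : weight w1 >= 1 on examination-1 likelihood terms.  The first
        examination is the only one spanning the full range of the prognostic
        subtypes, so its data may be up-weighted (see
        :func:`gomlife.likelihood.select_exam1_weight`).
    max_iter, tol : outer-iteration budget and relative log-likelihood
        convergence tolerance.
    n_restarts, n_short_iter : random restarts are run for ``n_short_iter``
        outer iterations each; the best is refined to convergence.
    zero_mortality_subtypes : 1-based subtype indices whose 6-month death
        probability is clamped to zero (optional parsimony constraint).
    random_state : seed for restarts and initialization.

    Attributes (after fit)
    ----------------------
    lambdas_ : dict variable name -> (K, L_j) pure-subtype response probabilities.
    mortality_lambdas_ : (K,) per-subtype 6-month death probabilities.
    pure_trajectories_ : PureTrajectorySet with the fitted paths.
    initial_scores_ : (n, K) exam-1 GoM scores per subject.
    subjects_ : subject ids aligned with ``initial_scores_`` rows.
    log_likelihood_ : final weighted log-likelihood.
    unweighted_log_likelihood_ : same parameters, w1 = 1.
    iteration_trace_ : weighted log-likelihood after each accepted iteration.
    n_iter_, converged_ : refinement iteration count and convergence flag.
    model_ : the fitted parameters bundled as a SubtypeModel.
    """

    def __init__(
        self,
        n_subtypes: int = 4,
        exam1_weight: float = 1.0,
        max_iter: int = 200,
        tol: float = 1e-5,
        n_restarts: int = 5,
        n_short_iter: int = 15,
        prob_floor: float = 1e-8,
        score_floor: float = 1e-8,
        zero_mortality_subtypes: tuple = (),
        trajectory_maxiter: int = 10,
        random_state: int | None = None,
    ):
        self.n_subtypes = n_subtypes
        self.exam1_weight = exam1_weight
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.n_short_iter = n_short_iter
        self.prob_floor = prob_floor
        self.score_floor = score_floor
        self.zero_mortality_subtypes = zero_mortality_subtypes
        self.trajectory_maxiter = trajectory_maxiter
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------
    def fit(self, X: Cohort, y=None) -> "LongitudinalGoM":
        if not isinstance(X, Cohort):
            raise TypeError("X must be a gomlife Cohort")
        if X.n_subjects == 0:
            raise ValueError("cannot fit an empty cohort")
        K = int(self.n_subtypes)
        if K < 2:
            raise ValueError("n_subtypes must be >= 2")
        if self.exam1_weight < 1.0:
            raise ValueError("exam1_weight must be >= 1")
        data = _em.FitData.from_cohort(X, K, self.exam1_weight)
        seed = 0 if self.random_state is None else int(self.random_state)
        clamp = tuple(k - 1 for k in self.zero_mortality_subtypes)

        best = None
        for r in range(max(1, int(self.n_restarts))):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
            params = self._init_params(data, rng)
            params, trace, _ = self._run(data, params, self.n_short_iter, clamp)
            if best is None or trace[-1] > best[1][-1] + 1e-9:
                best = (params, trace)
        params, trace0 = best
        params, trace, converged = self._run(data, params, self.max_iter, clamp)
        full_trace = np.concatenate([trace0, trace])

        g1, LAM, lamD, z = params
        self.lambdas_ = data.unstack_lambdas(LAM)
        self.mortality_lambdas_ = lamD
        self.pure_trajectories_ = PureTrajectorySet.from_logits(z, K)
        self.initial_scores_ = g1
        self.subjects_ = list(X.subjects)
        U = self.pure_trajectories_.cumulative()
        parts = _em.loglik_parts(data, g1, U, LAM, lamD, self.prob_floor)
        self.log_likelihood_ = _em.weighted_total(parts, self.exam1_weight)
        self.unweighted_log_likelihood_ = _em.weighted_total(parts, 1.0)
        self.iteration_trace_ = full_trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        if not converged:
            warnings.warn(
                "fit did not converge within max_iter; result flagged, not fatal",
                RuntimeWarning,
            )
        self.model_ = SubtypeModel(
            K=K,
            catalog=X.catalog,
            lambdas=self.lambdas_,
            mortality_lambdas=lamD,
            pure_trajectories=self.pure_trajectories_.u,
            exam1_weight=self.exam1_weight,
            n_exams=X.n_exams,
            meta=dict(
                weighted_log_likelihood=self.log_likelihood_,
                unweighted_log_likelihood=self.unweighted_log_likelihood_,
                n_iterations=self.n_iter_,
                converged=bool(converged),
            ),
        )
        return self

    def _init_params(self, data: _em.FitData, rng: np.random.Generator):
        n, K, J, Lmax = data.n, data.K, len(data.var_names), data.Lmax
        g1 = rng.dirichlet(np.ones(K), size=n)
        # pooled level frequencies, jittered per subtype
        counts = np.zeros((J, Lmax))
        np.add.at(counts, (data.rj, data.rl), 1.0)
        counts += 0.5 * data.level_mask
        freq = counts / counts.sum(axis=1, keepdims=True)
        LAM = freq[:, None, :] * np.exp(
            0.6 * rng.standard_normal((J, K, Lmax)) * data.level_mask[:, None, :]
        )
        LAM *= data.level_mask[:, None, :]
        LAM /= LAM.sum(axis=2, keepdims=True)
        lamD = rng.uniform(0.01, 0.10, size=K)
        z = rng.normal(-2.5, 0.25, size=(data.T - 1, n_transfer_params(K)))
        return g1, LAM, lamD, z

    def _run(self, data: _em.FitData, params, n_iter: int, clamp):
        g1, LAM, lamD, z = params
        floor, sfloor = self.prob_floor, self.score_floor
        trace = []
        prev = -np.inf
        converged = False
        for it in range(n_iter):
            P = transfers_from_logits(z, data.K)
            U = cumulative_transfers(P)
            G = _em.scores_at_exams(g1, U)
            for _ in range(2):
                LAM = _em.em_lambda_step(data, G, LAM, floor)
            for _ in range(2):
                lamD = _em.em_mortality_step(data, G, lamD, floor, clamp)
            for _ in range(2):
                g1 = _em.em_score_step(data, g1, U, LAM, lamD, floor, sfloor)
            # trajectory block: accept only improvements
            obj0, _ = _em.trajectory_negloglik_and_grad(
                z.ravel(), data, g1, LAM, lamD, floor
            )
            res = minimize(
                _em.trajectory_negloglik_and_grad,
                z.ravel(),
                args=(data, g1, LAM, lamD, floor),
                jac=True,
                method="L-BFGS-B",
                options=dict(maxiter=self.trajectory_maxiter),
            )
            if res.fun < obj0:
                z = res.x.reshape(z.shape)
            U = cumulative_transfers(transfers_from_logits(z, data.K))
            parts = _em.loglik_parts(data, g1, U, LAM, lamD, floor)
            ll = _em.weighted_total(parts, self.exam1_weight)
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) < self.tol * (abs(ll) + 1.0):
                converged = True
                prev = ll
                break
            prev = ll
        return (g1, LAM, lamD, z), np.asarray(trace), converged

    # -- prediction ---------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Exam-1 GoM scores for new patients from single-examination data.

        ``X`` is a list of response mappings (variable name -> level) or a
        DataFrame with columns subject_id, variable, level; returns an
        (n, K) array of simplex scores.
        """
        self._check_fitted()
        records = _as_records(X)
        return np.vstack(
            [estimate_scores_single_exam(rec, self.model_) for rec in records]
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")


def _as_records(X) -> list:
    if hasattr(X, "columns"):  # DataFrame
        return [
            dict(zip(sub["variable"], sub["level"]))
            for _, sub in X.groupby("subject_id", sort=False)
        ]
    if isinstance(X, dict):
        return [X]
    return list(X)


# ---------------------------------------------------------------------------
# public operations (thin wrappers / model-level functions)
# ---------------------------------------------------------------------------

def response_distribution(g: np.ndarray, lambda_j: np.ndarray) -> np.ndarray:
    """Mixture outcome distribution ``P(level l) = sum_k g_k lambda_kjl``."""
    g = np.asarray(g, dtype=float)
    lambda_j = np.asarray(lambda_j, dtype=float)
    if g.ndim != 1 or lambda_j.ndim != 2 or lambda_j.shape[0] != g.shape[0]:
        raise ValueError(
            f"dimension mismatch: scores {g.shape} vs lambda {lambda_j.shape}"
        )
    return g @ lambda_j


def weighted_loglik(
    cohort: Cohort,
    model: SubtypeModel,
    scores: np.ndarray,
    w1: float | None = None,
    prob_floor: float = _em.PROB_FLOOR,
) -> float:
    """Weighted log-likelihood of a cohort under fixed model parameters.

    Exam-1 item terms carry weight w1 (default: the model's); item terms for
    later exams and the per-interval survival/death terms carry weight 1.
    Zero-probability observations are floored at ``prob_floor`` with a warning.
    """
    if w1 is None:
        w1 = model.exam1_weight
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (cohort.n_subjects, model.K):
        raise ValueError("scores must have shape (n_subjects, K)")
    if np.any(scores < -1e-6) or np.any(np.abs(scores.sum(axis=1) - 1) > 1e-6):
        raise ValueError("scores must lie on the simplex")
    data = _em.FitData.from_cohort(
        cohort, model.K, w1, var_names=list(model.lambdas)
    )
    U = np.transpose(model.full_pure_trajectories(), (1, 0, 2))
    LAM = data.stack_lambdas(model.lambdas)
    parts = _em.loglik_parts(
        data, scores, U, LAM, model.mortality_lambdas, prob_floor
    )
    if parts["n_floored"]:
        warnings.warn(
            f"{parts['n_floored']} observed outcomes had probability below the "
            f"{prob_floor} floor",
            RuntimeWarning,
        )
    return _em.weighted_total(parts, w1)


def fit_model(cohort: Cohort, K: int, config: EstimationConfig) -> FitResult:
    """Fit the model by weighted maximum likelihood (see LongitudinalGoM)."""
    w1 = config.exam1_weight_grid[0] if len(config.exam1_weight_grid) == 1 else 1.0
    est = LongitudinalGoM(
        n_subtypes=K,
        exam1_weight=w1,
        max_iter=config.max_iterations,
        tol=config.tol,
        n_restarts=config.n_restarts,
        n_short_iter=config.n_short_iterations,
        prob_floor=config.prob_floor,
        score_floor=config.score_floor,
        zero_mortality_subtypes=config.zero_mortality_subtypes,
        trajectory_maxiter=config.trajectory_maxiter,
        random_state=config.seed,
    ).fit(cohort)
    return FitResult(
        model=est.model_,
        initial_scores=est.initial_scores_,
        subjects=est.subjects_,
        weighted_log_likelihood=est.log_likelihood_,
        unweighted_log_likelihood=est.unweighted_log_likelihood_,
        exam1_weight=w1,
        iteration_trace=est.iteration_trace_,
        converged=est.converged_,
    )


def select_exam1_weight(cohort: Cohort, K: int, config: EstimationConfig):
    """Choose the exam-1 weight w1 from a grid by an AIC-style budget.

    For each candidate the model is refit and the *unweighted* log-likelihood
    of everything except the exam-1 item block (items at exams 2..T plus the
    survival terms) is evaluated.  The chosen w1 is the largest candidate whose
    deterioration, on the AIC scale (2 log-likelihood units), relative to
    w1 = 1 stays within ``aic_budget_per_weight_unit * (w1 - 1)``.

    Returns ``(w1, details)`` where details maps each candidate to its
    post-exam-1 log-likelihood and deterioration.
    """
    grid = sorted(set(float(w) for w in config.exam1_weight_grid))
    if not grid:
        raise ValueError("candidate grid must be nonempty")
    if grid == [1.0]:
        return 1.0, {1.0: dict(loglik_post_exam1=None, deterioration=0.0)}
    if 1.0 not in grid:
        grid = [1.0] + grid
    details = {}
    for w1 in grid:
        est = LongitudinalGoM(
            n_subtypes=K,
            exam1_weight=w1,
            max_iter=config.max_iterations,
            tol=config.tol,
            n_restarts=config.n_restarts,
            n_short_iter=config.n_short_iterations,
            zero_mortality_subtypes=config.zero_mortality_subtypes,
            trajectory_maxiter=config.trajectory_maxiter,
            random_state=config.seed,
        ).fit(cohort)
        data = _em.FitData.from_cohort(cohort, K, w1)
        U = est.pure_trajectories_.cumulative()
        parts = _em.loglik_parts(
            data,
            est.initial_scores_,
            U,
            data.stack_lambdas(est.lambdas_),
            est.mortality_lambdas_,
        )
        details[w1] = dict(
            loglik_post_exam1=parts["items_rest"] + parts["mortality"]
        )
    ref = details[1.0]["loglik_post_exam1"]
    chosen = 1.0
    for w1 in grid:
        det = 2.0 * (ref - details[w1]["loglik_post_exam1"])
        details[w1]["deterioration"] = det
        if det <= config.aic_budget_per_weight_unit * (w1 - 1.0):
            chosen = max(chosen, w1)
    return chosen, details


def estimate_scores_single_exam(
    responses: dict, model: SubtypeModel, tol: float = 1e-12, max_iter: int = 2000
) -> np.ndarray:
    """Maximum-likelihood GoM scores from one examination's responses.

    Maximizes the exam-1 item likelihood over the simplex with the model
    parameters held fixed (EM multiplicative updates).  With subtype-identical
    lambdas the likelihood is flat; the simplex barycenter is returned with a
    warning.
    """
    rows = [
        model.lambdas[v][:, int(l)]
        for v, l in responses.items()
        if v in model.lambdas and l is not None
    ]
    if not rows:
        raise ValueError("no non-missing responses: scores are unidentified")
    C = np.vstack(rows)  # (n_items, K)
    K = model.K
    if np.ptp(C, axis=1).max() < 1e-12:
        warnings.warn(
            "likelihood is flat in the scores (subtype-identical lambdas); "
            "returning the simplex barycenter",
            RuntimeWarning,
        )
        return np.full(K, 1.0 / K)
    g = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        p = np.maximum(C @ g, 1e-300)
        new = g * (C / p[:, None]).mean(axis=0)
        new = np.maximum(new, 0.0)
        new /= new.sum()
        if np.abs(new - g).max() < tol:
            g = new
            break
        g = new
    return g


def fit_conditional_lambdas(
    cohort: Cohort,
    model: SubtypeModel,
    scores: np.ndarray,
    extra_variables: list,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> dict:
    """Lambda tables for variables held out of the main fit.

    The GoM scores and trajectories stay fixed, so the extra variables'
    lambdas maximize their own likelihood independently (weighted response
    frequencies at the EM fixed point); the main model is untouched.
    """
    overlap = [v for v in extra_variables if v in model.lambdas]
    if overlap:
        raise ValueError(f"variables already in the fitted model: {overlap}")
    missing = [v for v in extra_variables if v not in cohort.catalog]
    if missing:
        raise ValueError(f"variables not declared in the cohort catalog: {missing}")
    data = _em.FitData.from_cohort(
        cohort, model.K, model.exam1_weight, var_names=list(extra_variables)
    )
    empty = [
        name
        for j, name in enumerate(data.var_names)
        if not np.any(data.rj == j)
    ]
    if empty:
        raise ValueError(f"no observations for variables: {empty}")
    U = np.transpose(model.full_pure_trajectories(), (1, 0, 2))
    G = _em.scores_at_exams(np.asarray(scores, float), U)
    counts = np.zeros((len(data.var_names), data.Lmax))
    np.add.at(counts, (data.rj, data.rl), 1.0)
    counts += 0.5 * data.level_mask
    LAM = np.repeat(
        (counts / counts.sum(axis=1, keepdims=True))[:, None, :], model.K, axis=1
    )
    for _ in range(max_iter):
        new = _em.em_lambda_step(data, G, LAM)
        if np.abs(new - LAM).max() < tol:
            LAM = new
            break
        LAM = new
    return data.unstack_lambdas(LAM)
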