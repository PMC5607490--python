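"""Subgroup construction, covariate salience, and observed-vs-estimated fit.

Salience of a covariate for a subtype is measured by the Kullback-Leibler
information of the subtype's pure response distribution against the pooled
marginal (all completed examinations weighted equally); pairs with KL > 0.50
*and* a positive BIC statistic for subtype-varying lambdas receive a low /
medium / high (L/M/H) severity code from the direction of the distribution
shift.  Goodness of fit compares model-estimated average survival and
full-time-care rates to Kaplan-Meier / binomial observed values with
pointwise (Greenwood, Wilson) and simultaneous (equal-precision) 95% bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm
from statsmodels.stats.proportion import proportion_confint

from . import _em
from .data_model import Cohort, SubtypeModel

KL_THRESHOLD = 0.50


def assign_subgroups(scores: np.ndarray) -> np.ndarray:
    """Rational subgroup labels: k if g_k > 0.5 (strict), else the residual 0.

    On the simplex at most one score can exceed 1/2, so the rule is
    well defined; labels are 1-based subtype indices with 0 the residual.
    """
    scores = np.asarray(scores, dtype=float)
    top = scores.argmax(axis=1)
    return np.where(scores[np.arange(len(scores)), top] > 0.5, top + 1, 0)


def kl_information(lambda_kj: np.ndarray, marginal_j: np.ndarray) -> float:
    """KL(lambda || marginal) in nats, with 0 log 0 = 0.

    A zero marginal level with positive lambda mass makes the statistic
    infinite; +inf is returned as a sentinel with a warning.
    """
    lam = np.asarray(lambda_kj, dtype=float)
    m = np.asarray(marginal_j, dtype=float)
    if lam.shape != m.shape or lam.ndim != 1:
        raise ValueError("distributions must be 1-d and the same length")
    for d, name in ((lam, "lambda"), (m, "marginal")):
        if np.any(d < -1e-12) or abs(d.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability distribution")
    pos = lam > 0
    if np.any(pos & (m <= 0)):
        warnings.warn(
            "marginal has zero mass where lambda is positive; KL is infinite",
            RuntimeWarning,
        )
        return float("inf")
    return float(np.sum(lam[pos] * np.log(lam[pos] / m[pos])))


def marginal_distribution(cohort: Cohort, variable: str) -> np.ndarray:
    """Pooled level frequencies over all completed examinations."""
    v = cohort.catalog[variable]
    obs = cohort.responses.loc[
        cohort.responses["variable"] == variable, "level"
    ].to_numpy()
    if obs.size == 0:
        raise ValueError(f"no observations for variable {variable!r}")
    return np.bincount(obs, minlength=v.n_levels) / obs.size


def _variable_loglik_pair(
    cohort: Cohort, model: SubtypeModel, scores: np.ndarray, variable: str
):
    """(loglik with subtype-specific lambdas, with shared marginal, df, n_obs).

    The subtype-specific lambdas are the conditional MLE given the fixed
    scores/trajectories; the shared-model MLE is the pooled marginal.
    """
    if variable not in cohort.catalog:
        raise ValueError(f"unknown variable {variable!r}")
    data = _em.FitData.from_cohort(cohort, model.K, 1.0, var_names=[variable])
    n_obs = data.ri.size
    if n_obs == 0:
        raise ValueError(f"no observations for variable {variable!r}")
    U = np.transpose(model.full_pure_trajectories(), (1, 0, 2))
    G = _em.scores_at_exams(np.asarray(scores, float), U)
    # conditional MLE of the subtype-specific lambdas (EM to convergence)
    marg = marginal_distribution(cohort, variable)
    LAM = np.repeat(marg[None, None, :], model.K, axis=1)
    LAM = LAM + 1e-3 * data.level_mask[:, None, :]
    LAM /= LAM.sum(axis=2, keepdims=True)
    if variable in model.lambdas:  # warm start from the fitted table
        LAM = 0.5 * LAM + 0.5 * model.lambdas[variable][None]
    for _ in range(500):
        new = _em.em_lambda_step(data, G, LAM)
        if np.abs(new - LAM).max() < 1e-10:
            LAM = new
            break
        LAM = new
    Gm = G[data.ri, data.rt]
    p1 = np.einsum("rk,rk->r", Gm, LAM[data.rj, :, data.rl])
    l1 = float(np.log(np.maximum(p1, 1e-300)).sum())
    l0 = float(np.log(np.maximum(marg[data.rl], 1e-300)).sum())
    Lj = cohort.catalog[variable].n_levels
    df = (model.K - 1) * (Lj - 1)
    return l1, l0, df, n_obs


def bic_statistic(
    cohort: Cohort, model: SubtypeModel, scores: np.ndarray, variable: str
) -> float:
    """BIC evidence for subtype-varying lambdas over a shared marginal.

    ``2*loglik(subtype-specific) - 2*loglik(shared) - df*log(n_obs)`` with
    df = (K-1)(L_j-1); positive values justify subtype-specific lambdas.
    """
    l1, l0, df, n_obs = _variable_loglik_pair(cohort, model, scores, variable)
    return 2.0 * (l1 - l0) - df * np.log(n_obs)


def wilks_screen(
    cohort: Cohort, model: SubtypeModel, scores: np.ndarray, variable: str
) -> float:
    """Wilks chi-square p-value for the same nested pair as the BIC screen."""
    l1, l0, df, _ = _variable_loglik_pair(cohort, model, scores, variable)
    lr = max(0.0, 2.0 * (l1 - l0))
    return float(chi2.sf(lr, df))


def lmh_code(
    lambda_kj: np.ndarray,
    marginal_j: np.ndarray,
    kl_value: float,
    bic_value: float,
    ordered: bool = True,
) -> str:
    """Severity code for one (subtype, covariate) pair.

    Unclassified unless BIC > 0 and KL > 0.50.  With an ordered level set:
    'H' when the subtype distribution stochastically dominates the marginal
    (CDF everywhere <=), 'L' when dominated, 'M' when neither dominates and
    the variable has >= 3 levels (the shift concentrates on intermediate
    severity levels).  Directionality is undefined for unordered variables.
    """
    if not (bic_value > 0 and kl_value > KL_THRESHOLD):
        return "unclassified"
    if not ordered:
        warnings.warn(
            "salient but unordered variable: severity direction undefined",
            RuntimeWarning,
        )
        return "unclassified"
    lam = np.asarray(lambda_kj, dtype=float)
    m = np.asarray(marginal_j, dtype=float)
    cl, cm = np.cumsum(lam), np.cumsum(m)
    tol = 1e-9
    high = np.all(cl[:-1] <= cm[:-1] + tol)
    low = np.all(cl[:-1] >= cm[:-1] - tol)
    if high and not low:
        return "H"
    if low and not high:
        return "L"
    if len(lam) >= 3 and not high and not low:
        return "M"
    return "unclassified"


def salience_report(
    cohort: Cohort,
    model: SubtypeModel,
    scores: np.ndarray,
    variables: list | None = None,
) -> pd.DataFrame:
    """Per (variable, subtype) KL/BIC statistics, severity codes and ranks.

    Variables are ranked by ascending Wilks p-value, ties broken by the
    largest per-subtype KL, descending.
    """
    if variables is None:
        variables = list(model.lambdas)
    rows = []
    for name in variables:
        v = cohort.catalog[name]
        marg = marginal_distribution(cohort, name)
        bic = bic_statistic(cohort, model, scores, name)
        pval = wilks_screen(cohort, model, scores, name)
        lam_table = model.lambdas.get(name)
        if lam_table is None:
            raise ValueError(f"no lambda table for variable {name!r}")
        for k in range(model.K):
            kl = kl_information(lam_table[k], marg)
            rows.append(
                dict(
                    variable=name,
                    domain=v.domain,
                    subtype=k + 1,
                    kl=kl,
                    bic=bic,
                    wilks_p=pval,
                    code=lmh_code(lam_table[k], marg, kl, bic, v.ordered),
                )
            )
    df = pd.DataFrame(rows)
    order = (
        df.groupby("variable")
        .agg(p=("wilks_p", "first"), klmax=("kl", "max"))
        .sort_values(["p", "klmax"], ascending=[True, False])
    )
    rank = {name: i + 1 for i, name in enumerate(order.index)}
    df["rank"] = df["variable"].map(rank)
    return df.sort_values(["rank", "subtype"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# observed curves: Kaplan-Meier, bands, FTC rates
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival on the exam grid with Greenwood 95% bands."""

    S: np.ndarray  # t = 0..T-1, S[0] = 1
    var: np.ndarray  # Greenwood variance of S
    lower: np.ndarray  # pointwise band, normal scale, clipped to [0, 1]
    upper: np.ndarray
    n_risk: np.ndarray  # at-risk count entering each interval (index t-1)
    n_events: np.ndarray


def km_curve(vital: pd.DataFrame, n_exams: int, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimate from per-subject death/censor intervals.

    Deaths in interval t drop the curve at exam t; censoring at interval c
    keeps the subject at risk through interval c.
    """
    if len(vital) == 0:
        raise ValueError("empty group")
    iv = vital["interval"].to_numpy()
    death = (vital["event"] == "death").to_numpy()
    T = n_exams
    S = np.ones(T)
    var_factor = np.zeros(T)
    n_risk = np.zeros(T - 1, dtype=int)
    n_events = np.zeros(T - 1, dtype=int)
    for t in range(1, T):
        at_risk = int((iv >= t).sum())
        d = int((death & (iv == t)).sum())
        n_risk[t - 1] = at_risk
        n_events[t - 1] = d
        frac = d / at_risk if at_risk else 0.0
        S[t] = S[t - 1] * (1.0 - frac)
        var_factor[t] = var_factor[t - 1] + (
            d / (at_risk * (at_risk - d)) if at_risk and at_risk > d else 0.0
        )
    var = S**2 * var_factor
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return KMCurve(
        S=S,
        var=var,
        lower=np.clip(S - half, 0.0, 1.0),
        upper=np.clip(S + half, 0.0, 1.0),
        n_risk=n_risk,
        n_events=n_events,
    )


def _equal_precision_critical(a1: float, a2: float, alpha: float) -> float:
    """Critical value of the equal-precision band (Miller-Siegmund tail bound)."""
    span = np.log(a2 * (1 - a1) / (a1 * (1 - a2)))

    def tail(e):
        return 4 * norm.pdf(e) / e + norm.pdf(e) * (e - 1 / e) * span - alpha

    return brentq(tail, 1.0, 10.0)


def simultaneous_band(km: KMCurve, confidence: float = 0.95):
    """Equal-precision simultaneous band over the observed exam range.

    The band inflates the pointwise standard error by a common critical value
    exceeding the normal quantile, so it contains the pointwise band wherever
    it is defined.  It is undefined (NaN) outside the event-supported range —
    before the first event the variance is degenerate and the equal-precision
    weight a(t) = n sigma^2/(1 + n sigma^2) vanishes.  With degenerate
    variance everywhere (no events) the pointwise band is returned with a
    warning.
    """
    alpha = 1.0 - confidence
    n = int(km.n_risk[0]) if km.n_risk.size else 0
    sigma2 = np.where(km.S > 0, km.var / np.maximum(km.S, 1e-300) ** 2, np.inf)
    valid = (km.var > 0) & (km.S > 0) & np.isfinite(sigma2)
    if not valid.any():
        warnings.warn(
            "degenerate variance everywhere; returning the pointwise band",
            RuntimeWarning,
        )
        return km.lower.copy(), km.upper.copy()
    a = n * sigma2[valid] / (1.0 + n * sigma2[valid])
    a1, a2 = float(a.min()), float(a.max())
    a1 = min(max(a1, 1e-6), 1 - 1e-6)
    a2 = min(max(a2, a1 + 1e-9), 1 - 1e-6)
    e = _equal_precision_critical(a1, a2, alpha)
    half = e * np.sqrt(km.var)
    lower = np.clip(km.S - half, 0.0, 1.0)
    upper = np.clip(km.S + half, 0.0, 1.0)
    lower[~valid] = np.nan
    upper[~valid] = np.nan
    return lower, upper


def observed_ftc_rates(
    cohort: Cohort, subjects: list | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Observed full-time-care proportion among survivors at each examination.

    Numerator: survivors coded at the FTC level; denominator: survivors with a
    non-missing FTC coding at the exam (the dead cannot attend, so they are
    excluded by construction).  Exams with an empty denominator get NaN (a
    gap), not zero.  Wilson 95% pointwise intervals.
    """
    v = cohort.catalog.disability_variable
    if v is None:
        raise ValueError("cohort catalog declares no disability variable")
    ftc_level = cohort.catalog.ftc_level
    r = cohort.responses
    r = r[r["variable"] == v.name]
    if subjects is not None:
        r = r[r["subject_id"].isin(set(subjects))]
    rows = []
    for t in range(1, cohort.n_exams + 1):
        sub = r[r["exam"] == t]
        denom = len(sub)
        num = int((sub["level"] == ftc_level).sum())
        if denom == 0:
            rows.append(dict(exam=t, n=0, rate=np.nan, lower=np.nan, upper=np.nan))
            continue
        lo, hi = proportion_confint(num, denom, alpha=alpha, method="wilson")
        rows.append(dict(exam=t, n=denom, rate=num / denom, lower=lo, upper=hi))
    return pd.DataFrame(rows)


def gof_compare(
    estimated: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> pd.DataFrame:
    """Flag, per grid point, whether the model curve lies inside the band.

    NaN band values (no observation at that exam) are skipped.  The returned
    frame carries one row per comparable point and an ``inside`` flag; overall
    coverage is ``inside.mean()``.
    """
    est = np.asarray(estimated, dtype=float)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if est.shape != lo.shape or est.shape != hi.shape:
        raise ValueError("curves and band must share the grid")
    ok = ~(np.isnan(lo) | np.isnan(hi) | np.isnan(est))
    idx = np.nonzero(ok)[0]
    inside = (est[idx] >= lo[idx] - 1e-12) & (est[idx] <= hi[idx] + 1e-12)
    return pd.DataFrame(
        {"grid_index": idx, "estimated": est[idx], "lower": lo[idx],
         "upper": hi[idx], "inside": inside}
    )
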