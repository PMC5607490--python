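"""Sullivan life-table decomposition of 10-year life expectancy.

For each subject the model yields a survival curve as the product of 6-month
conditional survival probabilities, ``S(t) = prod_{s<=t} (1 - q(s))`` with
``q(s) = sum_k g_k(s) lambda_k,death``, and a disability (full-time-care)
prevalence curve ``pi(t) = sum_k g_k(t) lambda_k,FTC``.  Sullivan's method
applies the prevalence to the survival function at each examination and sums
person-years (trapezoidal rule) over the 10-year horizon:

    TLE  = 0.5 * sum_t (S(t-1) + S(t)) / 2
    DFLE = 0.5 * sum_t (F(t-1) + F(t)) / 2,   F(t) = S(t) (1 - pi(t))
    DLE  = TLE - DFLE   (exactly, by construction)

Survival beyond 10 years (examination 21) is censored: the grid is truncated,
no extrapolated tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GoMTrajectory, INTERVAL_YEARS


@dataclass
class SurvivalCurve:
    """S(t) for t = 0..T-1 on the examination grid; S(0) = 1."""

    S: np.ndarray
    delta: float = INTERVAL_YEARS

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 1 or self.S[0] != 1.0:
            raise ValueError("survival curve must be 1-d with S(0) = 1")
        if np.any((self.S < -1e-12) | (self.S > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def __len__(self) -> int:
        return len(self.S)


@dataclass
class LifeExpectancy:
    """10-year total, disability-free and disabled life expectancy, in years."""

    tle: float
    dfle: float
    dle: float
    horizon: float = 10.0

    def __post_init__(self) -> None:
        if not np.isclose(self.tle, self.dfle + self.dle, atol=1e-9):
            raise ValueError("TLE must equal DFLE + DLE")
        if self.dfle < -1e-12 or self.dle < -1e-12:
            raise ValueError("life expectancy components must be nonnegative")
        if self.tle > self.horizon + 1e-12:
            raise ValueError("TLE cannot exceed the horizon")


def survival_curve(
    traj: GoMTrajectory, mortality_lambdas: np.ndarray
) -> SurvivalCurve:
    """Per-subject survival as the product of 6-month conditional survivals.

    The interval death probability uses the scores at the interval's starting
    examination: ``q(t) = g(t) . lambda_death`` for t = 1..T-1.
    """
    lamD = np.asarray(mortality_lambdas, dtype=float)
    q = traj.scores[:-1] @ lamD  # intervals 1..T-1 start at exams 1..T-1
    if np.any((q < 0) | (q > 1)):
        raise ValueError("interval death probabilities must lie in [0, 1]")
    S = np.empty(traj.n_exams)
    S[0] = 1.0
    S[1:] = np.cumprod(1.0 - q)
    return SurvivalCurve(S)


def disability_curve(
    traj: GoMTrajectory, disability_lambdas: np.ndarray
) -> np.ndarray:
    """Per-exam full-time-care prevalence ``pi(t) = g(t) . lambda_FTC``."""
    lam = np.asarray(disability_lambdas, dtype=float)
    pi = traj.scores @ lam
    return np.clip(pi, 0.0, 1.0)


def sullivan_decompose(S: SurvivalCurve, pi: np.ndarray) -> LifeExpectancy:
    """Decompose person-years under S into disability-free and disabled parts.

    Trapezoidal person-years between adjacent examinations; the prevalence at
    intake (exam 1, t = 0) enters the first trapezoid.  DLE is defined by
    subtraction so TLE = DFLE + DLE holds exactly.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != S.S.shape:
        raise ValueError(
            f"grid mismatch: survival has {len(S)} points, prevalence {len(pi)}"
        )
    F = S.S * (1.0 - pi)
    tle = S.delta * float((S.S[:-1] + S.S[1:]).sum()) / 2.0
    dfle = S.delta * float((F[:-1] + F[1:]).sum()) / 2.0
    return LifeExpectancy(tle=tle, dfle=dfle, dle=tle - dfle)


def aggregate_life_expectancies(
    les: list, labels: list
) -> pd.DataFrame:
    """Group means with between-individual 95% CIs plus max/min/ratio rows.

    One row per group label (sorted), then ``Total`` over everyone, then
    ``Maximum``/``Minimum`` over the group rows and their ``Ratio``.  CI limits
    are mean +/- 1.96 SD/sqrt(n); the ratio CI endpoints are formed from the
    component CIs (low = max-low / min-high, high = max-high / min-low).
    """
    if len(les) == 0:
        raise ValueError("no subjects to aggregate")
    if len(les) != len(labels):
        raise ValueError("labels must align with the life-expectancy list")
    df = pd.DataFrame(
        {
            "group": labels,
            "tle": [le.tle for le in les],
            "dfle": [le.dfle for le in les],
            "dle": [le.dle for le in les],
        }
    )
    rows = []

    def _summary(name: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        if n < 2:
            warnings.warn(
                f"group {name!r} has fewer than 2 subjects; CI is degenerate",
                RuntimeWarning,
            )
        rec = {"group": name, "n": n}
        for comp in ("tle", "dfle", "dle"):
            x = sub[comp].to_numpy()
            m = float(x.mean())
            half = 1.96 * float(x.std(ddof=1)) / np.sqrt(n) if n > 1 else 0.0
            rec[comp] = m
            rec[f"{comp}_lo"] = m - half
            rec[f"{comp}_hi"] = m + half
        return rec

    for name in sorted(df["group"].unique()):
        rows.append(_summary(name, df[df["group"] == name]))
    rows.append(_summary("Total", df))
    group_rows = pd.DataFrame(rows[:-1]).set_index("group")
    total_n = len(df)
    for tag, pick in (("Maximum", "idxmax"), ("Minimum", "idxmin")):
        rec = {"group": tag, "n": total_n}
        for comp in ("tle", "dfle", "dle"):
            which = getattr(group_rows[comp], pick)()
            for suff in ("", "_lo", "_hi"):
                rec[comp + suff] = group_rows.loc[which, comp + suff]
        rows.append(rec)
    mx, mn = rows[-2], rows[-1]
    ratio = {"group": "Ratio", "n": total_n}
    for comp in ("tle", "dfle", "dle"):
        ratio[comp] = mx[comp] / mn[comp]
        ratio[f"{comp}_lo"] = mx[f"{comp}_lo"] / mn[f"{comp}_hi"]
        ratio[f"{comp}_hi"] = mx[f"{comp}_hi"] / mn[f"{comp}_lo"]
    rows.append(ratio)
    return pd.DataFrame(rows).set_index("group")


def average_model_curves(
    survival_curves: list,
    prevalence_curves: list,
    labels: list,
) -> dict:
    """Group-mean survival and survivor-weighted FTC-rate curves.

    The estimated survival curve of a group is the plain mean of the member
    curves; the estimated FTC rate at an exam conditions on survival:
    ``sum_i S_i(t) pi_i(t) / sum_i S_i(t)``.
    Returns {label: {"survival": array, "ftc_rate": array, "n": int}}.
    """
    if len(survival_curves) == 0:
        raise ValueError("no curves to average")
    S = np.vstack([sc.S for sc in survival_curves])
    PI = np.vstack([np.asarray(p, float) for p in prevalence_curves])
    if S.shape != PI.shape:
        raise ValueError("survival and prevalence grids do not match")
    labels = np.asarray(labels)
    out = {}
    for name in np.unique(labels):
        sel = labels == name
        Ssub, Psub = S[sel], PI[sel]
        denom = Ssub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ftc = np.where(denom > 0, (Ssub * Psub).sum(axis=0) / denom, np.nan)
        out[name] = dict(
            survival=Ssub.mean(axis=0), ftc_rate=ftc, n=int(sel.sum())
        )
    return out
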