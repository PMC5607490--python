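"""Vectorized likelihood kernels for the longitudinal GoM model.

The weighted log-likelihood has three parts per subject i:

* w1 * sum of exam-1 item log-probabilities,
* sum of item log-probabilities for exams t >= 2,
* per 6-month interval, log survival (1 - q) or log death (q),

where the item probability of level l of variable j at exam t is the mixture
``sum_k g_ik(t) lambda_kjl`` and the interval death probability is
``q_i(t) = sum_k g_ik(t) lambda_k,death``.  Because the time-t scores are a
linear map of the initial scores, ``g_i(t) = g_i(1) U(t)``, every likelihood
term is *linear* in g_i(1); the subject block is therefore a plain mixture
likelihood and admits monotone EM multiplicative updates.  The same holds for
the lambda block given the scores (standard GoM EM).  Transfer-matrix logits
are updated by L-BFGS with an analytic adjoint gradient through the cumulative
products U(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Cohort
from .trajectories import (
    cumulative_transfers,
    n_transfer_params,
    transfers_from_logits,
)

PROB_FLOOR = 1e-8


@dataclass
class FitData:
    """Index arrays extracted once from a cohort for fast likelihood work."""

    n: int
    T: int
    K: int
    var_names: list
    n_levels: np.ndarray  # (J,)
    Lmax: int
    # response rows
    ri: np.ndarray  # subject index
    rt: np.ndarray  # 0-based exam index
    rj: np.ndarray  # variable index
    rl: np.ndarray  # level
    rw: np.ndarray  # weight (w1 at exam 1, else 1)
    rows_by_exam: list  # index arrays per exam
    # mortality rows (one per observed at-risk interval)
    mi: np.ndarray
    mt: np.ndarray  # 0-based exam index at interval start
    md: np.ndarray  # 1 = death in this interval
    level_mask: np.ndarray  # (J, Lmax) valid-level mask

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, K: int, exam1_weight: float, var_names=None
    ) -> "FitData":
        catalog = cohort.catalog
        if var_names is None:
            var_names = [v.name for v in catalog.item_variables]
        vidx = {name: j for j, name in enumerate(var_names)}
        n_levels = np.array([catalog[name].n_levels for name in var_names])
        Lmax = int(n_levels.max()) if len(n_levels) else 2
        r = cohort.responses[cohort.responses["variable"].isin(vidx)]
        ri = r["subject_id"].map(cohort.subject_index).to_numpy(dtype=np.int64)
        rt = r["exam"].to_numpy(dtype=np.int64) - 1
        rj = r["variable"].map(vidx).to_numpy(dtype=np.int64)
        rl = r["level"].to_numpy(dtype=np.int64)
        rw = np.where(rt == 0, float(exam1_weight), 1.0)
        T = cohort.n_exams
        rows_by_exam = [np.nonzero(rt == t)[0] for t in range(T)]
        mi_list, mt_list, md_list = [], [], []
        for _, row in cohort.vital.iterrows():
            i = cohort.subject_index(row["subject_id"])
            interval = int(row["interval"])
            died = row["event"] == "death"
            n_surv = interval - 1 if died else interval
            for t in range(n_surv):
                mi_list.append(i)
                mt_list.append(t)
                md_list.append(0)
            if died:
                mi_list.append(i)
                mt_list.append(interval - 1)
                md_list.append(1)
        level_mask = np.arange(Lmax)[None, :] < n_levels[:, None]
        return cls(
            n=cohort.n_subjects,
            T=T,
            K=K,
            var_names=list(var_names),
            n_levels=n_levels,
            Lmax=Lmax,
            ri=ri,
            rt=rt,
            rj=rj,
            rl=rl,
            rw=rw,
            rows_by_exam=rows_by_exam,
            mi=np.asarray(mi_list, dtype=np.int64),
            mt=np.asarray(mt_list, dtype=np.int64),
            md=np.asarray(md_list, dtype=np.int64),
            level_mask=level_mask,
        )

    def stack_lambdas(self, lambdas: dict) -> np.ndarray:
        """(J, K, Lmax) padded lambda array in ``var_names`` order."""
        LAM = np.zeros((len(self.var_names), self.K, self.Lmax))
        for j, name in enumerate(self.var_names):
            lam = lambdas[name]
            LAM[j, :, : lam.shape[1]] = lam
        return LAM

    def unstack_lambdas(self, LAM: np.ndarray) -> dict:
        return {
            name: LAM[j, :, : self.n_levels[j]].copy()
            for j, name in enumerate(self.var_names)
        }


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def scores_at_exams(g1: np.ndarray, U: np.ndarray) -> np.ndarray:
    """All time-varying scores G[i, t] = g1[i] U(t), shape (n, T, K)."""
    return np.einsum("nk,tkm->ntm", g1, U)


def loglik_parts(
    data: FitData,
    g1: np.ndarray,
    U: np.ndarray,
    LAM: np.ndarray,
    lamD: np.ndarray,
    floor: float = PROB_FLOOR,
) -> dict:
    """Item (exam-1 / later) and mortality log-likelihood components.

    Returns unweighted parts; callers combine them with w1.  Probabilities are
    floored at ``floor`` inside the logarithms to guard -inf.
    """
    G = scores_at_exams(g1, U)
    a = LAM[data.rj, :, data.rl]
    p = np.einsum("rk,rk->r", G[data.ri, data.rt], a)
    logp = np.log(np.maximum(p, floor))
    exam1 = data.rt == 0
    ll_items_exam1 = float(logp[exam1].sum())
    ll_items_rest = float(logp[~exam1].sum())
    q = G[data.mi, data.mt] @ lamD
    p_obs = np.where(data.md == 1, q, 1.0 - q)
    ll_mort = float(np.log(np.maximum(p_obs, floor)).sum())
    return dict(
        items_exam1=ll_items_exam1,
        items_rest=ll_items_rest,
        mortality=ll_mort,
        n_floored=int((p < floor).sum() + (p_obs < floor).sum()),
    )


def weighted_total(parts: dict, w1: float) -> float:
    return w1 * parts["items_exam1"] + parts["items_rest"] + parts["mortality"]


# ---------------------------------------------------------------------------
# EM blocks (each monotone in the weighted log-likelihood)
# ---------------------------------------------------------------------------

def em_lambda_step(
    data: FitData,
    G: np.ndarray,
    LAM: np.ndarray,
    floor: float = PROB_FLOOR,
    only_vars: np.ndarray | None = None,
) -> np.ndarray:
    """One EM sweep over item lambdas with scores fixed."""
    J, K, Lmax = LAM.shape
    Gm = G[data.ri, data.rt]  # (R, K)
    a = LAM[data.rj, :, data.rl]
    num = Gm * a
    p = np.maximum(num.sum(axis=1), floor)
    resp = data.rw[:, None] * num / p[:, None]
    acc = np.zeros((J, K, Lmax))
    flat = data.rj * Lmax + data.rl
    for k in range(K):
        acc[:, k, :] = np.bincount(
            flat, weights=resp[:, k], minlength=J * Lmax
        ).reshape(J, Lmax)
    tot = acc.sum(axis=2, keepdims=True)
    new = np.divide(acc, tot, out=LAM.copy(), where=tot > 0)
    new *= data.level_mask[:, None, :]
    # renormalize over valid levels (no-op except where a row had zero mass)
    s = new.sum(axis=2, keepdims=True)
    np.divide(new, s, out=new, where=s > 0)
    if only_vars is not None:
        keep = np.ones(J, dtype=bool)
        keep[only_vars] = False
        new[keep] = LAM[keep]
    return new


def em_mortality_step(
    data: FitData,
    G: np.ndarray,
    lamD: np.ndarray,
    floor: float = PROB_FLOOR,
    clamp_zero: tuple = (),
) -> np.ndarray:
    """One EM sweep over the per-subtype 6-month death probabilities."""
    if data.mi.size == 0:
        return lamD.copy()
    Gm = G[data.mi, data.mt]
    q = np.clip(Gm @ lamD, floor, 1 - floor)
    death = data.md == 1
    resp_death = Gm[death] * lamD[None, :] / q[death, None]
    resp_surv = Gm[~death] * (1.0 - lamD)[None, :] / (1.0 - q[~death, None])
    num = resp_death.sum(axis=0)
    den = num + resp_surv.sum(axis=0)
    new = np.divide(num, den, out=np.zeros_like(lamD), where=den > 0)
    for k in clamp_zero:
        new[k] = 0.0
    return new


def em_score_step(
    data: FitData,
    g1: np.ndarray,
    U: np.ndarray,
    LAM: np.ndarray,
    lamD: np.ndarray,
    floor: float = PROB_FLOOR,
    score_floor: float = 1e-8,
) -> np.ndarray:
    """One EM multiplicative update of the initial scores, all else fixed."""
    n, K = g1.shape
    # coefficient of g1 in each item probability: M[t, j, l, :] = U(t) lambda_j[:, l]
    M = np.einsum("tkb,jbl->tjlk", U, LAM)
    C = M[data.rt, data.rj, data.rl]  # (R, K)
    p = np.maximum(np.einsum("rk,rk->r", g1[data.ri], C), floor)
    wC = data.rw[:, None] * C / p[:, None]
    num = np.zeros((n, K))
    for k in range(K):
        num[:, k] = np.bincount(data.ri, weights=wC[:, k], minlength=n)
    den = np.bincount(data.ri, weights=data.rw, minlength=n).astype(float)
    if data.mi.size:
        MD = U @ lamD  # (T, K)
        cD = MD[data.mt]
        cm = np.where(data.md[:, None] == 1, cD, 1.0 - cD)
        pm = np.clip(np.einsum("rk,rk->r", g1[data.mi], cm), floor, None)
        wM = cm / pm[:, None]
        for k in range(K):
            num[:, k] += np.bincount(data.mi, weights=wM[:, k], minlength=n)
        den += np.bincount(data.mi, minlength=n).astype(float)
    ok = den > 0
    new = g1.copy()
    new[ok] = g1[ok] * num[ok] / den[ok, None]
    new = np.maximum(new, score_floor)
    new /= new.sum(axis=1, keepdims=True)
    return new


# ---------------------------------------------------------------------------
# trajectory block: objective + analytic gradient in the transfer logits
# ---------------------------------------------------------------------------

def trajectory_negloglik_and_grad(
    z_flat: np.ndarray,
    data: FitData,
    g1: np.ndarray,
    LAM: np.ndarray,
    lamD: np.ndarray,
    floor: float = PROB_FLOOR,
):
    """Negative weighted log-likelihood and gradient w.r.t. transfer logits.

    The gradient is the adjoint of the cumulative products U(t) = U(t-1) P_t,
    followed by the softmax Jacobian of each matrix row.
    """
    T, K = data.T, data.K
    n_free = n_transfer_params(K)
    z = z_flat.reshape(T - 1, n_free)
    P = transfers_from_logits(z, K)
    U = cumulative_transfers(P)
    G = scores_at_exams(g1, U)

    a = LAM[data.rj, :, data.rl]
    p = np.einsum("rk,rk->r", G[data.ri, data.rt], a)
    pf = np.maximum(p, floor)
    rw = data.rw
    ll = float((rw * np.log(pf)).sum())
    # dL/dU(t) accumulators from item terms: (w/p) * outer(g1_i, a_r)
    coef = np.where(p > floor, rw / pf, 0.0)
    E = coef[:, None] * g1[data.ri]  # (R, K)
    A = np.zeros((T, K, K))
    for t in range(1, T):
        idx = data.rows_by_exam[t]
        if idx.size:
            A[t] = E[idx].T @ a[idx]
    if data.mi.size:
        q = G[data.mi, data.mt] @ lamD
        p_obs = np.where(data.md == 1, q, 1.0 - q)
        pf = np.maximum(p_obs, floor)
        ll += float(np.log(pf).sum())
        mcoef = np.where(data.md == 1, 1.0, -1.0) / pf
        mcoef = np.where(p_obs > floor, mcoef, 0.0)
        Em = mcoef[:, None] * g1[data.mi]
        for t in range(1, T):
            sel = data.mt == t
            if sel.any():
                A[t] += np.outer(Em[sel].sum(axis=0), lamD)
    # exam-1 terms (t=0) do not depend on the transfers (U(1) = I)

    # adjoint through U(t) = U(t-1) P_{t-1}
    dP = np.zeros_like(P)
    D = A[T - 1]
    dP[T - 2] = U[T - 2].T @ D
    for t in range(T - 3, -1, -1):
        D = A[t + 1] + D @ P[t + 1].T
        dP[t] = U[t].T @ D

    # softmax rows -> logits
    grad = np.zeros_like(z)
    pos = 0
    for m in range(K - 1):
        width = K - 1 - m
        cols = np.arange(m, K)
        s = P[:, m, cols]  # (T-1, width+1), first entry = stay prob
        drow = dP[:, m, cols]
        inner = (s * drow).sum(axis=1, keepdims=True)
        grow = s * (drow - inner)
        grad[:, pos : pos + width] = grow[:, 1:]
        pos += width
    return -ll, -grad.ravel()
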