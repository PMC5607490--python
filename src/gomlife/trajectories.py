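"""Deterministic pure-subtype trajectories and their mixture composition.

Disease progression is modeled as irreversible movement of GoM scores across
the simplex toward the terminal subtype K.  Each prognostic subtype k < K
carries a deterministic path u_k(t) starting at its vertex e_k; a subject with
initial scores g(1) follows the weighted combination
``g(t) = sum_k g_k(1) u_k(t)``.

The paths are parameterized by per-step *transfer matrices*: at each
examination step an upper-triangular row-stochastic matrix P_t moves score
mass only from lower-numbered to higher-numbered subtypes (the terminal row is
the identity), so ``u_k(t) = e_k P_1 ... P_{t-1}``.  Row entries are logistic
(softmax) transforms of unconstrained logits, which guarantees every
structural constraint by construction: vertex initial condition, simplex
closure, no mass on lower-numbered subtypes, nondecreasing terminal mass, and
contraction of the composed trajectories in total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CohortValidationError, GoMTrajectory


def n_transfer_params(K: int) -> int:
    """Free logits per step: one per (source m, destination d > m), terminal row fixed."""
    return (K - 1) * K // 2


def transfer_param_index(K: int) -> list[tuple[int, int]]:
    """(source, destination) pairs in flattened logit order."""
    return [(m, d) for m in range(K - 1) for d in range(m + 1, K)]


def transfers_from_logits(logits: np.ndarray, K: int) -> np.ndarray:
    """Map unconstrained logits (T-1, n_free) to transfer matrices (T-1, K, K).

    Row m of each matrix is softmax over {stay, move to m+1, ..., move to K},
    with the stay logit pinned at 0; the terminal row is the identity.
    """
    logits = np.asarray(logits, dtype=float)
    n_steps = logits.shape[0]
    if logits.shape != (n_steps, n_transfer_params(K)):
        raise ValueError(
            f"logits must have shape (n_steps, {n_transfer_params(K)})"
        )
    P = np.zeros((n_steps, K, K))
    pos = 0
    for m in range(K - 1):
        width = K - 1 - m
        z = logits[:, pos : pos + width]  # (n_steps, width)
        pos += width
        full = np.concatenate([np.zeros((n_steps, 1)), z], axis=1)
        full = full - full.max(axis=1, keepdims=True)
        e = np.exp(full)
        probs = e / e.sum(axis=1, keepdims=True)
        P[:, m, m] = probs[:, 0]
        P[:, m, m + 1 :] = probs[:, 1:]
    P[:, K - 1, K - 1] = 1.0
    return P


def cumulative_transfers(P: np.ndarray) -> np.ndarray:
    """Cumulative products U(t) = P_1 ... P_{t-1}, shape (T, K, K); U(1) = I.

    Row k of U(t) is the pure trajectory u_{k+1}(t).
    """
    n_steps, K, _ = P.shape
    U = np.empty((n_steps + 1, K, K))
    U[0] = np.eye(K)
    for t in range(n_steps):
        U[t + 1] = U[t] @ P[t]
    return U


@dataclass
class PureTrajectorySet:
    """The K-1 prognostic paths u_k(t) plus the implicit terminal vertex path.

    ``u`` has shape (K-1, T, K).  When built from transfer logits the
    structural constraints hold automatically; arbitrary arrays are validated.
    """

    u: np.ndarray
    logits: np.ndarray | None = None  # (T-1, n_free) if transfer-parameterized

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != self.u.shape[0] + 1:
            raise CohortValidationError("pure trajectories must have shape (K-1, T, K)")
        rep = validate_trajectories(self, _construct=True)
        if not rep.ok:
            raise CohortValidationError(
                "invalid pure trajectory set: " + "; ".join(rep.violations)
            )

    @classmethod
    def from_logits(cls, logits: np.ndarray, K: int) -> "PureTrajectorySet":
        P = transfers_from_logits(logits, K)
        U = cumulative_transfers(P)
        return cls(u=np.transpose(U, (1, 0, 2))[: K - 1], logits=np.asarray(logits, float))

    @property
    def K(self) -> int:
        return self.u.shape[2]

    @property
    def n_exams(self) -> int:
        return self.u.shape[1]

    def full(self) -> np.ndarray:
        """(K, T, K) including the constant terminal path e_K."""
        K, T = self.K, self.n_exams
        out = np.empty((K, T, K))
        out[: K - 1] = self.u
        out[K - 1] = 0.0
        out[K - 1, :, K - 1] = 1.0
        return out

    def cumulative(self) -> np.ndarray:
        """(T, K, K) matrices U(t) whose row k is u_{k+1}(t)."""
        return np.transpose(self.full(), (1, 0, 2))


def compose_trajectory(g1: np.ndarray, pure: PureTrajectorySet) -> GoMTrajectory:
    """Mix the pure paths with initial scores: g(t) = sum_k g_k(1) u_k(t).

    ``g1`` must lie on the K-simplex (tolerance 1e-6).  The result is a valid
    trajectory with g(1) = g1 whose terminal component is nondecreasing.
    """
    g1 = np.asarray(g1, dtype=float)
    if g1.shape != (pure.K,):
        raise CohortValidationError(f"initial scores must have shape ({pure.K},)")
    if np.any(g1 < -1e-6) or abs(g1.sum() - 1.0) > 1e-6:
        raise CohortValidationError("initial scores must lie on the simplex")
    g1 = np.clip(g1, 0.0, None)
    g1 = g1 / g1.sum()
    scores = np.einsum("k,tkm->tm", g1, pure.cumulative())
    # renormalize away accumulated rounding so the trajectory invariants hold
    scores = np.clip(scores, 0.0, None)
    scores /= scores.sum(axis=1, keepdims=True)
    scores[:, -1] = np.maximum.accumulate(scores[:, -1])
    return GoMTrajectory(scores)


@dataclass
class TrajectoryReport:
    """Result of :func:`validate_trajectories` (report-only)."""

    ok: bool
    violations: list = field(default_factory=list)
    hull_distance_to_terminal: np.ndarray | None = None  # per exam, Hausdorff to e_K
    tv_diameter: np.ndarray | None = None  # per exam, max pairwise TV distance


def validate_trajectories(
    pure: PureTrajectorySet, atol: float = 1e-8, _construct: bool = False
) -> TrajectoryReport:
    """Check the structural constraints and report hull contraction.

    Confirms the vertex initial condition, simplex closure, nondecreasing
    terminal mass and the ordering constraint (no mass on lower-numbered
    subtypes), and reports two per-exam contraction diagnostics: the Hausdorff
    distance of the path set to the terminal vertex and the total-variation
    diameter of the path set — both shrink as the score range contracts.
    """
    u = pure.u
    Km1, T, K = u.shape
    v: list[str] = []
    if np.any(u < -atol) or np.any(np.abs(u.sum(axis=2) - 1.0) > atol):
        v.append("simplex violation")
    for k in range(Km1):
        ek = np.zeros(K)
        ek[k] = 1.0
        if np.any(np.abs(u[k, 0] - ek) > atol):
            v.append(f"trajectory {k + 1} does not start at its vertex")
        bad_t = np.nonzero(np.diff(u[k, :, -1]) < -atol)[0]
        if bad_t.size:
            v.append(
                f"trajectory {k + 1}: terminal component decreases between exams "
                f"{bad_t[0] + 1} and {bad_t[0] + 2}"
            )
        if k > 0 and np.any(u[k, :, :k] > atol):
            v.append(f"trajectory {k + 1}: mass on a lower-numbered subtype")
    if _construct:
        return TrajectoryReport(ok=not v, violations=v)
    full = pure.full()
    hull = (1.0 - full[:, :, -1]).max(axis=0)
    diam = np.zeros(T)
    for a in range(K):
        for b in range(a + 1, K):
            diam = np.maximum(diam, 0.5 * np.abs(full[a] - full[b]).sum(axis=1))
    return TrajectoryReport(
        ok=not v,
        violations=v,
        hull_distance_to_terminal=hull,
        tv_diameter=diam,
    )
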