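"""Core types, validation and text-format I/O for longitudinal GoM cohorts.

A cohort is a long-format table of categorical responses — one row per
(subject, examination, variable, level) — together with a vital-status table
giving, for every subject, either the 6-month interval in which death occurred
or the last interval through which survival is known (censoring).  Examinations
are indexed 1..T on a semiannual grid (T = 21 covers 10 years); mortality
intervals are the half-open gaps (exam t, exam t+1], indexed 1..T-1.

All probabilities are stored on [0, 1]; percentages appear only in
presentation-layer output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: number of semiannual examinations (10-year follow-up)
DEFAULT_N_EXAMS = 21
#: length of one inter-examination interval, in years
INTERVAL_YEARS = 0.5

#: name of the auto-generated death variable
DEATH_VARIABLE = "_death"

SIMPLEX_ATOL = 1e-6
MODEL_SCHEMA_VERSION = 1

ROLES = ("symptom", "disability", "death", "summary")


class CohortValidationError(ValueError):
    """A cohort or model file violates a structural invariant."""


@dataclass(frozen=True)
class Variable:
    """One categorical variable (covariate) with ``n_levels`` coded 0..L-1."""

    name: str
    n_levels: int
    domain: str = ""
    ordered: bool = True
    fixed: bool = False
    role: str = "symptom"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise CohortValidationError(
                f"variable {self.name!r}: n_levels must be >= 2, got {self.n_levels}"
            )
        if self.role not in ROLES:
            raise CohortValidationError(
                f"variable {self.name!r}: unknown role {self.role!r}"
            )


class VariableCatalog:
    """Declared set of variables; the binary death variable is auto-created.

    Exactly one variable carries ``role='death'`` (added automatically when the
    user does not supply one) and at most one carries ``role='disability'``;
    the full-time-care (FTC) state is by convention the *top* level of the
    disability variable.
    """

    def __init__(self, variables: list[Variable]):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in catalog")
        if not any(v.role == "death" for v in variables):
            variables = list(variables) + [
                Variable(DEATH_VARIABLE, 2, domain="vital", role="death")
            ]
        if sum(v.role == "death" for v in variables) != 1:
            raise CohortValidationError("catalog must contain exactly one death variable")
        if sum(v.role == "disability" for v in variables) > 1:
            raise CohortValidationError("catalog may contain at most one disability variable")
        self.variables: tuple[Variable, ...] = tuple(variables)
        self._by_name = {v.name: v for v in self.variables}

    def __getitem__(self, name: str) -> Variable:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def item_variables(self) -> tuple[Variable, ...]:
        """All variables that appear as responses (everything but death)."""
        return tuple(v for v in self.variables if v.role != "death")

    @property
    def death_variable(self) -> Variable:
        return next(v for v in self.variables if v.role == "death")

    @property
    def disability_variable(self) -> Variable | None:
        for v in self.variables:
            if v.role == "disability":
                return v
        return None

    @property
    def ftc_level(self) -> int | None:
        """Level index coding full-time care: the top category of the disability variable."""
        v = self.disability_variable
        return None if v is None else v.n_levels - 1

    def to_dict(self) -> list[dict]:
        return [
            dict(
                name=v.name,
                n_levels=v.n_levels,
                domain=v.domain,
                ordered=v.ordered,
                fixed=v.fixed,
                role=v.role,
            )
            for v in self.variables
        ]

    @classmethod
    def from_dict(cls, records: list[dict]) -> "VariableCatalog":
        return cls([Variable(**r) for r in records])


@dataclass
class Cohort:
    """Validated long-format cohort.

    Parameters
    ----------
    responses : DataFrame with columns subject_id, exam, variable, level.
        Missing (subject, exam, variable) combinations are simply absent —
        never imputed.
    vital : DataFrame with columns subject_id, event ('death'|'censor'), interval.
        ``death`` in interval d means the subject was alive at exam d and died
        before exam d+1; ``censor`` at c means survival is known through
        interval c and unknown after.
    catalog : VariableCatalog
    n_exams : total examinations T (default 21).
    """

    responses: pd.DataFrame
    vital: pd.DataFrame
    catalog: VariableCatalog
    n_exams: int = DEFAULT_N_EXAMS

    def __post_init__(self) -> None:
        self.responses = self.responses.reset_index(drop=True)
        self.vital = self.vital.reset_index(drop=True)
        self._validate()
        order = {s: i for i, s in enumerate(self.vital["subject_id"])}
        self.subjects: list = list(self.vital["subject_id"])
        self._subject_index = order

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        req = {"subject_id", "exam", "variable", "level"}
        if not req.issubset(self.responses.columns):
            raise CohortValidationError(f"responses must have columns {sorted(req)}")
        reqv = {"subject_id", "event", "interval"}
        if not reqv.issubset(self.vital.columns):
            raise CohortValidationError(f"vital table must have columns {sorted(reqv)}")
        if self.vital["subject_id"].duplicated().any():
            dup = self.vital.loc[self.vital["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"duplicate vital record for subject {dup!r}")
        bad_event = ~self.vital["event"].isin(["death", "censor"])
        if bad_event.any():
            row = self.vital[bad_event].iloc[0]
            raise CohortValidationError(
                f"subject {row.subject_id!r}: unknown vital event {row.event!r}"
            )
        iv = self.vital["interval"]
        if not np.issubdtype(np.asarray(iv).dtype, np.integer):
            try:
                conv = iv.astype(int)
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(f"malformed vital interval: {exc}") from exc
            if not np.array_equal(conv, iv.astype(float)):
                raise CohortValidationError("malformed vital interval: non-integer value")
            self.vital["interval"] = conv
            iv = self.vital["interval"]
        out = (iv < 1) | (iv > self.n_exams - 1)
        if out.any():
            row = self.vital[out].iloc[0]
            raise CohortValidationError(
                f"subject {row.subject_id!r}: interval {row.interval} outside 1..{self.n_exams - 1}"
            )

        r = self.responses
        unknown = ~r["variable"].isin([v.name for v in self.catalog.item_variables])
        if unknown.any():
            row = r[unknown].iloc[0]
            raise CohortValidationError(
                f"row {row.name}: unknown variable {row.variable!r}"
            )
        n_levels = r["variable"].map({v.name: v.n_levels for v in self.catalog})
        bad_level = (r["level"] < 0) | (r["level"] >= n_levels)
        if bad_level.any():
            row = r[bad_level].iloc[0]
            raise CohortValidationError(
                f"row {row.name}: level {row.level} outside declared levels of "
                f"variable {row.variable!r}"
            )
        bad_exam = (r["exam"] < 1) | (r["exam"] > self.n_exams)
        if bad_exam.any():
            row = r[bad_exam].iloc[0]
            raise CohortValidationError(
                f"row {row.name}: exam {row.exam} outside 1..{self.n_exams}"
            )
        if r.duplicated(subset=["subject_id", "exam", "variable"]).any():
            row = r[r.duplicated(subset=["subject_id", "exam", "variable"])].iloc[0]
            raise CohortValidationError(
                f"duplicate response for subject {row.subject_id!r}, exam {row.exam}, "
                f"variable {row.variable!r}"
            )
        unknown_subj = ~r["subject_id"].isin(self.vital["subject_id"])
        if unknown_subj.any():
            row = r[unknown_subj].iloc[0]
            raise CohortValidationError(
                f"row {row.name}: subject {row.subject_id!r} has no vital record"
            )
        # a subject who died in interval d was last examined alive at exam d
        death = self.vital[self.vital["event"] == "death"]
        last_alive = dict(zip(death["subject_id"], death["interval"]))
        lim = r["subject_id"].map(last_alive)
        posthumous = lim.notna() & (r["exam"] > lim)
        if posthumous.any():
            row = r[posthumous].iloc[0]
            raise CohortValidationError(
                f"row {row.name}: subject {row.subject_id!r} has a response at exam "
                f"{row.exam} after death in interval {int(last_alive[row.subject_id])}"
            )

    # -- conveniences -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_index(self, subject_id) -> int:
        return self._subject_index[subject_id]

    def last_observable_exam(self) -> pd.Series:
        """Per subject, the last exam at which a response may exist.

        Death in interval d -> exam d; censoring at c -> exam c+1.
        """
        iv = self.vital.set_index("subject_id")
        out = iv["interval"].where(iv["event"] == "death", iv["interval"] + 1)
        return out.astype(int)


@dataclass
class CohortReport:
    """Report-only summary produced by :func:`validate_cohort`."""

    n_subjects: int
    n_deaths: int
    n_censored: int
    total_data_points: int
    exams_attended: dict
    missingness: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"missing_fraction": pd.Series(self.missingness, dtype=float)}
        )


def validate_cohort(cohort: Cohort) -> CohortReport:
    """Summarize a cohort: counts, attendance, per-variable missingness.

    Missingness for a time-varying variable is relative to the subject-exam
    slots at which the subject could still respond (up to the death exam or
    one past the censoring interval); fixed variables only have an exam-1 slot.
    """
    r = cohort.responses
    exams_attended = (
        r.groupby("subject_id")["exam"].nunique().to_dict() if len(r) else {}
    )
    n_deaths = int((cohort.vital["event"] == "death").sum())
    missing: dict[str, float] = {}
    if cohort.n_subjects:
        last = cohort.last_observable_exam()
        slots_tv = int(last.clip(upper=cohort.n_exams).sum())
        counts = r.groupby("variable").size()
        for v in cohort.catalog.item_variables:
            denom = cohort.n_subjects if v.fixed else slots_tv
            got = int(counts.get(v.name, 0))
            missing[v.name] = 1.0 - got / denom if denom else float("nan")
    return CohortReport(
        n_subjects=cohort.n_subjects,
        n_deaths=n_deaths,
        n_censored=cohort.n_subjects - n_deaths,
        total_data_points=int(len(r)),
        exams_attended=exams_attended,
        missingness=missing,
    )


# ---------------------------------------------------------------------------
# cohort I/O (long CSV + vital CSV)
# ---------------------------------------------------------------------------

def read_cohort(
    responses_path,
    vital_path,
    catalog: VariableCatalog,
    n_exams: int = DEFAULT_N_EXAMS,
) -> Cohort:
    """Read a cohort from the long response CSV and companion vital CSV."""
    responses = pd.read_csv(
        responses_path, dtype={"subject_id": str, "variable": str}
    )
    vital = pd.read_csv(vital_path, dtype={"subject_id": str, "event": str})
    for col in ("exam", "level"):
        if col in responses and not np.issubdtype(responses[col].dtype, np.integer):
            try:
                responses[col] = responses[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(f"malformed {col} column: {exc}") from exc
    return Cohort(responses, vital, catalog, n_exams=n_exams)


def write_cohort(cohort: Cohort, responses_path, vital_path) -> None:
    cohort.responses.to_csv(responses_path, index=False)
    cohort.vital.to_csv(vital_path, index=False)


# ---------------------------------------------------------------------------
# subtype model (parameters) + I/O
# ---------------------------------------------------------------------------

class GoMTrajectory:
    """A per-subject sequence of GoM score vectors g(t), t = 1..T.

    Scores are nonnegative, sum to 1 at every examination, and the terminal
    (last) component never decreases: disease progression is irreversible.
    """

    __slots__ = ("scores",)

    def __init__(self, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2:
            raise CohortValidationError("trajectory scores must be a (T, K) array")
        if np.any(scores < -1e-9):
            raise CohortValidationError("trajectory has negative scores")
        sums = scores.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise CohortValidationError("trajectory scores must sum to 1 at every exam")
        if np.any(np.diff(scores[:, -1]) < -1e-9):
            raise CohortValidationError("terminal score component must be nondecreasing")
        self.scores = scores

    @property
    def n_exams(self) -> int:
        return self.scores.shape[0]

    @property
    def n_subtypes(self) -> int:
        return self.scores.shape[1]

    def __getitem__(self, t: int) -> np.ndarray:
        """Score vector at 1-based examination ``t``."""
        return self.scores[t - 1]


@dataclass
class SubtypeModel:
    """Fitted (or preset) model parameters.

    Attributes
    ----------
    catalog : variable catalog the λ tables refer to.
    lambdas : mapping variable name -> (K, L_j) array of pure-subtype response
        probabilities, constant over examinations; rows sum to 1.
    mortality_lambdas : (K,) per-subtype 6-month death probabilities.
    pure_trajectories : (K-1, T, K) array; row k-1 is the deterministic path
        u_k(t) of a subject starting at prognostic vertex k.  The terminal
        subtype K is absorbing (u_K(t) = e_K, not stored).
    exam1_weight : weight w1 >= 1 applied to examination-1 likelihood terms.
    meta : fit metadata (log-likelihood, convergence info, ...).
    """

    K: int
    catalog: VariableCatalog
    lambdas: dict
    mortality_lambdas: np.ndarray
    pure_trajectories: np.ndarray
    exam1_weight: float = 1.0
    n_exams: int = DEFAULT_N_EXAMS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mortality_lambdas = np.asarray(self.mortality_lambdas, dtype=float)
        self.pure_trajectories = np.asarray(self.pure_trajectories, dtype=float)
        self.lambdas = {k: np.asarray(v, dtype=float) for k, v in self.lambdas.items()}
        self._validate()

    def _validate(self) -> None:
        K, T = self.K, self.n_exams
        if K < 2:
            raise CohortValidationError("K must be >= 2 (at least one prognostic + terminal)")
        if self.exam1_weight < 1.0:
            raise CohortValidationError("exam1_weight must be >= 1")
        if self.mortality_lambdas.shape != (K,):
            raise CohortValidationError("mortality_lambdas must have shape (K,)")
        if np.any((self.mortality_lambdas < 0) | (self.mortality_lambdas > 1)):
            raise CohortValidationError("mortality_lambdas must lie in [0, 1]")
        if self.pure_trajectories.shape != (K - 1, T, K):
            raise CohortValidationError(
                "pure_trajectories must have shape (K-1, T, K); terminal subtype "
                f"is implicit. Got {self.pure_trajectories.shape}"
            )
        u = self.pure_trajectories
        if np.any(u < -SIMPLEX_ATOL) or np.any(
            np.abs(u.sum(axis=2) - 1.0) > SIMPLEX_ATOL
        ):
            raise CohortValidationError("pure trajectories must be simplex-valued")
        for k in range(K - 1):
            ek = np.zeros(K)
            ek[k] = 1.0
            if np.any(np.abs(u[k, 0] - ek) > SIMPLEX_ATOL):
                raise CohortValidationError(
                    f"pure trajectory {k + 1} must start at its vertex e_{k + 1}"
                )
            if np.any(np.diff(u[k, :, -1]) < -SIMPLEX_ATOL):
                raise CohortValidationError(
                    f"pure trajectory {k + 1}: terminal component must be nondecreasing"
                )
            if k > 0 and np.any(u[k, :, :k] > SIMPLEX_ATOL):
                raise CohortValidationError(
                    f"pure trajectory {k + 1}: mass on a lower-numbered subtype"
                )
        for name, lam in self.lambdas.items():
            if name not in self.catalog:
                raise CohortValidationError(f"lambda table for unknown variable {name!r}")
            Lj = self.catalog[name].n_levels
            if lam.shape != (K, Lj):
                raise CohortValidationError(
                    f"lambda table for {name!r} must have shape ({K}, {Lj})"
                )
            if np.any(lam < -SIMPLEX_ATOL) or np.any(
                np.abs(lam.sum(axis=1) - 1.0) > SIMPLEX_ATOL
            ):
                raise CohortValidationError(
                    f"lambda rows for variable {name!r} must sum to 1"
                )

    # -- conveniences -------------------------------------------------------
    @property
    def ftc_lambdas(self) -> np.ndarray | None:
        """Per-subtype probability of the full-time-care level, if declared."""
        v = self.catalog.disability_variable
        if v is None or v.name not in self.lambdas:
            return None
        return self.lambdas[v.name][:, -1]

    def full_pure_trajectories(self) -> np.ndarray:
        """(K, T, K) array including the constant terminal path e_K."""
        K, T = self.K, self.n_exams
        full = np.empty((K, T, K))
        full[: K - 1] = self.pure_trajectories
        full[K - 1] = 0.0
        full[K - 1, :, K - 1] = 1.0
        return full


def write_model(model: SubtypeModel, path) -> None:
    """Serialize a SubtypeModel to JSON (lossless for float64)."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "K": model.K,
        "n_exams": model.n_exams,
        "exam1_weight": model.exam1_weight,
        "variables": model.catalog.to_dict(),
        "lambdas": {k: v.tolist() for k, v in model.lambdas.items()},
        "mortality_lambdas": model.mortality_lambdas.tolist(),
        "pure_trajectories": model.pure_trajectories.tolist(),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> SubtypeModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise CohortValidationError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    return SubtypeModel(
        K=doc["K"],
        catalog=VariableCatalog.from_dict(doc["variables"]),
        lambdas={k: np.asarray(v) for k, v in doc["lambdas"].items()},
        mortality_lambdas=np.asarray(doc["mortality_lambdas"]),
        pure_trajectories=np.asarray(doc["pure_trajectories"]),
        exam1_weight=doc.get("exam1_weight", 1.0),
        n_exams=doc.get("n_exams", DEFAULT_N_EXAMS),
        meta=doc.get("meta", {}),
    )
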