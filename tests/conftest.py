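import numpy as np
import pandas as pd
import pytest

from gomlife import (
    Cohort,
    SubtypeModel,
    Variable,
    VariableCatalog,
)
from gomlife.trajectories import (
    PureTrajectorySet,
    n_transfer_params,
)


@pytest.fixture
def tiny_catalog():
    return VariableCatalog(
        [
            Variable("cog", 3, domain="cognition"),
            Variable("func", 2, domain="functioning"),
            Variable("eic", 3, domain="dependence", role="disability"),
        ]
    )


@pytest.fixture
def tiny_cohort(tiny_catalog):
    """2 subjects, 3 variables, 2 exams, one death in interval 1."""
    responses = pd.DataFrame(
        [
            ("A", 1, "cog", 0),
            ("A", 1, "func", 1),
            ("A", 1, "eic", 0),
            ("B", 1, "cog", 2),
            ("B", 1, "eic", 2),
            ("B", 2, "func", 0),
        ],
        columns=["subject_id", "exam", "variable", "level"],
    )
    vital = pd.DataFrame(
        [("A", "death", 1), ("B", "censor", 2)],
        columns=["subject_id", "event", "interval"],
    )
    return Cohort(responses, vital, tiny_catalog, n_exams=5)


def make_small_model(K=4, T=10, n_binary=10, seed=7, separation=0.9):
    """Compact well-separated model for fast simulation tests."""
    rng = np.random.default_rng(seed)
    variables = [Variable(f"b{j:02d}", 2) for j in range(n_binary)]
    variables.append(Variable("eic", 3, role="disability"))
    catalog = VariableCatalog(variables)
    lambdas = {}
    for j in range(n_binary):
        hi = rng.permutation(K) / max(K - 1, 1)
        p1 = 0.5 + (hi - 0.5) * separation
        lambdas[f"b{j:02d}"] = np.column_stack([1 - p1, p1])
    lambdas["eic"] = np.array(
        [[0.9, 0.1, 0.0], [0.8, 0.2, 0.0], [0.4, 0.6, 0.0], [0.1, 0.068, 0.832]]
    )[:K]
    z = rng.normal(-1.8, 0.2, size=(T - 1, n_transfer_params(K)))
    mort = np.zeros(K)
    mort[0], mort[-1] = 0.006, 0.16
    return SubtypeModel(
        K=K,
        catalog=catalog,
        lambdas=lambdas,
        mortality_lambdas=mort,
        pure_trajectories=PureTrajectorySet.from_logits(z, K).u,
        n_exams=T,
    )


@pytest.fixture
def small_model():
    return make_small_model()
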