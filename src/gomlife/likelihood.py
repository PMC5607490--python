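"""Likelihood-estimation operations (thin wrappers over LongitudinalGoM)."""

from .estimator import (
    EstimationConfig,
    FitResult,
    LongitudinalGoM,
    estimate_scores_single_exam,
    fit_conditional_lambdas,
    fit_model,
    response_distribution,
    select_exam1_weight,
    weighted_loglik,
)

__all__ = [
    "EstimationConfig",
    "FitResult",
    "LongitudinalGoM",
    "estimate_scores_single_exam",
    "fit_conditional_lambdas",
    "fit_model",
    "response_distribution",
    "select_exam1_weight",
    "weighted_loglik",
]
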