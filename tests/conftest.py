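import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture(scope="session")
def evaluator():
    """Shared tail evaluator with the default point budget."""
    from pwer import TailEvaluator

    return TailEvaluator()


@pytest.fixture(scope="session")
def fast_evaluator():
    """Reduced point budget for tests that solve many designs."""
    from pwer import TailEvaluator

    return TailEvaluator(n_points=2**10)


def random_correlation(d: int, rng: np.random.Generator) -> np.ndarray:
    """A well-conditioned random correlation matrix."""
    A = rng.normal(size=(d, d))
    S = A @ A.T + d * np.eye(d)
    Di = 1.0 / np.sqrt(np.diag(S))
    return S * Di[:, None] * Di[None, :]


def random_design(m: int, N: int, rng: np.random.Generator, regime="known-homogeneous"):
    """A random biomarker design: counts, allocation and statistic model."""
    from pwer import (
        BiomarkerModel,
        TreatmentPattern,
        VarianceModel,
        correlation_matrix,
        draw_strata_counts,
        stratified_allocation,
        true_prevalences,
    )

    while True:
        p = rng.uniform(0.15, 0.85, size=m)
        prev, tau = true_prevalences(BiomarkerModel(m=m, probs=p))
        counts = draw_strata_counts(prev, N, rng)
        pattern = TreatmentPattern.distinct(m)
        alloc = stratified_allocation(counts, pattern, seed=rng)
        try:
            model = correlation_matrix(alloc, VarianceModel(regime))
        except Exception:
            continue
        return prev, counts, alloc, model
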