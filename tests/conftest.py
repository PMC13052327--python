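import numpy as np
import pandas as pd
import pytest

from proteoage import (
    ComparisonSpec,
    DifferentialExpression,
    SimulationConfig,
    classify,
    simulate_cohort,
    validate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with planted effects, shared across tests."""
    config = SimulationConfig(
        n_proteins=300,
        effect_fractions=(0.70, 0.10, 0.10, 0.10),
        seed=11,
    )
    matrix, cohort, truth = simulate_cohort(config)
    return matrix, validate_cohort(cohort), truth


@pytest.fixture(scope="session")
def de_results(small_cohort):
    matrix, cohort, _ = small_cohort
    de_age = DifferentialExpression(
        matrix, cohort, ComparisonSpec("OC", "YC", paired=False)
    ).fit()
    de_disease = DifferentialExpression(
        matrix, cohort, ComparisonSpec("OP", "OC", paired=True)
    ).fit()
    return de_age, de_disease


@pytest.fixture(scope="session")
def assignment(de_results):
    return classify(*de_results)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival_frame(n=60, p=6, beta=(1.0, 1.0), seed=0, rate=0.1, horizon=6.0):
    """Simple single-purpose survival fixture: two strata, planted effects on
    the first ``len(beta)`` covariates."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"P{j:05d}" for j in range(1, p + 1)]
    )
    lp = X.to_numpy()[:, : len(beta)] @ np.asarray(beta)
    t = rng.exponential(1.0 / (rate * np.exp(lp)))
    event = (t < horizon).astype(int)
    t = np.minimum(t, horizon)
    strata = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    sex = pd.DataFrame({"sex_male": rng.integers(0, 2, n).astype(float)})
    return X, t, event, strata, sex
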