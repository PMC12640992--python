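import numpy as np
import pytest

from panfuse.io import ExpressionMatrix, SurvivalTable
from panfuse.synth import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated planted subtypes, 90 samples x 40 genes."""
    cfg = SimulationConfig(
        n_samples=90, n_genes=40, k_subtypes=3, n_informative=20,
        effect_size=6.0, seed=11,
    )
    X, truth, _ = simulate_expression(cfg)
    return X, truth


@pytest.fixture(scope="session")
def separable_cohort():
    """Reference study cohort: 300 samples x 200 genes, k=3, effect size 3."""
    cfg = SimulationConfig(
        n_samples=300, n_genes=200, k_subtypes=3, n_informative=40,
        effect_size=3.0, seed=1,
    )
    X, truth, _ = simulate_expression(cfg)
    return X, truth


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        ["TP53", "CASP8", "NINJ1"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.5, -0.25], [0.0, 7.0]]),
    )


@pytest.fixture
def simple_survival():
    return SurvivalTable(
        [f"s{i}" for i in range(1, 5)],
        np.array([1.0, 2.0, 3.0, 4.0]),
        np.array([1, 1, 1, 1]),
    )
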