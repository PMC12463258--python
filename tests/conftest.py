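import numpy as np
import pytest

from icare.case_store import CaseTable
from icare.synthgen import ScenarioSpec, generate


@pytest.fixture(scope="session")
def scenario1():
    """Moderate-size scenario-1 table: features predictive on opposite halves."""
    return generate(ScenarioSpec.standard(1, n_samples=600, seed=11))


@pytest.fixture(scope="session")
def scenario4():
    """Two added features identical in law (nothing to personalize)."""
    return generate(ScenarioSpec.standard(4, n_samples=600, seed=11))


@pytest.fixture(scope="session")
def scenario5():
    """One dominant feature plus two pure-noise features."""
    return generate(ScenarioSpec.standard(5, n_samples=600, seed=11))


@pytest.fixture
def tiny_table():
    """Hand-sized 6-case pool over three features, both classes present."""
    X = np.array(
        [
            [0.0, 0.1, 0.9],
            [0.2, 0.3, 0.8],
            [0.4, 0.6, 0.7],
            [0.6, 0.4, 0.3],
            [0.8, 0.7, 0.2],
            [1.0, 0.9, 0.1],
        ]
    )
    y = np.array([0, 0, 0, 1, 1, 1])
    return CaseTable(feature_names=["a", "b", "c"], X=X, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
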