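import numpy as np
import pytest

from stabmark import CorrelationSpec, LabeledMatrix, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_signal_data():
    """50x20 independent dataset with 2 strongly shifted variables."""
    return simulate_dataset(
        SimulationConfig(n_total=50, p=20, q=0.1, delta=2.0, seed=42)
    )


@pytest.fixture
def noise_data(rng):
    """Pure-noise two-group data (no truth mask, no signal)."""
    n, p = 40, 30
    return LabeledMatrix(
        X=rng.standard_normal((n, p)),
        y=np.repeat([0, 1], n // 2),
        var_names=np.array([f"V{i}" for i in range(p)], dtype=object),
    )


def make_labeled(X, y, truth=None):
    X = np.asarray(X, dtype=float)
    return LabeledMatrix(
        X=X,
        y=np.asarray(y),
        var_names=np.array([f"V{i}" for i in range(X.shape[1])], dtype=object),
        truth=truth,
    )


@pytest.fixture
def block_config():
    return SimulationConfig(
        n_total=50, p=50, q=0.1, delta=0.4,
        correlation=CorrelationSpec("block"), seed=7,
    )
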