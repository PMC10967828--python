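import numpy as np
import pytest

from octseg import ModelConfig, SyntheticConfig, build_model, generate_dataset


@pytest.fixture(scope="session")
def tiny_synth_config():
    """Small, fully deterministic layered phantom used across modules."""
    return SyntheticConfig(height=64, width=32, seed=42)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_synth_config):
    pairs, _ = generate_dataset(tiny_synth_config, 12)
    return pairs


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest hybrid model that still has the full 5-stage layout."""
    return build_model(ModelConfig(depth=5, base_channels=2,
                                   input_shape=(64, 32), seed=0))


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x (float64)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g
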