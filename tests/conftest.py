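import numpy as np
import pytest

from nucposer import SimConfig, analyze_dataset, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The default study conditions: 200 genes, 50x coverage, fixed seed."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return analyze_dataset(default_dataset)


def gaussian_bumps(length: int, centers, heights, sigma: float = 30.0) -> np.ndarray:
    """Noise-free coverage: a sum of Gaussian nucleosome bumps."""
    x = np.arange(length, dtype=float)
    cov = np.zeros(length)
    for c, h in zip(centers, heights):
        cov += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return cov
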