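import numpy as np
import pytest

from harmonyseg import HSParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_params():
    """Small 3-D search box [0, 1]^3 with a quick budget."""
    return HSParams(
        n_dims=3,
        lower_bound=0.0,
        upper_bound=1.0,
        hms=10,
        max_iterations=50,
        seed=7,
    )


@pytest.fixture
def clean_phantom():
    """Noise-free three-class phantom: classes are exactly separable."""
    return generate_phantom(
        shape=(64, 64),
        class_means=(0.2, 0.5, 0.8),
        class_stds=0.0,
        geometry="nested_disks",
        seed=11,
    )


@pytest.fixture
def noisy_phantom():
    """Moderately noisy three-class phantom."""
    return generate_phantom(
        shape=(64, 64),
        class_means=(0.2, 0.5, 0.8),
        class_stds=0.05,
        geometry="nested_disks",
        seed=13,
    )
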