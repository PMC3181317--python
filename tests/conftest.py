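import numpy as np
import pytest

from diffpcor import GroupedDataset, SimulationSpec, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_dataset(rng):
    """Two Gaussian groups, M=4, with a shared latent factor."""
    factor = rng.standard_normal((40, 1))
    values = 0.6 * factor + rng.standard_normal((40, 4))
    labels = np.array(["A"] * 25 + ["B"] * 15, dtype=object)
    return GroupedDataset(values, ["w", "x", "y", "z"], labels)


@pytest.fixture
def null_spec():
    """Two groups drawn from one block-structured model (global null)."""
    return SimulationSpec(block_sizes=[5, 5], n_a=200, n_b=200, seed=0)


def make_null_dataset(seed, block_sizes=(5, 5), n_a=200, n_b=200):
    spec = SimulationSpec(
        block_sizes=list(block_sizes), n_a=n_a, n_b=n_b, seed=seed
    )
    return sample_dataset(spec)
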