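import numpy as np
import pandas as pd
import pytest

from ffnet import AbundanceTable, SimConfig, simulate_dataset


def make_table(values, mode="raw", features=None, samples=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"F{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=features, columns=samples), mode=mode)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Planted-coupling dataset with no coupling noise: every truth edge is
    perfectly monotone on the emitted tables."""
    return simulate_dataset(
        SimConfig(n_timepoints=8, n_microbes=20, n_volatiles=50,
                  n_coupled_pairs=30, noise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_dataset(
        SimConfig(n_timepoints=8, n_microbes=12, n_volatiles=20,
                  n_coupled_pairs=10, noise_sd=0.4, seed=7)
    )
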