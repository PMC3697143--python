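import numpy as np
import pytest

from spectralglm import (
    MultiRunSeries,
    StimulusSet,
    generate_stimulus_train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study_stimuli():
    """Event-related two-stimulus schedule at the study's design shape."""
    ind = generate_stimulus_train(
        T=156, TR=2.0, duration_s=2.0, isi_range_s=(0.0, 8.0), seed=7, n_types=2
    )
    return StimulusSet(ind, ("pos", "neg"), 2.0)


def white_noise_series(rng, n_voxels=50, S=3, T=156, sigma=1.0, baseline=100.0):
    values = baseline + rng.normal(0.0, sigma, size=(n_voxels, S, T))
    grid = (n_voxels, 1, 1)
    return MultiRunSeries(
        values, tuple(f"run{s}" for s in range(S)), grid, np.ones(grid, bool), 2.0
    )


@pytest.fixture
def noise_series(rng):
    return white_noise_series(rng)
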