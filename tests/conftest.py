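import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from emopac import synth


@pytest.fixture(scope="session")
def tiny_layout():
    """Just the twelve electrodes of the four analysis clusters."""
    return [ch for cl in ("LF", "RF", "LP", "RP") for ch in synth.CLUSTERS[cl]]


@pytest.fixture(scope="session")
def noise_dataset(tiny_layout):
    """Small pure-noise dataset shared by read-only tests."""
    cfg = synth.SimulationConfig(
        n_participants=2, n_trials_per_condition=4, sampling_rate=256.0,
        epoch_window=(-3.0, 10.0), channel_layout=tiny_layout, seed=11,
    )
    return synth.simulate_eeg(cfg, 0)


@pytest.fixture(scope="session")
def coupled_dataset(tiny_layout):
    """Dataset with a strong LF->LP theta/low-gamma coupling injected."""
    cfg = synth.SimulationConfig(
        n_participants=2, n_trials_per_condition=10, sampling_rate=256.0,
        epoch_window=(-3.0, 10.0), channel_layout=tiny_layout,
        conditions=("neutral",),
        coupling_specs=[synth.CouplingSpec("LF", "LP", 5.0, 40.0, 0.8)],
        seed=21,
    )
    return synth.simulate_eeg(cfg, 0)
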