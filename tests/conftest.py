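import numpy as np
import pytest

from h1fret.simulate import SimulationParams, simulate_titration_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_params():
    return SimulationParams(noise_model="none", seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """A full noiseless synthetic titration on disk (WT emulation)."""
    out = tmp_path_factory.mktemp("wt_noiseless")
    params = SimulationParams(noise_model="none", seed=11)
    manifest = simulate_titration_dataset(params, saturation_ratio=1.0,
                                          out_dir=out, condition="WT")
    return manifest, params
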