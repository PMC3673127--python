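import numpy as np
import pytest
from hypothesis import settings

import mripad as mp

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_spec():
    return mp.ColorMapSpec()


@pytest.fixture(scope="session")
def zero_model():
    """Noise-free sensor: deterministic counts."""
    return mp.SensorModel(rel_noise_sigma=0.0, luminance_walk_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_model():
    return mp.SensorModel()


@pytest.fixture(scope="session")
def zero_pipeline(default_spec, zero_model):
    """Zero-noise calibration -> forward map (N=32) -> LUT (B=256)."""
    table = mp.calibrate_simulated(default_spec, zero_model, seed=1)
    fwd = mp.interpolate_forward(table, 32)
    fwd.meta["spec_hash"] = table.meta["spec_hash"]
    lut = mp.build_lut(fwd)
    return table, fwd, lut


@pytest.fixture(scope="session")
def small_pipeline(default_spec, zero_model):
    """Reduced instance for exhaustive oracles: N=8 pixels, B=32 bins."""
    table = mp.calibrate_simulated(default_spec, zero_model, seed=1)
    fwd = mp.interpolate_forward(table, 8)
    fwd.meta["spec_hash"] = table.meta["spec_hash"]
    lut = mp.build_lut(fwd, bins=32)
    return table, fwd, lut


@pytest.fixture(scope="session")
def fixture_lib(default_spec):
    return mp.make_fixture_scripts(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
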