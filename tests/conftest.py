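import numpy as np
import pytest

from ssoptk.inversion import build_lut
from ssoptk.oxygenation import load_extinction_table
from ssoptk.pipeline import PipelineConfig, make_phantom_reference
from ssoptk.scenes import (
    AcquisitionSpec,
    NoiseModel,
    QUARTER_SHAPE,
    make_ischemia_scene,
    render_frames,
)


@pytest.fixture(scope="session")
def ext_table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def lut_02():
    """Default lookup table at the instrument's modulation frequency."""
    return build_lut(0.2)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(noise=NoiseModel(kind="none"), seed=0)


@pytest.fixture(scope="session")
def tvio_t1_scene():
    return make_ischemia_scene("TVIO", "T1", shape=QUARTER_SHAPE)


@pytest.fixture(scope="session")
def tvio_t1_stack(tvio_t1_scene, noiseless_acq):
    return render_frames(tvio_t1_scene, noiseless_acq)


@pytest.fixture(scope="session")
def noiseless_config():
    return PipelineConfig(noise_kind="none")


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_config):
    phantom, _ = make_phantom_reference(noiseless_config, seed=7)
    return phantom
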