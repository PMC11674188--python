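import numpy as np
import pytest

from imfseg import phantom as ph
from imfseg import pipeline as pl


@pytest.fixture(scope="session")
def calf_phantom():
    """One default calf phantom with moderate fat, shared across the suite."""
    return ph.generate_phantom(ph.calf_1T(true_imf_fraction=8.0, seed=7))


@pytest.fixture(scope="session")
def pipeline_config():
    return pl.PipelineConfig(slice_preset="calf_1T")


@pytest.fixture(scope="session")
def calf_case(calf_phantom, pipeline_config):
    """The shared phantom run once through the full pipeline."""
    return pl.segment_case(calf_phantom.volume, pipeline_config)


@pytest.fixture(scope="session")
def lean_phantom():
    """A phantom with zero true fat (lean muscle)."""
    return ph.generate_phantom(ph.calf_1T(true_imf_fraction=0.0, seed=3))


@pytest.fixture(scope="session")
def lean_case(lean_phantom, pipeline_config):
    return pl.segment_case(lean_phantom.volume, pipeline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)
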