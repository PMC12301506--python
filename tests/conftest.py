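import numpy as np
import pytest

from megdot import synthgen as sg
from megdot.pipeline import PipelineConfig, build_context


@pytest.fixture(scope="session")
def small_head():
    """Compact phantom for unit tests (24x24x16 voxels, 2 mm)."""
    return sg.build_head_phantom((24, 24, 16), 2.0)


@pytest.fixture(scope="session")
def small_layout():
    return sg.build_probe_geometry(pitch_mm=10.0)


@pytest.fixture(scope="session")
def small_sens(small_head, small_layout):
    return sg.simulate_sensitivity(small_head, small_layout)


@pytest.fixture(scope="session")
def default_ctx():
    """The study-scale analysis context (40x40x20 phantom, default probe)."""
    return build_context(PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
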