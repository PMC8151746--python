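import numpy as np
import pytest

import pincam as pc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def linear_preset():
    return pc.load_preset("linear_no_overlap")


@pytest.fixture(scope="session")
def circular_preset():
    return pc.load_preset("circular_no_overlap")


@pytest.fixture(scope="session")
def overlap_preset():
    return pc.load_preset("circular_overlap")


@pytest.fixture(scope="session")
def static_preset():
    return pc.load_preset("static_no_overlap")


@pytest.fixture(scope="session")
def sharp_circular_preset(circular_preset):
    """Circular no-overlap camera with the intrinsic blur switched off,
    for tests that need unblurred impact points."""
    import copy

    sysm = copy.deepcopy(circular_preset)
    sysm.panel.intrinsic_fwhm_xy = 0.0
    return sysm


@pytest.fixture(scope="session")
def point_source_events(circular_preset):
    """Small shared acquisition: point-like source at mid FOV."""
    from pincam.phantoms import Phantom, Sphere

    phantom = Phantom([Sphere((0.0, 0.0, 50.0), 1.0, 1e5)], "pt50")
    config = pc.AcquisitionConfig(duration=10.0, seed=42)
    return pc.simulate(phantom, circular_preset, config)
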