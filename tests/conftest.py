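import numpy as np
import pytest

from ctcap import BodySpec, build_spectrum, scale_reference_phantom


@pytest.fixture(scope="session")
def reference_phantom():
    return scale_reference_phantom(BodySpec(height_cm=178.6, weight_kg=73.2))


@pytest.fixture(scope="session")
def ct_spectrum():
    """The modelled CT beam: 120 kV, 7.4 mm Al HVL."""
    return build_spectrum(120.0, target_hvl_al_mm=7.4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20111017)
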