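import numpy as np
import pytest

from waspmorph.landmark_io import DEFAULT_HEAD_SCHEME, LandmarkConfiguration
from waspmorph.synthetic import make_templates


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def scheme():
    return DEFAULT_HEAD_SCHEME


@pytest.fixture
def symmetric_config():
    """A perfectly bilaterally symmetric head (the Nv male template)."""
    coords = make_templates()[("Nv", "male")].coords
    return LandmarkConfiguration(specimen_id="sym", coords=coords)


@pytest.fixture
def random_config_factory(rng):
    """Factory for nondegenerate random 16-landmark configurations: template
    plus isotropic jitter, so shapes stay head-like but asymmetric."""
    base = make_templates()[("Ng", "male")].coords

    def make(jitter=0.05, specimen_id="rand"):
        return LandmarkConfiguration(
            specimen_id=specimen_id,
            coords=base + rng.normal(0.0, jitter, size=base.shape),
        )

    return make
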