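import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from canalseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default desk-scale phantom: 160x160x128 voxels at 0.4 mm."""
    return generate_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free phantom with the default intensity ladder."""
    return generate_phantom(PhantomConfig(seed=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def fine_phantom():
    """Scanner-resolution phantom: the same 64 mm field of view sampled at
    0.2 mm (320x320x256), used by the annotation-densification tests."""
    return generate_phantom(PhantomConfig(shape=(320, 320, 256), spacing=(0.2, 0.2, 0.2), seed=0))


@pytest.fixture(scope="session")
def default_roi(default_phantom):
    from canalseg.mandible_roi import extract_mandible_roi

    return extract_mandible_roi(default_phantom.volume)
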