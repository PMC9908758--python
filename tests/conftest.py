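import numpy as np
import pytest

from evtopo import (
    ElectrodeMontage,
    default_montage,
    build_source_space,
    leadfield_single_sphere,
)

try:  # derandomise hypothesis wherever it is used
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def montage64():
    return default_montage()


@pytest.fixture(scope="session")
def montage4():
    """Tiny regular montage for fast container/round-trip tests."""
    pos = np.array(
        [[1.0, 0, 0.3], [-1.0, 0, 0.3], [0, 1.0, 0.3], [0, -1.0, 0.3]]
    )
    return ElectrodeMontage(("A", "B", "C", "D"), pos)


@pytest.fixture(scope="session")
def small_space():
    """~250-node source space for localization tests."""
    return build_source_space(16.0, 4.0, connectivity=26)


@pytest.fixture(scope="session")
def small_lead(small_space, montage64):
    return leadfield_single_sphere(small_space, montage64, head_radius_mm=85.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
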