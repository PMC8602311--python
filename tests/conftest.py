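"""Shared fixtures: small seeded phantoms reused across the suite."""

import numpy as np
import pytest

from rcmstain import PhantomSpec, generate_pair


@pytest.fixture(scope="session")
def phantom_pair():
    """Mid-sized phantom with melanin, shared read-only across tests."""
    spec = PhantomSpec(height=192, width=192, n_slices=5, n_nuclei=20,
                      melanin_fraction=0.2, seed=11)
    return generate_pair(spec)


@pytest.fixture(scope="session")
def small_pair():
    """64x64 phantom sized for network forward/backward passes."""
    spec = PhantomSpec(height=64, width=64, n_slices=14, n_nuclei=6,
                       nucleus_radius_range=(5.0, 8.0), seed=3)
    return generate_pair(spec)


@pytest.fixture(scope="session")
def seg_phantom():
    """Well-separated bright-nucleus phantom for segmentation scoring."""
    spec = PhantomSpec(height=256, width=256, n_slices=3, n_nuclei=30,
                       nucleus_radius_range=(7.0, 7.0), noise_sigma=0.01,
                       seed=5)
    return generate_pair(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
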