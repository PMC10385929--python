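import numpy as np
import pytest

from hydroflex.core import ChannelGeometry
from hydroflex.synthetic import (
    GaussianBeadSpec,
    make_channel_system,
    make_gaussian_beads,
    vibrational_covariance,
    _default_mean,
)


@pytest.fixture(scope="session")
def geom0():
    """Channel geometry with the mirror plane pinned at z = 0 (synthetic
    systems are built symmetric about the origin)."""
    return ChannelGeometry(z_origin=0.0)


@pytest.fixture(scope="session")
def channel_system():
    """One scripted channel system shared across read-only tests."""
    return make_channel_system(n_complete_out=3, n_complete_in=2, n_partial=4,
                               n_interface=2, n_wrap=2, n_bulk=30,
                               n_frames=150, seed=11)


@pytest.fixture(scope="session")
def gauss_vibrational():
    """Gaussian 4-bead fixture with purely vibrational covariance
    (leading eigenvalues 4, 1, 0.25 A^2) and its analytic ground truth."""
    mean = _default_mean(4)
    masses = np.full(4, 100.0)
    lams = np.array([4.0, 1.0, 0.25])
    C = vibrational_covariance(mean, masses, lams)
    res = make_gaussian_beads(GaussianBeadSpec(
        covariance=C, n_frames=10_000, seed=42,
        mean_structure=mean, masses=masses))
    return res, lams
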