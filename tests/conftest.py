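import numpy as np
import pytest

from spindlequant.core import SpindleTrajectory
from spindlequant.params import OpticsParams, PhenotypeParams


@pytest.fixture
def noiseless_params() -> PhenotypeParams:
    return PhenotypeParams(length_noise_sd=0.0)


@pytest.fixture
def small_optics() -> OpticsParams:
    """Small render geometry to keep image tests fast."""
    return OpticsParams(n_y=64, n_x=64, n_slices=9, n_frames=61)


def make_traj(lengths, dt: float = 1.0) -> SpindleTrajectory:
    lengths = np.asarray(lengths, dtype=float)
    return SpindleTrajectory(np.arange(lengths.size) * dt, lengths, dt)


@pytest.fixture
def traj_factory():
    return make_traj


def plateau_ramp(plateau: float, onset: float, rate: float, n: int = 61,
                 plateau_cap: float = 8.0, drift: float = 0.0) -> np.ndarray:
    """Piecewise trace: drift from `plateau` until `onset`, then ramp at `rate`."""
    t = np.arange(n, dtype=float)
    pre = plateau + drift * t
    post = (plateau + drift * onset) + rate * (t - onset)
    return np.minimum(np.where(t <= onset, pre, post), plateau_cap)


@pytest.fixture
def plateau_ramp_factory():
    return plateau_ramp
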