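import numpy as np
import pytest

from motion4d.acquisition import AcquisitionParams, simulate_mr
from motion4d.phantom import PhantomSpec
from motion4d.waveforms import generate_sinusoid


@pytest.fixture(scope="session")
def sin10():
    """Baseline study waveform: 10 mm peak-to-peak, 4 s period."""
    return generate_sinusoid(10, 4, 60, 0.01)


@pytest.fixture(scope="session")
def sin10_fine():
    """Densely sampled sinusoid for binning oracles (dt = 1 ms)."""
    return generate_sinusoid(10, 4, 60, 0.001)


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_acq():
    """Coarse, fast acquisition for structural (non-metrological) tests."""
    return AcquisitionParams(n_spokes=400, n_bins=4, matrix=64, seed=7, orientation="coronal")


@pytest.fixture(scope="session")
def small_mr_set(sin10, small_acq, phantom):
    return simulate_mr(sin10, small_acq, phantom)


@pytest.fixture(scope="session")
def coronal_10bin_set(sin10, phantom):
    """Desk-scale modified-protocol scan: coronal, 10 bins, 3000 views."""
    acq = AcquisitionParams(orientation="coronal", n_bins=10, seed=1)
    return simulate_mr(sin10, acq, phantom)


@pytest.fixture(scope="session")
def static_mr_set(phantom):
    """Motionless phantom under the baseline protocol (coronal for speed)."""
    trace = generate_sinusoid(0, 4, 60, 0.01)
    acq = AcquisitionParams(orientation="coronal", n_bins=5, seed=2)
    return simulate_mr(trace, acq, phantom)


def body_background_mask(matrix: int, fov: float, r_in: float = 35.0, r_out: float = 85.0):
    """In-plane annulus inside the phantom body but clear of the sphere's
    motion range; used for streak/noise statistics."""
    x = (np.arange(matrix) + 0.5) * fov / matrix - fov / 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    rr = np.sqrt(X**2 + Y**2)
    return (rr > r_in) & (rr < r_out)
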