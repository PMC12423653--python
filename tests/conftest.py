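import numpy as np
import pytest

from actifil.greens import build_greens
from actifil.kernel import compute_kernels
from actifil.modal import eigendecompose, travelling_wave_kernel
from actifil.monophasic import analytic_system
from actifil.profiles import fixture_profiles

SP_REF = 4.7  # the monophasic optimum used throughout the worked examples


@pytest.fixture(scope="session")
def greens47():
    return build_greens(SP_REF)


@pytest.fixture(scope="session")
def system47():
    return analytic_system(SP_REF)


@pytest.fixture(scope="session")
def kernel47():
    return compute_kernels(SP_REF, n=100)


@pytest.fixture(scope="session")
def basis47(kernel47):
    return eigendecompose(kernel47)


@pytest.fixture(scope="session")
def kernel_wave():
    """Near-optimal travelling-wave kernel (k = 0.72, Sp = 3)."""
    return travelling_wave_kernel(3.0, 0.72, n=100)


@pytest.fixture(scope="session")
def basis_wave(kernel_wave):
    return eigendecompose(kernel_wave)


@pytest.fixture()
def random_profiles():
    """Five seeded smooth random profiles (low-order Fourier series)."""
    return [fixture_profiles("random", seed=1000 + i) for i in range(5)]


@pytest.fixture()
def uniform_time_grid():
    return np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
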