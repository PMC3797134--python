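import numpy as np
import pytest

from aptcest import (AcquisitionSchedule, PhantomSpec, SaturationParams,
                     ScannerParams, amide_pool, generate_phantom_stack,
                     mt_pool, water_pool)


@pytest.fixture(scope="session")
def scanner():
    return ScannerParams()


@pytest.fixture(scope="session")
def sat():
    return SaturationParams()


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule.default()


@pytest.fixture(scope="session")
def water_only():
    return (water_pool(),)


@pytest.fixture(scope="session")
def tumor_pools():
    """Tumor-like tissue: elevated amide fraction plus MT background."""
    return (water_pool(), amide_pool(3e-3), mt_pool())


@pytest.fixture(scope="session")
def cord_pools():
    """Reference tissue: background amide fraction plus MT background."""
    return (water_pool(), amide_pool(1e-3), mt_pool())


@pytest.fixture(scope="session")
def two_pool():
    """Water + amide only; the oracle configuration without MT."""
    return (water_pool(), amide_pool(3e-3))


@pytest.fixture(scope="session")
def phantom_nf():
    """Noise-free default phantom (smooth B0 field on)."""
    spec = PhantomSpec(noise_sigma=0.0, seed=11)
    stack, truth = generate_phantom_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default phantom with noise, fixed seed."""
    spec = PhantomSpec(seed=11)
    stack, truth = generate_phantom_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
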