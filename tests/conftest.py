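import numpy as np
import pytest

from dixonrecon.kspace import SamplingMask, apply_mask_zero_fill, generate_vd_poisson_mask
from dixonrecon.phantom import (
    PhantomSpec,
    make_thigh_phantom,
    phantom_kspace,
    simulate_dixon_echoes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_mask():
    return generate_vd_poisson_mask(32, 8, 4.0, 0.04, seed=0)


@pytest.fixture(scope="session")
def five_muscle_phantom():
    spec = PhantomSpec(
        matrix=(32, 32, 8),
        n_muscles=5,
        ff_assignments=(5.0, 10.0, 30.0, 60.0, 85.0),
        b0_amplitude=50.0,
        seed=1,
    )
    return make_thigh_phantom(spec)


def make_dataset(seed, mask, noise_sd=0.02, n_muscles=6, matrix=(32, 32, 8)):
    """In-memory phantom acquisition dict matching the HDF5 layout."""
    spec = PhantomSpec(
        matrix=matrix, seed=seed, n_muscles=n_muscles, b0_amplitude=25.0, noise_sd=noise_sd
    )
    ph = make_thigh_phantom(spec)
    stack = simulate_dixon_echoes(ph.water, ph.fat, ph.b0, spec)
    k_full = phantom_kspace(stack)
    k_us = np.stack([apply_mask_zero_fill(k, mask).data for k in k_full])
    return {
        "kspace": k_full,
        "kspace_us": k_us,
        "mask": mask,
        "TE_list": stack.TE_list,
        "phantom": ph,
    }


def random_complex(rng, shape):
    return rng.normal(size=shape) + 1j * rng.normal(size=shape)
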