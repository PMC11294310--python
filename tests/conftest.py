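"""Shared fixtures: kernels from the packaged table and cached slices."""

from functools import lru_cache

import pytest

from phantomiq import (
    AcquisitionSpec,
    PhantomSpec,
    kernel_from_table,
    load_kernel_table,
    simulate_noise_free,
    simulate_slice,
)


@pytest.fixture(scope="session")
def kernel_table():
    return load_kernel_table()


@pytest.fixture(scope="session")
def qr60():
    return kernel_from_table("Qr60")


@pytest.fixture(scope="session")
def qr44():
    return kernel_from_table("Qr44")


@pytest.fixture(scope="session")
def qr72():
    return kernel_from_table("Qr72")


@lru_cache(maxsize=64)
def _cached_noise_free(kernel_name: str, diameter: float, concentration: float):
    phantom = PhantomSpec(inner_diameter=diameter, iodine_concentration=concentration)
    return phantom, simulate_noise_free(phantom, kernel_from_table(kernel_name))


@pytest.fixture(scope="session")
def noise_free_slice():
    """Factory: (kernel name, diameter, concentration) -> (phantom, slice)."""
    return _cached_noise_free


@pytest.fixture(scope="session")
def noisy_slice(noise_free_slice):
    """Factory for seeded noisy slices reusing cached noise-free images."""

    def make(kernel_name: str, diameter: float, concentration: float,
             ctdi: float, qir: int, seed: int):
        phantom, base = noise_free_slice(kernel_name, diameter, concentration)
        acq = AcquisitionSpec(ctdi=ctdi, qir_level=qir)
        img = simulate_slice(
            phantom, kernel_from_table(kernel_name), acq, seed, _noise_free_image=base
        )
        return phantom, img

    return make
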