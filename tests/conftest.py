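import numpy as np
import pytest

from mtpm.scatter import ScatterConfig, ScatterKernel, sample_kernel


@pytest.fixture(scope="session")
def tissue_kernel() -> ScatterKernel:
    """A moderately sampled scattering kernel at 100 µm depth, shared
    across tests that only need a realistic non-trivial PSF."""
    cfg = ScatterConfig(
        mu=20.0, g=0.9, z_h=100.0, n_photons=300_000, kernel_halfwidth=16, seed=42
    )
    return sample_kernel(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
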