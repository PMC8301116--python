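import numpy as np
import pytest

from nmrcal.spectra_io import SpectraMatrix
from nmrcal.synthetic_data import GeneratorConfig, synthesize


@pytest.fixture(scope="session")
def default_set():
    """One default-condition synthetic study: 35 samples, 3072 points."""
    return synthesize(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def clean_set():
    """Noise-free, scatter-free variant with fully driver-determined
    properties: the perfect-recovery limit."""
    return synthesize(GeneratorConfig(seed=1, noise_sd=0.0,
                                      scatter_slope_sd=0.0,
                                      scatter_offset_sd=0.0,
                                      offspectral_residual=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix(rng):
    """A 6x12 random spectra matrix on a descending grid."""
    grid = np.linspace(200.0, 10.0, 12)
    X = rng.normal(size=(6, 12)) + 5.0
    ids = tuple(f"s{i}" for i in range(6))
    return SpectraMatrix(ids, grid, X)
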