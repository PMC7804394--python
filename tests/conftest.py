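import numpy as np
import pytest

from accessmarks.intervals import Genome
from accessmarks.simulate import SimSpec, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled study conditions for fast end-to-end tests."""
    return SimSpec(
        chrom_sizes={f"Chr{i}": 1_000_000 for i in range(1, 4)},
        n_ths=120,
        n_tfbs=3000,
        n_noise_peaks=20,
        n_extra_genes=40,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return simulate_study(small_spec, seed=7)
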