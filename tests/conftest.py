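import numpy as np
import pytest

from nucleoid3d import ContactMatrix, GenomeBinning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_binning(n_bins, bin_size=5000, circular=True):
    return GenomeBinning(
        genome_length=n_bins * bin_size, bin_size=bin_size, circular=circular
    )


def random_symmetric_matrix(n, rng, low=0.5, high=5.0):
    """Random dense symmetric positive contact matrix on n bins."""
    raw = rng.uniform(low, high, size=(n, n))
    return ContactMatrix(binning=make_binning(n), values=(raw + raw.T) / 2.0)


@pytest.fixture
def make_matrix(rng):
    def _make(n, **kwargs):
        return random_symmetric_matrix(n, rng, **kwargs)

    return _make
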