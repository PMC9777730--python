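import numpy as np
import pytest

from swehist import build_colormap
from swehist.histograms import N_BINS, ChannelHistogramSet


@pytest.fixture(scope="session")
def cmap():
    return build_colormap()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_histset(bin_masses: dict[int, int], n_valid: int | None = None) -> ChannelHistogramSet:
    """Build a histogram set with identical counts in all 3 channels.

    ``bin_masses`` maps 1-based bin index -> count.
    """
    counts = np.zeros((3, N_BINS), dtype=np.int64)
    for k, c in bin_masses.items():
        counts[:, k - 1] = c
    n = int(counts[0].sum()) if n_valid is None else n_valid
    normalized = counts / n if n else np.zeros_like(counts, dtype=float)
    return ChannelHistogramSet(counts=counts, normalized=normalized, n_valid_pixels=n)


@pytest.fixture
def histset_factory():
    return make_histset
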