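import numpy as np
import pytest

from ltrburst.dots import IdentityDistribution


def exact_gaussian_distribution(mu, sigma, amplitude, lo, hi, width):
    """Histogram whose counts are the Gaussian evaluated at bin midpoints."""
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = amplitude * np.exp(-0.5 * ((mids - mu) / sigma) ** 2)
    return IdentityDistribution(bin_edges=edges, counts=counts)


@pytest.fixture
def gaussian_dist_factory():
    return exact_gaussian_distribution
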