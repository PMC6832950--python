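import numpy as np
import pytest

import histoyield as hy


@pytest.fixture(scope="session")
def small_archive():
    """A small but complete synthetic region: 6 counties x 3 years."""
    cfg = hy.SimConfig(n_counties=6, years=(2003, 2004, 2005), seed=7)
    return hy.simulate_region(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_archive):
    ds, report = hy.tensorize_archive(small_archive)
    assert report.n_dropped == 0
    return ds


def brute_force_histogram(pixels, limits, n_bins):
    """Independent oracle: per-pixel loop with explicit bin edges.

    Bins are [edge_i, edge_{i+1}) with the last bin closed; out-of-range
    pixels go to the boundary bins; counts normalized by the pixel count.
    """
    lo, hi = limits
    edges = [lo + (hi - lo) * i / n_bins for i in range(n_bins + 1)]
    counts = [0] * n_bins
    px = [p for p in np.asarray(pixels).ravel() if not np.isnan(p)]
    if not px:
        return np.zeros(n_bins)
    for v in px:
        if v < lo:
            counts[0] += 1
        elif v >= hi:
            counts[n_bins - 1] += 1
        else:
            for b in range(n_bins):
                if edges[b] <= v < edges[b + 1]:
                    counts[b] += 1
                    break
    return np.array(counts, dtype=float) / len(px)
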