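import numpy as np
import pytest

import ctdna_stability as cs


@pytest.fixture(scope="session")
def genome100k():
    return cs.make_genome(100_000)


@pytest.fixture(scope="session")
def onk6():
    return cs.onk6_truth(0.5)


@pytest.fixture(scope="session")
def onk6_segments(onk6):
    return onk6.classified_segments()


@pytest.fixture(scope="session")
def onk6_ratio(onk6, genome100k):
    return cs.expected_bin_ratio(onk6, genome100k)


@pytest.fixture
def small_genome():
    # 2 chromosomes, 16 bins
    return cs.make_genome(100_000, {"1": 1_000_000, "2": 550_000})


def make_profile(counts, chrom="1", bin_size=1000):
    counts = np.asarray(counts, dtype=float)
    start = np.arange(len(counts)) * bin_size
    return cs.BinProfile(np.full(len(counts), chrom, dtype=object),
                         start, start + bin_size, counts)


@pytest.fixture
def flat_profile():
    return make_profile(np.full(100, 50))
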