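import numpy as np
import pytest

from remodelscan import CohortConfig, simulate_cohort
from remodelscan.genomic_signal import GenomicInterval, SignalTrack


@pytest.fixture(scope="session")
def small_cohort():
    """120-site cohort shared by tests that only need realistic inputs."""
    return simulate_cohort(CohortConfig(n_sites=120, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(values, bin_size=10, chrom="chr1", normalized=False):
    return SignalTrack({chrom: np.asarray(values, dtype=float)},
                       bin_size=bin_size, origin="test", normalized=normalized)


@pytest.fixture
def track_factory():
    return make_track


def anchor(summit, chrom="chr1", name="site", halfwidth=150):
    return GenomicInterval(chrom, max(0, summit - halfwidth),
                           summit + halfwidth, name, 0.0, summit)


@pytest.fixture
def anchor_factory():
    return anchor
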