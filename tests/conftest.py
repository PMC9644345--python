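import numpy as np
import pytest

from enhscape.intervals import GenomicInterval, IntervalSet, TSSRecord
from enhscape.simulate import SimulationParams, make_en7_fixture, simulate_study


def random_intervals(rng, n, chroms=("chr1",), span=1_000_000, max_len=2_000):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv_{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A default-parameter noise-free synthetic study, shared read-only."""
    out = tmp_path_factory.mktemp("study")
    return simulate_study(SimulationParams(seed=11), out)


@pytest.fixture(scope="session")
def en7_fixture(tmp_path_factory):
    return make_en7_fixture(tmp_path_factory.mktemp("en7"))
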