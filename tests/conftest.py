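import numpy as np
import pytest

from chirpkit.core import GenomeAssembly
from chirpkit.coverage import CoverageTrack


@pytest.fixture
def assembly() -> GenomeAssembly:
    return GenomeAssembly({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_records(rng, chrom="chr1", size=100_000, n=50, max_len=2_000):
    """Random disjoint (chrom, start, end, value) records."""
    cuts = np.sort(rng.choice(size, size=2 * n, replace=False))
    records = []
    for i in range(n):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if s == e:
            continue
        records.append((chrom, s, e, float(rng.integers(0, 20))))
    return records


def perbase_from_records(records, size):
    """Independent per-base expansion of raw records (oracle helper)."""
    arr = np.zeros(size)
    for _, s, e, v in records:
        arr[s:e] = v
    return arr


@pytest.fixture
def random_track_factory(assembly, rng):
    def make(seed=None, **kwargs):
        local = np.random.default_rng(seed) if seed is not None else rng
        records = random_records(local, **kwargs)
        return CoverageTrack.from_records(assembly, records), records

    return make
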