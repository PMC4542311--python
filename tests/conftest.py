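import numpy as np
import pandas as pd
import pytest

from scmethdyn.methcore import MethylomeSample
from scmethdyn.readproc import ReadRecord


def make_sample(sample_id, calls, **kwargs):
    """Build a MethylomeSample from (chrom, pos, meth, total) tuples."""
    df = pd.DataFrame(calls, columns=["chrom", "pos", "meth_count", "total_count"])
    return MethylomeSample(sample_id=sample_id, calls=df, **kwargs)


def random_sample(rng, sample_id, n=50, chroms=("chr1", "chr2"), max_pos=10_000):
    """A random sparse methylome with binary depth-1 calls."""
    records = set()
    while len(records) < n:
        records.add((chroms[rng.integers(len(chroms))], int(rng.integers(max_pos))))
    calls = [
        (chrom, pos, int(rng.integers(0, 2)), 1) for chrom, pos in sorted(records)
    ]
    return make_sample(sample_id, calls, aligned_reads=int(rng.integers(100, 1000)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def genome_read():
    def _make(start=100, end=200, converted=5, total=6, obs=(), chrom="chr1", source="genome"):
        return ReadRecord(
            chrom=chrom,
            start=start,
            end=end,
            non_cpg_c_total=total,
            non_cpg_c_converted=converted,
            cpg_obs=tuple(obs),
            source=source,
        )

    return _make
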