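import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ribofrag.model import Feature, GenomicInterval, ReadAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_reads(rng, n, contig="chr1", span=(0, 1000), len_range=(15, 40)):
    reads = []
    for _ in range(n):
        length = int(rng.integers(*len_range))
        start = int(rng.integers(span[0], span[1] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(
            ReadAlignment(
                GenomicInterval(contig, start, start + length, strand), length
            )
        )
    return reads


@pytest.fixture
def plus_feature():
    return Feature("feat_plus", GenomicInterval("chr1", 100, 200, "+"), "ncRNA")


@pytest.fixture
def minus_feature():
    return Feature("feat_minus", GenomicInterval("chr1", 100, 200, "-"), "ncRNA")
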