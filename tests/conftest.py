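import numpy as np
import pytest

from endshift import AlignedRead, LocusAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def plus_locus():
    return LocusAnnotation("locA", "chr1", 0, 4000, "+")


@pytest.fixture
def two_loci():
    return [
        LocusAnnotation("locA", "chr1", 0, 1000, "+"),
        LocusAnnotation("locB", "chr1", 800, 2000, "+"),
    ]


def make_read(read_id="r1", chrom="chr1", start=100, end=400, strand="+", **kw):
    return AlignedRead(read_id, chrom, start, end, strand, **kw)


@pytest.fixture
def read_factory():
    return make_read
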