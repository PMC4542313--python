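import numpy as np
import pysam
import pytest

from archseq import ErrorModel, default_panel, load_table2_fixture
from archseq.simulate import sam_header


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def records():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def header(panel):
    return sam_header(panel)


@pytest.fixture()
def clean_err():
    """Noise-free model: no substitution error, every quality passes."""
    return ErrorModel(sub_error_rate=0.0, bq_pass_fraction=1.0, mq_pass_fraction=1.0)


def make_read(
    header: pysam.AlignmentHeader,
    contig: str,
    start: int,  # 1-based
    seq: str,
    bq: int | list[int] = 30,
    mapq: int = 60,
    cigar=None,
    name: str = "r",
) -> pysam.AlignedSegment:
    """Hand-build a single aligned read for filter/pileup tests."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = header.get_tid(contig)
    a.reference_start = start - 1
    a.mapping_quality = mapq
    a.flag = 0
    a.query_sequence = seq
    a.cigartuples = cigar if cigar is not None else [(0, len(seq))]
    quals = [bq] * len(seq) if isinstance(bq, int) else list(bq)
    a.query_qualities = quals
    return a


@pytest.fixture()
def read_factory(header):
    def factory(contig, start, seq, **kw):
        return make_read(header, contig, start, seq, **kw)

    return factory
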