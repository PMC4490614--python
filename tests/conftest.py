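import pytest

from consensv import Locus, Precision, SVCall, SVType


def make_call(
    id="c1",
    caller="Crest",
    source="Illumina HiSeq",
    chrom="chr1",
    start=1000,
    end=1500,
    svtype=SVType.DEL,
    size=None,
    precision=Precision.BREAKPOINT,
):
    if size is None:
        size = max(end - start, 1)
    return SVCall(
        id=id,
        caller=caller,
        source=source,
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        size=size,
        precision=precision,
    )


def make_locus(
    id="L1",
    chrom="chr1",
    start=1000,
    end=1500,
    svtype=SVType.DEL,
    size=None,
    sources=("Illumina HiSeq",),
    callers=("Crest",),
    members=("c1",),
    bitflag=0,
):
    if size is None:
        size = max(end - start, 1)
    return Locus(
        id=id,
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        size=size,
        members=tuple(members),
        sources=frozenset(sources),
        callers=frozenset(callers),
        bitflag=bitflag,
    )


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture
def locus_factory():
    return make_locus
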