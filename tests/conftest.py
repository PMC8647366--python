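import numpy as np
import pytest

from scampi.genemodel import ExonInterval, GeneModel
from scampi.alignments import AlignedRead

_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}


def parse_cigar(cigar: str) -> tuple[tuple[int, int], ...]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((_OPS[ch], int(num)))
            num = ""
    return tuple(out)


def make_read(
    cigar: str,
    ref_start: int = 0,
    seq: str | None = None,
    chrom: str = "chr1",
    strand: str = "+",
    read_id: str = "r1",
) -> AlignedRead:
    """Hand-construct an AlignedRead from a CIGAR string for unit tests."""
    tuples = parse_cigar(cigar)
    qlen = sum(ln for op, ln in tuples if op in (0, 1, 4, 7, 8))
    if seq is None:
        seq = "A" * qlen
    assert len(seq) == qlen, f"need {qlen} query bases, got {len(seq)}"
    left_s = right_s = left_h = right_h = 0
    seen_aligned = False
    for op, ln in tuples:
        if op == 4:
            if seen_aligned:
                right_s = ln
            else:
                left_s = ln
        elif op == 5:
            if seen_aligned:
                right_h = ln
            else:
                left_h = ln
        else:
            seen_aligned = True
    blocks = []
    rpos = ref_start
    for op, ln in tuples:
        if op in (0, 7, 8):
            if blocks and blocks[-1][1] == rpos:
                blocks[-1] = (blocks[-1][0], rpos + ln)
            else:
                blocks.append((rpos, rpos + ln))
            rpos += ln
        elif op in (2, 3):
            rpos += ln
    return AlignedRead(
        read_id=read_id,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=rpos,
        mapped_strand=strand,
        query_seq=seq,
        cigartuples=tuples,
        left_clip_len=left_s,
        right_clip_len=right_s,
        left_hard_clip=left_h,
        right_hard_clip=right_h,
        blocks=blocks,
    )


@pytest.fixture
def toy_gene():
    """8-exon plus-strand gene with 100-bp exons spaced 100 bp apart."""
    exons = tuple(
        ExonInterval(index=i + 1, chrom="chr1", start=200 * i, end=200 * i + 100)
        for i in range(8)
    )
    return GeneModel(
        name="TOY8", chrom="chr1", strand="+", exons=exons,
        anchor_first=1, anchor_last=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
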