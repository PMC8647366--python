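import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_read
from scampi._util import revcomp
from scampi.alignments import (
    extract_search_sequence,
    read_alignments,
    window_bases,
)
from scampi.genemodel import AnalysisWindow


def _write_sam(path, records, chrom="chr1", length=10000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, pos, cigar, seq in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = -1 if flag & 4 else 0
            a.reference_start = -1 if flag & 4 else pos
            a.mapping_quality = 0 if flag & 4 else 60
            if not flag & 4:
                a.cigarstring = cigar
            a.query_sequence = seq
            out.write(a)


class TestReadAlignments:
    def test_primary_only_with_skip_counts(self, tmp_path):
        sam = tmp_path / "t.sam"
        _write_sam(
            sam,
            [
                ("r1", 0, 100, "50M", "A" * 50),
                ("r2", 0, 150, "50M", "C" * 50),
                ("r3", 256, 200, "50M", "G" * 50),  # secondary
                ("r4", 0, 250, "50M", "T" * 50),
                ("r5", 2048, 300, "50M", "T" * 50),  # supplementary
            ],
        )
        counts = {}
        reads = list(read_alignments(sam, counts=counts))
        assert [r.read_id for r in reads] == ["r1", "r2", "r4"]
        assert counts["secondary"] == 1 and counts["supplementary"] == 1

    def test_clip_lengths_and_single_block(self, tmp_path):
        sam = tmp_path / "t.sam"
        _write_sam(sam, [("r1", 0, 500, "25S100M10S", "A" * 135)])
        (read,) = read_alignments(sam)
        assert (read.left_clip_len, read.right_clip_len) == (25, 10)
        assert read.blocks == [(500, 600)]

    def test_deletion_consumes_reference_and_splits_blocks(self, tmp_path):
        sam = tmp_path / "t.sam"
        _write_sam(sam, [("r1", 0, 100, "10M2D10M", "A" * 20)])
        (read,) = read_alignments(sam)
        assert read.blocks == [(100, 110), (112, 122)]

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "nope.sam"
        with pytest.raises((OSError, ValueError)):
            list(read_alignments(bad))


class TestSearchSequence:
    def test_plus_strand_gene_returns_left_clip_verbatim(self, toy_gene):
        clip = "ACGTACGTACGTACGTACGTACGT"
        read = make_read("24S30M", ref_start=0, seq=clip + "A" * 30)
        s = extract_search_sequence(read, toy_gene)
        assert s.seq == clip and s.origin == "left_clip"

    def test_minus_strand_gene_returns_revcomp_of_right_clip(self, toy_gene):
        from dataclasses import replace

        minus_gene = replace(
            toy_gene,
            strand="-",
            exons=tuple(
                type(e)(index=len(toy_gene.exons) - e.index + 1, chrom=e.chrom,
                        start=e.start, end=e.end)
                for e in toy_gene.exons
            )[::-1],
        )
        read = make_read("30M4S", seq="A" * 30 + "AAAC", strand="-")
        s = extract_search_sequence(read, minus_gene)
        assert s.seq == "GTTT" and s.origin == "right_clip_revcomp"

    def test_read_without_clips_yields_empty_sequence(self, toy_gene):
        read = make_read("30M")
        s = extract_search_sequence(read, toy_gene)
        assert s.seq == ""

    def test_wrong_orientation_read_is_excluded(self, toy_gene):
        read = make_read("24S30M", seq="A" * 54, strand="-")
        assert extract_search_sequence(read, toy_gene) is None

    def test_hard_clipped_barcode_side_is_excluded(self, toy_gene):
        read = make_read("20H30M", seq="A" * 30)
        assert extract_search_sequence(read, toy_gene) is None


class TestWindowBases:
    WINDOW = AnalysisWindow(chrom="chr1", start=48, end=52)

    def test_perfect_match_reproduces_reference_window(self):
        seq = "ACGT" * 25
        read = make_read("100M", ref_start=0, seq=seq)
        obs = window_bases(read, self.WINDOW)
        assert obs.covered and obs.spans and not obs.has_deletion
        assert obs.obs_seq == seq[48:52]

    def test_deletion_spanning_window_flagged(self):
        # 40M then 20D covering [40,60) then 40M
        read = make_read("40M20D40M", ref_start=0, seq="A" * 80)
        obs = window_bases(read, self.WINDOW)
        assert obs.has_deletion and not obs.covered

    def test_central_insertion_lengthens_observation(self):
        # insertion anchored at position 50, the middle of the 4-bp window
        seq = "A" * 50 + "G" + "A" * 50
        read = make_read("50M1I50M", ref_start=0, seq=seq)
        obs = window_bases(read, self.WINDOW)
        assert obs.covered and obs.n_insertions == 1
        assert len(obs.obs_seq) == 5
        assert obs.obs_seq == "AAGAA"

    def test_boundary_insertions_count_as_inside(self):
        for cut in (48, 52):  # anchors exactly on window start / end
            read = make_read(f"{cut}M1I{100 - cut}M", ref_start=0, seq="A" * 101)
            obs = window_bases(read, self.WINDOW)
            assert obs.n_insertions == 1, f"anchor {cut}"
        read = make_read("53M1I47M", ref_start=0, seq="A" * 101)
        assert window_bases(read, self.WINDOW).n_insertions == 0

    def test_read_stopping_short_of_window_is_uncovered(self):
        read = make_read("47M", ref_start=0, seq="A" * 47)
        obs = window_bases(read, self.WINDOW)
        assert not obs.covered and not obs.spans and not obs.has_deletion

    def test_read_on_other_chromosome_is_uncovered(self):
        read = make_read("100M", ref_start=0, seq="A" * 100, chrom="chr2")
        obs = window_bases(read, self.WINDOW)
        assert not obs.covered and obs.obs_seq == ""


@settings(deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", max_size=60))
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**32 - 1))
def test_cigar_partitions_query_exactly(seed):
    """Soft clips + insertions + matches always account for every query base."""
    import numpy as np

    rng = np.random.default_rng(seed)
    parts, q = [], 0
    left = int(rng.integers(0, 30))
    if left:
        parts.append(f"{left}S")
        q += left
    for _ in range(int(rng.integers(1, 5))):
        m = int(rng.integers(1, 50))
        parts.append(f"{m}M")
        q += m
        op = rng.choice(["I", "D", "N", ""])
        if op:
            ln = int(rng.integers(1, 10))
            parts.append(f"{ln}{op}")
            if op == "I":
                q += ln
    read = make_read("".join(parts), seq="A" * q)
    covered = read.left_clip_len + read.right_clip_len + sum(
        1 for qp, _, op in read.aligned_pairs if op in ("M", "I")
    )
    assert covered == len(read.query_seq)
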