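"""SAM/BAM access for targeted long reads.

Nanopore reads of amplified cDNA carry the 10x 5' construct
(adapter + 16-bp cell barcode + 10-bp UMI) ahead of the cDNA. That prefix
does not align to the genome and therefore survives as a soft clip at one
end of the alignment. This module wraps pysam records into a light
:class:`AlignedRead` that exposes exactly what downstream steps need:

* soft-clip segments (barcode search material),
* gapless reference blocks (exon-pattern calling),
* per-base aligned pairs (cut-site window genotyping).

Reads from a minus-strand gene align reverse-complemented, so their
construct prefix becomes the *right* soft clip and must be
reverse-complemented before barcode matching; this strand-aware extraction
lives in :func:`extract_search_sequence`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator

import pysam

from ._util import revcomp
from .genemodel import AnalysisWindow, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "SearchSequence",
    "WindowObservation",
    "read_alignments",
    "extract_search_sequence",
    "window_bases",
]

# CIGAR op codes (SAM spec order)
_CIGAR_M = {0, 7, 8}  # M, =, X — consume query and reference
_CIGAR_I = 1
_CIGAR_D = 2
_CIGAR_N = 3
_CIGAR_S = 4
_CIGAR_H = 5


@dataclass
class AlignedRead:
    """One primary alignment, decomposed for downstream analysis.

    ``blocks`` are the gapless reference intervals consumed by match ops
    (split at both deletions and reference skips). ``aligned_pairs`` is a
    per-base list of ``(query_pos, ref_pos, op)`` with op in {"M","I","D"};
    reference skips (introns) contribute no pairs.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    mapped_strand: str
    query_seq: str
    cigartuples: tuple[tuple[int, int], ...]
    left_clip_len: int = 0
    right_clip_len: int = 0
    left_hard_clip: int = 0
    right_hard_clip: int = 0
    blocks: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        cig = tuple(aln.cigartuples or ())
        left_s = right_s = left_h = right_h = 0
        # clips may only appear at the ends (optionally behind a hard clip);
        # a clip is "left" iff no alignment op has been seen yet
        seen_aligned = False
        for op, ln in cig:
            if op == _CIGAR_S:
                if seen_aligned:
                    right_s = ln
                else:
                    left_s = ln
            elif op == _CIGAR_H:
                if seen_aligned:
                    right_h = ln
                else:
                    left_h = ln
            else:
                seen_aligned = True
        blocks: list[tuple[int, int]] = []
        rpos = aln.reference_start
        for op, ln in cig:
            if op in _CIGAR_M:
                if blocks and blocks[-1][1] == rpos:
                    blocks[-1] = (blocks[-1][0], rpos + ln)
                else:
                    blocks.append((rpos, rpos + ln))
                rpos += ln
            elif op in (_CIGAR_D, _CIGAR_N):
                rpos += ln
        read = cls(
            read_id=aln.query_name,
            chrom=aln.reference_name,
            ref_start=aln.reference_start,
            ref_end=rpos,
            mapped_strand="-" if aln.is_reverse else "+",
            query_seq=aln.query_sequence or "",
            cigartuples=cig,
            left_clip_len=left_s,
            right_clip_len=right_s,
            left_hard_clip=left_h,
            right_hard_clip=right_h,
            blocks=blocks,
        )
        read._check_query_partition()
        return read

    def _check_query_partition(self) -> None:
        """Clips + insertions + matches must partition the stored query."""
        consumed = sum(
            ln for op, ln in self.cigartuples if op in _CIGAR_M or op == _CIGAR_I or op == _CIGAR_S
        )
        if self.query_seq and consumed != len(self.query_seq):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {consumed} query bases but "
                f"sequence has {len(self.query_seq)}"
            )

    @cached_property
    def aligned_pairs(self) -> list[tuple[int | None, int | None, str]]:
        pairs: list[tuple[int | None, int | None, str]] = []
        qpos, rpos = 0, self.ref_start
        for op, ln in self.cigartuples:
            if op in _CIGAR_M:
                pairs.extend((qpos + j, rpos + j, "M") for j in range(ln))
                qpos += ln
                rpos += ln
            elif op == _CIGAR_I:
                pairs.extend((qpos + j, None, "I") for j in range(ln))
                qpos += ln
            elif op == _CIGAR_D:
                pairs.extend((None, rpos + j, "D") for j in range(ln))
                rpos += ln
            elif op == _CIGAR_N:
                rpos += ln
            elif op == _CIGAR_S:
                qpos += ln
        return pairs

    @property
    def left_clip_seq(self) -> str:
        return self.query_seq[: self.left_clip_len]

    @property
    def right_clip_seq(self) -> str:
        if self.right_clip_len == 0:
            return ""
        return self.query_seq[-self.right_clip_len :]


@dataclass(frozen=True)
class SearchSequence:
    """Barcode-bearing sequence oriented adapter -> barcode -> UMI."""

    read_id: str
    seq: str
    origin: str  # "left_clip" or "right_clip_revcomp"


@dataclass(frozen=True)
class WindowObservation:
    """What a read shows inside a cut-site analysis window.

    ``covered``: every reference position of the window is matched to a query
    base. ``obs_seq``: the query bases aligned within the window, with
    insertion bases interleaved in alignment order (an insertion anchored on
    either window boundary counts as inside). ``has_deletion``: a deletion op
    consumed at least one window position. ``spans``: the aligned portion of
    the read extends across the whole window.
    """

    read_id: str
    covered: bool
    spans: bool
    obs_seq: str
    has_deletion: bool
    n_insertions: int


def read_alignments(
    path: str | Path,
    region: str | None = None,
    *,
    counts: dict[str, int] | None = None,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped; the skip
    counts are logged (and accumulated into ``counts`` when provided). For a
    ``region`` on an unindexed SAM, falls back to a full scan with an
    overlap filter.
    """
    stats = counts if counts is not None else {}
    for key in ("primary", "unmapped", "secondary", "supplementary"):
        stats.setdefault(key, 0)
    with pysam.AlignmentFile(str(path), require_index=False) as fh:
        if region is not None:
            try:
                iterator = fh.fetch(region=region)
            except ValueError:
                chrom, _, span = region.partition(":")
                lo, hi = 0, float("inf")
                if span:
                    a, _, b = span.partition("-")
                    lo, hi = int(a) - 1, int(b)
                iterator = (
                    a
                    for a in fh.fetch(until_eof=True)
                    if not a.is_unmapped
                    and a.reference_name == chrom
                    and a.reference_start < hi
                    and a.reference_end > lo
                )
        else:
            iterator = fh.fetch(until_eof=True)
        for aln in iterator:
            if aln.is_unmapped:
                stats["unmapped"] += 1
                continue
            if aln.is_secondary:
                stats["secondary"] += 1
                continue
            if aln.is_supplementary:
                stats["supplementary"] += 1
                continue
            stats["primary"] += 1
            yield AlignedRead.from_pysam(aln)
    skipped = stats["unmapped"] + stats["secondary"] + stats["supplementary"]
    if skipped:
        logger.info(
            "read_alignments(%s): %d primary, skipped %d unmapped / %d secondary / %d supplementary",
            path,
            stats["primary"],
            stats["unmapped"],
            stats["secondary"],
            stats["supplementary"],
        )


def extract_search_sequence(
    read: AlignedRead, gene: GeneModel
) -> SearchSequence | None:
    """Strand-aware barcode search sequence for one read.

    For a plus-strand gene the construct prefix is the left soft clip,
    returned verbatim; for a minus-strand gene it is the reverse complement
    of the right soft clip. Returns None for reads aligned in the unexpected
    orientation or whose barcode-side clip was hard-clipped (the sequence is
    simply not in the record); callers count and exclude these. An empty
    clip yields an empty SearchSequence, which downstream matching treats as
    unmatchable.
    """
    if read.mapped_strand != gene.strand:
        return None
    if gene.strand == "+":
        if read.left_hard_clip:
            return None
        return SearchSequence(read.read_id, read.left_clip_seq, "left_clip")
    if read.right_hard_clip:
        return None
    return SearchSequence(read.read_id, revcomp(read.right_clip_seq), "right_clip_revcomp")


def window_bases(
    read: AlignedRead, window: AnalysisWindow, ref_seq: str | None = None
) -> WindowObservation:
    """Collect the aligned bases a read places inside an analysis window.

    Insertions are attributed to the inter-base reference position they are
    anchored at (the next aligned reference position); anchors equal to
    either window boundary count as inside, which favors sensitivity to
    cut-site indels. ``ref_seq`` is accepted for interface symmetry but the
    observation itself is reference-free.
    """
    start, end = window.start, window.end
    if read.chrom != window.chrom or read.ref_end <= start or read.ref_start >= end:
        return WindowObservation(read.read_id, False, False, "", False, 0)

    pairs = read.aligned_pairs
    # precompute, for each pair index, the next reference position at/after it
    next_ref = [0] * (len(pairs) + 1)
    next_ref[len(pairs)] = read.ref_end
    for i in range(len(pairs) - 1, -1, -1):
        rp = pairs[i][1]
        next_ref[i] = rp if rp is not None else next_ref[i + 1]

    chars: list[str] = []
    matched_positions: set[int] = set()
    has_deletion = False
    n_ins = 0
    for i, (qpos, rpos, op) in enumerate(pairs):
        if op == "M":
            if start <= rpos < end:
                matched_positions.add(rpos)
                chars.append(read.query_seq[qpos])
        elif op == "D":
            if start <= rpos < end:
                has_deletion = True
        else:  # insertion: anchored at the next aligned reference position
            anchor = next_ref[i + 1]
            if start <= anchor <= end:
                n_ins += 1
                chars.append(read.query_seq[qpos])
    covered = len(matched_positions) == end - start
    spans = read.ref_start <= start and read.ref_end >= end
    return WindowObservation(
        read_id=read.read_id,
        covered=covered,
        spans=spans,
        obs_seq="".join(chars),
        has_deletion=has_deletion,
        n_insertions=n_ins,
    )
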