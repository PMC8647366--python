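"""Fully synthetic targeted single-cell long-read experiments.

The generator emulates the data this pipeline consumes in the wet lab:

* a whitelist of 16-bp droplet barcodes (optionally with a minimum pairwise
  edit distance, for matcher stress tests),
* a toy multi-exon target gene embedded in a synthetic reference, sized so
  the full-length cDNA lands on the ~1.1 kb amplicon scale of real targeted
  libraries,
* per-cell molecules following a 10x 5' read structure
  (22-nt partial read-1 adapter + 16-bp barcode + 10-bp UMI + TSO-like
  spacer + cDNA built by concatenating the retained exons),
* CRISPR indels injected at a guide's cut site with a configurable per-read
  probability,
* i.i.d. per-base substitution/insertion/deletion errors at nanopore-like
  rates (defaults 0.03/0.02/0.02),
* alignments written as SAM with truth-aware CIGARs (soft-clipped
  construct, exon match blocks separated by reference skips, errors folded
  in as M/I/D), plus per-read truth tables, a guide-assignment TSV and a
  negative-binomial expression matrix in MTX triplet form.

Every source of randomness flows from the single config seed; identical
configs produce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import sparse
from scipy.io import mmwrite

from ._util import revcomp
from .barcode_match import BarcodeWhitelist, edit_distance
from .genemodel import (
    ExonInterval,
    GeneModel,
    GuideTarget,
    cut_site,
    write_gene_model,
    write_guides,
)
from .isoform_call import parse_label

logger = logging.getLogger(__name__)

__all__ = [
    "PARTIAL_R1",
    "TSO_SPACER",
    "CellGroup",
    "SimConfig",
    "SimBundle",
    "simulate_whitelist",
    "make_toy_gene",
    "make_toy_guide",
    "apply_errors",
    "simulate_molecule",
    "simulate_expression",
    "emit_sam",
    "simulate_experiment",
]

# 10x 5' partial read-1 primer: the adapter ahead of the cell barcode.
PARTIAL_R1 = "CTACACGACGCTCTTCCGATCT"
# TSO-like spacer between the UMI and the cDNA body.
TSO_SPACER = "TTTCTTATATGGG"

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_whitelist(
    n: int,
    seed: int | None = None,
    min_pairwise_dist: int = 0,
    rng: np.random.Generator | None = None,
    max_attempts_per_barcode: int = 2000,
) -> BarcodeWhitelist:
    """Draw ``n`` distinct random 16-mers, optionally enforcing a minimum
    pairwise edit distance by greedy rejection sampling."""
    if n < 1:
        raise ValueError("whitelist size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n:
        for _ in range(max_attempts_per_barcode):
            cand = _random_seq(rng, 16)
            if cand in seen:
                continue
            if min_pairwise_dist > 0 and any(
                edit_distance(cand, bc) < min_pairwise_dist for bc in barcodes
            ):
                continue
            barcodes.append(cand)
            seen.add(cand)
            break
        else:
            raise RuntimeError(
                f"could not extend whitelist to {n} barcodes at min pairwise "
                f"distance {min_pairwise_dist}"
            )
    return BarcodeWhitelist(barcodes=tuple(barcodes), source="<simulated>")


def make_toy_gene(
    rng: np.random.Generator,
    n_exons: int = 8,
    strand: str = "+",
    exon_len: tuple[int, int] = (120, 161),
    intron_len: tuple[int, int] = (200, 401),
    pad: int = 300,
    name: str = "GENE1",
    chrom: str = "synth1",
) -> tuple[GeneModel, str]:
    """Build a random multi-exon gene and its reference chromosome.

    Default sizes put the full-length cDNA near 1.1 kb, the amplicon scale
    of the targeted libraries this pipeline is meant for.
    """
    intervals = []
    pos = pad
    for _ in range(n_exons):
        ln = int(rng.integers(*exon_len))
        intervals.append((chrom, pos, pos + ln))
        pos += ln + int(rng.integers(*intron_len))
    ref_len = pos + pad
    ref = _random_seq(rng, ref_len)
    genomic = intervals if strand == "+" else intervals[::-1]
    exons = tuple(
        ExonInterval(index=i + 1, chrom=c, start=s, end=e)
        for i, (c, s, e) in enumerate(genomic)
    )
    gene = GeneModel(
        name=name,
        chrom=chrom,
        strand=strand,
        exons=exons,
        anchor_first=1,
        anchor_last=n_exons,
    )
    return gene, ref


def make_toy_guide(
    gene: GeneModel,
    ref: str,
    exon_ordinal: int = 4,
    name: str | None = None,
) -> GuideTarget:
    """Define a plus-strand guide whose cut site is the middle of an exon.

    The protospacer is lifted from the reference so that simulated edits
    fall at a genotypeable position covered by full-length molecules.
    """
    exon = gene.exon(exon_ordinal)
    cut = (exon.start + exon.end) // 2
    pam_start = cut + 3
    return GuideTarget(
        name=name or f"{gene.name}_ex{exon_ordinal}",
        gene=gene.name,
        chrom=gene.chrom,
        protospacer=ref[pam_start - 20 : pam_start],
        protospacer_strand="+",
        pam_start=pam_start,
    )


@dataclass(frozen=True)
class CellGroup:
    """One simulated subpopulation: isoform mixture plus optional edit spec."""

    name: str
    fraction: float
    mixture: dict[str, float]  # pattern label -> probability, sums to 1
    guide: str | None = None
    mut_prob: float = 0.0


def _default_groups() -> list[CellGroup]:
    """Two-arm design mirroring a splice-site editing experiment: an edited
    arm with predominant exon-5 skipping and frequent cut-site indels, and
    an unedited arm expressing mostly full-length transcripts."""
    full = "12345678"
    skip5 = "1234-678"
    return [
        CellGroup(
            name="edited",
            fraction=0.5,
            mixture={skip5: 0.8, full: 0.2},
            guide="GENE1_ex4",
            mut_prob=0.64,
        ),
        CellGroup(
            name="unedited",
            fraction=0.5,
            mixture={full: 0.95, skip5: 0.05},
            guide="nontarget-1",
            mut_prob=0.0,
        ),
    ]


@dataclass
class SimConfig:
    """All knobs of a simulated experiment; defaults are the study conditions.

    Error rates are i.i.d. per base. ``indel_sizes`` maps signed sizes
    (negative = deletion) to probabilities for CRISPR edits at the cut site.
    Expression counts are negative binomial with per-gene dispersion; the
    target gene is highly expressed and ``expr_fold`` raises it in
    ``expr_high_group`` cells (mirroring the higher target expression seen
    in unedited cells).
    """

    seed: int = 0
    n_cells: int = 100
    whitelist_size: int = 500
    min_whitelist_dist: int = 0
    adapter: str = PARTIAL_R1
    spacer: str = TSO_SPACER
    umi_len: int = 10
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    mean_molecules_per_cell: float = 20.0
    duplicate_rate: float = 0.05
    groups: list[CellGroup] = field(default_factory=_default_groups)
    indel_sizes: dict[int, float] = field(
        default_factory=lambda: {-3: 0.2, -2: 0.25, -1: 0.2, 1: 0.25, 2: 0.1}
    )
    gene_strand: str = "+"
    n_exons: int = 8
    guide_exon: int = 4
    # expression matrix
    n_expr_genes: int = 200
    expr_mean: float = 5.0
    expr_mean_target: float = 50.0
    expr_dispersion: float = 0.1
    expr_fold: float = 1.5
    expr_high_group: str = "unedited"

    def __post_init__(self) -> None:
        for g in self.groups:
            total = sum(g.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {g.name}: mixture sums to {total}, not 1")
            if not 0.0 <= g.mut_prob <= 1.0:
                raise ValueError(f"group {g.name}: mut_prob outside [0,1]")
        for r in (self.sub_rate, self.ins_rate, self.del_rate, self.duplicate_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        if abs(sum(g.fraction for g in self.groups) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")


def apply_errors(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> str:
    """Corrupt a sequence with i.i.d. per-base errors.

    Per base: deletion with ``del_rate``; otherwise an insertion of one
    random base before it with ``ins_rate``; otherwise substitution to one
    of the three other bases with ``sub_rate``. A final insertion may follow
    the last base.
    """
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < del_rate:
            continue
        if rng.random() < ins_rate:
            out.append(_BASES[rng.integers(0, 4)])
        if r < del_rate + sub_rate:
            others = [b for b in "ACGT" if b != ch]
            out.append(others[rng.integers(0, 3)])
        else:
            out.append(ch)
    if seq and rng.random() < ins_rate:
        out.append(_BASES[rng.integers(0, 4)])
    return "".join(out)


@dataclass
class SimRead:
    """One emitted read plus its truth row."""

    read_id: str
    barcode: str
    umi: str
    group: str
    guide: str | None
    pattern: str
    status: str  # WT / MUT
    bc_offset: int  # offset of the (corrupted) barcode within the search prefix
    is_duplicate: bool
    # SAM fields (genomic orientation)
    ref_start: int
    cigar: list[tuple[int, int]]
    seq: str
    flag: int


# CIGAR op codes
_M, _I, _D, _N, _S = 0, 1, 2, 3, 4


def _build_events(
    gene: GeneModel,
    ref: str,
    present: frozenset[int],
    edit: tuple[int, int] | None,  # (cut position, signed size) or None
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> list[tuple[int, int | None, str]]:
    """Per-base alignment events (op, ref_pos, base) for one molecule,
    genomic orientation, with the CRISPR edit and sequencing errors folded in."""
    events: list[tuple[int, int | None, str]] = []
    exons = sorted((gene.exon(i) for i in present), key=lambda e: e.start)
    for exon in exons:
        for p in range(exon.start, exon.end):
            events.append((_M, p, ref[p]))
    if edit is not None:
        cut, size = edit
        if size < 0:  # deletion of |size| bases right of the cut
            dropped = set(range(cut, cut - size))
            events = [
                (_D, rp, "") if op == _M and rp in dropped else (op, rp, b)
                for op, rp, b in events
            ]
        else:  # insertion of `size` random bases at the cut
            ins = [(_I, None, _BASES[rng.integers(0, 4)]) for _ in range(size)]
            idx = next(
                (i for i, (op, rp, _) in enumerate(events) if op == _M and rp == cut),
                len(events),
            )
            events = events[:idx] + ins + events[idx:]
    if sub_rate + ins_rate + del_rate > 0:
        corrupted: list[tuple[int, int | None, str]] = []
        for op, rp, b in events:
            if op != _M:
                corrupted.append((op, rp, b))
                continue
            r = rng.random()
            if r < del_rate:
                corrupted.append((_D, rp, ""))
                continue
            if rng.random() < ins_rate:
                corrupted.append((_I, None, _BASES[rng.integers(0, 4)]))
            if r < del_rate + sub_rate:
                others = [x for x in "ACGT" if x != b]
                corrupted.append((_M, rp, others[rng.integers(0, 3)]))
            else:
                corrupted.append((_M, rp, b))
        events = corrupted
    return events


def _events_to_alignment(
    events: list[tuple[int, int | None, str]],
) -> tuple[int, list[tuple[int, int]], str, str, str]:
    """Compress per-base events to (ref_start, cigar runs, aligned seq,
    leading unaligned bases, trailing unaligned bases)."""
    # strip leading/trailing deletions; detach boundary insertions into clips
    while events and events[0][0] == _D:
        events.pop(0)
    while events and events[-1][0] == _D:
        events.pop()
    lead = []
    while events and events[0][0] == _I:
        lead.append(events.pop(0)[2])
    tail = []
    while events and events[-1][0] == _I:
        tail.append(events.pop()[2])
    tail.reverse()
    if not events:
        raise ValueError("molecule has no aligned bases")
    ref_start = events[0][1]
    runs: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    prev_ref: int | None = None
    for op, rp, b in events:
        if op in (_M, _D) and prev_ref is not None and rp > prev_ref:
            runs.append((_N, rp - prev_ref))
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
        if op in (_M, _I):
            seq_parts.append(b)
        if op in (_M, _D):
            prev_ref = rp + 1
    return ref_start, runs, "".join(seq_parts), "".join(lead), "".join(tail)


def simulate_molecule(
    read_id: str,
    barcode: str,
    group: CellGroup,
    gene: GeneModel,
    ref: str,
    config: SimConfig,
    rng: np.random.Generator,
    guide_cut: int | None,
    *,
    fixed_umi: str | None = None,
    fixed_pattern: str | None = None,
    fixed_status: str | None = None,
    is_duplicate: bool = False,
) -> SimRead:
    """Simulate one molecule end-to-end: pattern draw, optional cut-site
    indel, construct prefix, sequencing errors, and the SAM representation.

    ``fixed_*`` pin the molecule-level truth (used to emit PCR duplicates of
    an earlier molecule with independent sequencing errors).
    """
    if fixed_pattern is None:
        labels = sorted(group.mixture)
        probs = np.array([group.mixture[l] for l in labels])
        pattern = labels[rng.choice(len(labels), p=probs)]
    else:
        pattern = fixed_pattern
    present = parse_label(pattern)
    umi = fixed_umi if fixed_umi is not None else _random_seq(rng, config.umi_len)

    if fixed_status is None:
        mutate = (
            guide_cut is not None
            and group.mut_prob > 0
            and rng.random() < group.mut_prob
        )
    else:
        mutate = fixed_status == "MUT"
    edit = None
    status = "WT"
    if mutate and guide_cut is not None:
        # apply the indel only when the cut falls strictly inside a retained exon
        ordinal = gene.exon_of_position(guide_cut)
        if ordinal in present:
            sizes = sorted(config.indel_sizes)
            p = np.array([config.indel_sizes[s] for s in sizes])
            size = sizes[rng.choice(len(sizes), p=p / p.sum())]
            edit = (guide_cut, size)
            status = "MUT"

    events = _build_events(
        gene, ref, present, edit, rng, config.sub_rate, config.ins_rate, config.del_rate
    )
    ref_start, runs, aligned_seq, lead, tail = _events_to_alignment(events)

    adapter_c = apply_errors(config.adapter, config.sub_rate, config.ins_rate, config.del_rate, rng)
    bc_c = apply_errors(barcode, config.sub_rate, config.ins_rate, config.del_rate, rng)
    umi_c = apply_errors(umi, config.sub_rate, config.ins_rate, config.del_rate, rng)
    spacer_c = apply_errors(config.spacer, config.sub_rate, config.ins_rate, config.del_rate, rng)
    prefix = adapter_c + bc_c + umi_c + spacer_c

    if gene.strand == "+":
        left = prefix + lead
        right = tail
        seq = left + aligned_seq + right
        cigar = [(_S, len(left))] + runs + ([(_S, len(right))] if right else [])
        flag = 0
    else:
        left = lead
        right = tail + revcomp(prefix)
        seq = left + aligned_seq + right
        cigar = ([(_S, len(left))] if left else []) + runs + [(_S, len(right))]
        flag = 16
    return SimRead(
        read_id=read_id,
        barcode=barcode,
        umi=umi,
        group=group.name,
        guide=group.guide,
        pattern=pattern,
        status=status,
        bc_offset=len(adapter_c),
        is_duplicate=is_duplicate,
        ref_start=ref_start,
        cigar=cigar,
        seq=seq,
        flag=flag,
    )


def emit_sam(
    reads: Sequence[SimRead],
    gene: GeneModel,
    ref: str,
    sam_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write simulated reads as a coordinate-sorted SAM plus a truth TSV."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": gene.chrom, "LN": len(ref)}],
    }
    ordered = sorted(reads, key=lambda r: (r.ref_start, r.read_id))
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = r.flag
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigartuples = r.cigar
            a.query_sequence = r.seq
            out.write(a)
    if truth_path is not None:
        truth_frame(reads).to_csv(truth_path, sep="\t", index=False)


def truth_frame(reads: Sequence[SimRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "barcode": r.barcode,
                "umi": r.umi,
                "bc_offset": r.bc_offset,
                "pattern": r.pattern,
                "status": r.status,
                "guide": r.guide,
                "group": r.group,
                "is_duplicate": r.is_duplicate,
            }
            for r in sorted(reads, key=lambda r: r.read_id)
        ]
    )


@dataclass
class SimBundle:
    """A written dataset plus in-memory handles for tests and examples."""

    out_dir: Path
    sam: Path
    ref_fasta: Path
    whitelist_path: Path
    gene_config: Path
    guide_table: Path
    truth_reads: Path
    cells_table: Path
    guide_assignments: Path
    expr_dir: Path
    config_json: Path
    gene: GeneModel
    ref: str
    whitelist: BarcodeWhitelist
    guides: list[GuideTarget]
    reads: list[SimRead]
    cells: pd.DataFrame  # barcode, group, guide


def _simulate_cells(
    config: SimConfig, whitelist: BarcodeWhitelist, rng: np.random.Generator
) -> pd.DataFrame:
    barcodes = [
        whitelist.barcodes[i]
        for i in rng.choice(len(whitelist), size=config.n_cells, replace=False)
    ]
    counts = np.floor(
        np.cumsum([g.fraction for g in config.groups]) * config.n_cells + 0.5
    ).astype(int)
    group_of = []
    start = 0
    for g, stop in zip(config.groups, counts):
        group_of.extend([g.name] * (stop - start))
        start = stop
    group_of = group_of[: config.n_cells]
    rng.shuffle(group_of)
    by_name = {g.name: g for g in config.groups}
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "group": group_of,
            "guide": [by_name[g].guide for g in group_of],
        }
    )


def simulate_expression(
    config: SimConfig,
    gene: GeneModel,
    cells: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[sparse.csr_matrix, list[str]]:
    genes = [gene.name] + [f"G{i:04d}" for i in range(1, config.n_expr_genes)]
    mu = np.full(len(genes), config.expr_mean, dtype=float)
    mu[0] = config.expr_mean_target
    disp = config.expr_dispersion
    n_cells = len(cells)
    mat = np.empty((len(genes), n_cells), dtype=np.int64)
    high = (cells["group"] == config.expr_high_group).to_numpy()
    for gi, m in enumerate(mu):
        cell_mu = np.full(n_cells, m)
        if gi == 0:
            cell_mu = np.where(high, m * config.expr_fold, m)
        if disp > 0:
            r = 1.0 / disp
            mat[gi] = rng.negative_binomial(r, r / (r + cell_mu))
        else:
            mat[gi] = rng.poisson(cell_mu)
    return sparse.csr_matrix(mat), genes


def simulate_experiment(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate and write a complete synthetic dataset bundle.

    Produces reference FASTA, coordinate-sorted SAM, whitelist, gene-model
    and guide configs, read/cell truth tables, a guide-assignment TSV and an
    MTX expression triplet, all under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    whitelist = simulate_whitelist(
        config.whitelist_size, min_pairwise_dist=config.min_whitelist_dist, rng=rng
    )
    gene, ref = make_toy_gene(rng, n_exons=config.n_exons, strand=config.gene_strand)
    guide = make_toy_guide(gene, ref, exon_ordinal=config.guide_exon)
    guides = [guide]
    cut = cut_site(guide)
    cells = _simulate_cells(config, whitelist, rng)
    by_name = {g.name: g for g in config.groups}

    reads: list[SimRead] = []
    counter = 0
    for _, cell in cells.iterrows():
        group = by_name[cell["group"]]
        # any group with a nonzero edit probability receives indels at the
        # site (background groups model off-target / ambient contamination)
        guide_cut = cut if group.mut_prob > 0 else None
        n_mol = max(1, int(rng.poisson(config.mean_molecules_per_cell)))
        for _ in range(n_mol):
            read = simulate_molecule(
                f"read{counter:07d}",
                cell["barcode"],
                group,
                gene,
                ref,
                config,
                rng,
                guide_cut,
            )
            counter += 1
            reads.append(read)
            if config.duplicate_rate > 0 and rng.random() < config.duplicate_rate:
                # PCR duplicate: same molecule truth, independent sequencing errors
                dup = simulate_molecule(
                    f"read{counter:07d}",
                    cell["barcode"],
                    group,
                    gene,
                    ref,
                    config,
                    rng,
                    guide_cut,
                    fixed_umi=read.umi,
                    fixed_pattern=read.pattern,
                    fixed_status=read.status,
                    is_duplicate=True,
                )
                counter += 1
                reads.append(dup)

    paths = SimBundle(
        out_dir=out_dir,
        sam=out_dir / "reads.sam",
        ref_fasta=out_dir / "ref.fasta",
        whitelist_path=out_dir / "whitelist.txt",
        gene_config=out_dir / "gene_model.json",
        guide_table=out_dir / "guides.tsv",
        truth_reads=out_dir / "truth_reads.tsv",
        cells_table=out_dir / "cells.tsv",
        guide_assignments=out_dir / "guide_assignments.tsv",
        expr_dir=out_dir / "expression",
        config_json=out_dir / "sim_config.json",
        gene=gene,
        ref=ref,
        whitelist=whitelist,
        guides=guides,
        reads=reads,
        cells=cells,
    )

    with open(paths.ref_fasta, "w") as fh:
        fh.write(f">{gene.chrom}\n")
        for i in range(0, len(ref), 80):
            fh.write(ref[i : i + 80] + "\n")
    whitelist.save(paths.whitelist_path)
    write_gene_model(gene, paths.gene_config)
    write_guides(guides, paths.guide_table)
    emit_sam(reads, gene, ref, paths.sam, paths.truth_reads)
    cells.sort_values("barcode").to_csv(paths.cells_table, sep="\t", index=False)

    assign_rows = []
    for _, cell in cells.iterrows():
        if cell["guide"] is None:
            continue
        assign_rows.append(
            {
                "barcode": cell["barcode"],
                "guide": cell["guide"],
                "umi_count": int(rng.integers(5, 15)),
            }
        )
        if rng.random() < 0.1:  # sparse cross-droplet noise
            other = guide.name if cell["guide"] != guide.name else "nontarget-1"
            assign_rows.append(
                {"barcode": cell["barcode"], "guide": other, "umi_count": 1}
            )
    pd.DataFrame(assign_rows, columns=["barcode", "guide", "umi_count"]).sort_values(
        ["barcode", "guide"]
    ).to_csv(paths.guide_assignments, sep="\t", index=False)

    expr, gene_names = simulate_expression(config, gene, cells, rng)
    paths.expr_dir.mkdir(exist_ok=True)
    mmwrite(str(paths.expr_dir / "matrix.mtx"), sparse.coo_matrix(expr))
    with open(paths.expr_dir / "barcodes.tsv", "w") as fh:
        fh.writelines(bc + "\n" for bc in cells["barcode"])
    with open(paths.expr_dir / "features.tsv", "w") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in gene_names)

    cfg = asdict(config)
    with open(paths.config_json, "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
        fh.write("\n")
    logger.info(
        "simulate_experiment: %d cells, %d reads written to %s",
        len(cells),
        len(reads),
        out_dir,
    )
    return paths
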