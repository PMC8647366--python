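"""Target-gene models, guide definitions, and cut-site analysis windows.

A targeted amplicon experiment is described by a small, user-supplied gene
model: the ordered exons of the gene of interest, the strand it is
transcribed from, and a pair of *anchor* exons that a long read must cover
to be counted (this filters reverse-transcription truncations and PCR
artifacts). CRISPR guides are described by their 20-nt protospacer and the
genomic position of the PAM; the nuclease cut site and a small symmetric
analysis window around it are derived from those.

All genomic coordinates are 0-based half-open (the BED/SAM convention);
1-based coordinates appear only in human-facing error messages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "ExonInterval",
    "GeneModel",
    "GuideTarget",
    "AnalysisWindow",
    "load_gene_model",
    "load_guides",
    "cut_site",
    "analysis_window",
]


@dataclass(frozen=True)
class ExonInterval:
    """One exon: 1-based ordinal plus a 0-based half-open genomic interval."""

    index: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"exon ordinal must be >= 1, got {self.index}")
        if not self.start < self.end:
            raise ValueError(
                f"exon {self.index}: start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of bases of ``[start, end)`` falling inside this exon."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class GeneModel:
    """A target gene: ordered exons plus the anchor exons used as read filters.

    ``exons`` are ordered by transcript ordinal (exon 1 first). For a
    plus-strand gene ordinals increase with genomic coordinate; for a
    minus-strand gene exon 1 is the genomically last interval.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    anchor_first: int
    anchor_last: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.name}: no exons")
        n = len(self.exons)
        ordinals = [e.index for e in self.exons]
        if ordinals != list(range(1, n + 1)):
            raise ValueError(
                f"gene {self.name}: exon ordinals must be consecutive from 1, got {ordinals}"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"gene {self.name}: exons {a.index} and {b.index} overlap "
                    f"([{a.start},{a.end}) vs [{b.start},{b.end}))"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if [e.index for e in expected] != list(range(1, n + 1)):
            raise ValueError(
                f"gene {self.name}: exon ordinals do not follow the {self.strand} strand "
                "convention (1..n in genomic order for '+', reversed for '-')"
            )
        if not self.anchor_first < self.anchor_last:
            raise ValueError(
                f"gene {self.name}: anchor_first ({self.anchor_first}) must be < "
                f"anchor_last ({self.anchor_last})"
            )
        for a in (self.anchor_first, self.anchor_last):
            if not 1 <= a <= n:
                raise ValueError(f"gene {self.name}: anchor exon {a} outside 1..{n}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the gene's exons (0-based half-open)."""
        return min(e.start for e in self.exons), max(e.end for e in self.exons)

    def exon(self, index: int) -> ExonInterval:
        return self.exons[index - 1]

    def exon_of_position(self, pos: int) -> int | None:
        """Exon ordinal containing genomic position ``pos``, or None (intronic).

        A position maps to at most one exon because exons never overlap.
        """
        for e in self.exons:
            if e.start <= pos < e.end:
                return e.index
        return None


@dataclass(frozen=True)
class GuideTarget:
    """A CRISPR guide: 20-nt protospacer plus the genomic position of its PAM.

    ``pam_start`` is the leftmost genomic coordinate of the 3-nt PAM. For a
    plus-strand protospacer the PAM sits immediately right of the protospacer;
    for a minus-strand protospacer it sits immediately left (the protospacer
    occupies ``[pam_start + 3, pam_start + 23)`` on the reference).
    """

    name: str
    gene: str
    chrom: str
    protospacer: str
    protospacer_strand: str
    pam_start: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(
                f"guide {self.name}: protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        if self.protospacer_strand not in ("+", "-"):
            raise ValueError(f"guide {self.name}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AnalysisWindow:
    """Reference interval around a cut site used for indel genotyping."""

    chrom: str
    start: int
    end: int
    guide: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start must be < end, got [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def cut_site(guide: GuideTarget, cut_offset: int = 3) -> int:
    """Blunt-cut coordinate for a guide, as a 0-based inter-base position.

    SpCas9 cuts between protospacer positions 17 and 18, i.e. ``cut_offset``
    (default 3) bases 5' of the PAM. ``cut_offset`` is exposed for nucleases
    with a different cut geometry.
    """
    if guide.protospacer_strand == "+":
        return guide.pam_start - cut_offset
    return guide.pam_start + 3 + cut_offset


def analysis_window(
    cut: int,
    flank: int = 2,
    *,
    chrom: str = "",
    guide: str | None = None,
    ref_length: int | None = None,
) -> AnalysisWindow:
    """Symmetric window ``[cut - flank, cut + flank)`` around a cut position.

    The default ``flank=2`` yields a 4-bp window: 2 bp on each side of the
    blunt cut. Raises if the window would extend past the reference bounds.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    start, end = cut - flank, cut + flank
    if start < 0:
        raise ValueError(f"analysis window [{start},{end}) extends past reference start")
    if ref_length is not None and end > ref_length:
        raise ValueError(
            f"analysis window [{start},{end}) extends past reference end {ref_length}"
        )
    return AnalysisWindow(chrom=chrom, start=start, end=end, guide=guide)


def _assign_ordinals(
    intervals: Sequence[tuple[str, int, int]], strand: str
) -> tuple[ExonInterval, ...]:
    """Order raw (chrom, start, end) intervals into strand-aware exon ordinals."""
    genomic = sorted(intervals, key=lambda iv: iv[1])
    ordered = genomic if strand == "+" else genomic[::-1]
    return tuple(
        ExonInterval(index=i + 1, chrom=c, start=s, end=e)
        for i, (c, s, e) in enumerate(ordered)
    )


def _read_bed_exons(path: Path, chrom_hint: str | None) -> list[tuple[str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED record {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            rows.append((fields[0], start, end))
    if chrom_hint is not None:
        for c, s, e in rows:
            if c != chrom_hint:
                raise ValueError(
                    f"{path}: BED record on {c} but gene model declares {chrom_hint}"
                )
    return rows


def load_gene_model(config_path: str | Path) -> GeneModel:
    """Load and validate a gene model from a JSON/YAML config.

    The config names ``gene``, ``chrom``, ``strand``, ``anchors`` (a 2-list of
    exon ordinals) and either inline ``exons`` (list of ``[start, end]`` or
    ``[chrom, start, end]``) or an ``exons_bed`` path to a BED file whose
    intervals are the exons. Exon ordinals are assigned by the strand
    convention, so inline exon order does not matter.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("gene", "chrom", "strand", "anchors"):
        if key not in cfg:
            raise ValueError(f"{config_path}: gene model config missing key {key!r}")
    chrom = cfg["chrom"]
    if "exons" in cfg:
        raw = []
        for rec in cfg["exons"]:
            if len(rec) == 2:
                raw.append((chrom, int(rec[0]), int(rec[1])))
            elif len(rec) == 3:
                raw.append((str(rec[0]), int(rec[1]), int(rec[2])))
            else:
                raise ValueError(f"{config_path}: malformed exon record {rec!r}")
    elif "exons_bed" in cfg:
        bed = Path(cfg["exons_bed"])
        if not bed.is_absolute():
            bed = config_path.parent / bed
        raw = _read_bed_exons(bed, chrom)
    else:
        raise ValueError(f"{config_path}: config must provide 'exons' or 'exons_bed'")
    anchors = cfg["anchors"]
    if len(anchors) != 2:
        raise ValueError(f"{config_path}: 'anchors' must be a pair of exon ordinals")
    return GeneModel(
        name=cfg["gene"],
        chrom=chrom,
        strand=cfg["strand"],
        exons=_assign_ordinals(raw, cfg["strand"]),
        anchor_first=int(anchors[0]),
        anchor_last=int(anchors[1]),
    )


def load_guides(path: str | Path) -> list[GuideTarget]:
    """Load guide definitions from a TSV with columns
    name, gene, chrom, protospacer, strand, pam_start."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "gene", "chrom", "protospacer", "strand", "pam_start"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: guide table missing columns {missing}")
    guides = []
    for _, row in df.iterrows():
        guides.append(
            GuideTarget(
                name=row["name"],
                gene=row["gene"],
                chrom=row["chrom"],
                protospacer=row["protospacer"],
                protospacer_strand=row["strand"],
                pam_start=int(row["pam_start"]),
            )
        )
    return guides


def write_guides(guides: Iterable[GuideTarget], path: str | Path) -> None:
    """Write a guide table TSV (inverse of :func:`load_guides`)."""
    rows = [
        {
            "name": g.name,
            "gene": g.gene,
            "chrom": g.chrom,
            "protospacer": g.protospacer,
            "strand": g.protospacer_strand,
            "pam_start": g.pam_start,
        }
        for g in guides
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gene_model(gene: GeneModel, path: str | Path) -> None:
    """Write a gene model config as JSON (inverse of :func:`load_gene_model`)."""
    cfg = {
        "gene": gene.name,
        "chrom": gene.chrom,
        "strand": gene.strand,
        "anchors": [gene.anchor_first, gene.anchor_last],
        "exons": [[e.start, e.end] for e in sorted(gene.exons, key=lambda e: e.start)],
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
        fh.write("\n")
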