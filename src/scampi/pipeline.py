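"""End-to-end pipeline wiring: BAM -> match table -> molecules -> matrices.

Each stage writes a plain TSV that the next stage (or a downstream-only
re-invocation) can consume, so runs are restartable. A run manifest records
package/library versions, effective parameters and input checksums for
provenance. All outputs are sorted on their keys, so re-running with the
same inputs — or with permuted input rows — is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import sparse
from scipy.io import mmwrite

from . import __version__
from .alignments import extract_search_sequence, read_alignments, window_bases
from .barcode_match import (
    BarcodeWhitelist,
    Molecule,
    build_reference_index,
    deduplicate,
    match_barcode,
)
from .genemodel import analysis_window, cut_site, load_gene_model, load_guides
from .integrate import (
    ExpressionMatrix,
    expression_contrast,
    join_cells,
    load_guide_assignments,
)
from .isoform_call import anchor_filter, build_matrix, call_exon_pattern, cluster_cells
from .mutation_call import classify_read, compare_target_vs_other, per_cell_rates

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    bam: str
    whitelist: str
    gene_model: str
    out_dir: str
    guides: str | None = None
    ref_fasta: str | None = None
    guide_table: str | None = None
    expr_dir: str | None = None
    contrast_gene: str | None = None
    contrast_group_a: str | None = None  # guide name defining group A cells
    contrast_group_b: str | None = None  # guide name; None = all other assigned cells
    k: int = 8
    top_n: int = 5
    accept_lt: int = 3
    umi_len: int = 10
    use_idf: bool = False
    expected_offset: int | None = 22
    min_overlap_frac: float = 0.5
    min_molecules_per_cell: int = 5
    flank: int = 2
    clusters: int | None = None
    min_support: int = 3
    min_purity: float = 0.8
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate_paths(self) -> None:
        required = {"bam": self.bam, "whitelist": self.whitelist, "gene_model": self.gene_model}
        optional = {
            "guides": self.guides,
            "ref_fasta": self.ref_fasta,
            "guide_table": self.guide_table,
            "expr_dir": self.expr_dir,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence.upper()
    return seqs


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every applicable stage and return the map of written outputs.

    Stages: barcode matching, UMI dedup + exon-pattern calling, isoform
    matrix (+ optional clustering), indel genotyping (when guides and a
    reference are given), per-cell join and optional expression contrast.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "package": {"name": "scampi", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "pysam": pysam.__version__,
        },
        "parameters": {k: v for k, v in vars(config).items()},
        "inputs": {},
        "stages": {},
    }
    for name in ("bam", "whitelist", "gene_model", "guides", "guide_table"):
        p = getattr(config, name)
        if p and Path(p).is_file():
            manifest["inputs"][name] = {"path": str(p), "md5": _md5(p)}

    gene = load_gene_model(config.gene_model)
    whitelist = BarcodeWhitelist.load(config.whitelist)
    index = build_reference_index(whitelist, k=config.k, use_idf=config.use_idf)

    # ---- stage: barcode matching -------------------------------------------
    counts: dict[str, int] = {}
    n_wrong_strand = 0
    match_rows = []
    reads_by_id = {}
    for read in read_alignments(config.bam, counts=counts):
        search = extract_search_sequence(read, gene)
        if search is None:
            n_wrong_strand += 1
            continue
        m = match_barcode(
            search,
            index,
            accept_lt=config.accept_lt,
            top_n=config.top_n,
            expected_offset=config.expected_offset,
        )
        reads_by_id[read.read_id] = read
        match_rows.append(
            {
                "read_id": m.read_id,
                "barcode": m.barcode if m.barcode is not None else "",
                "edit_distance": m.edit_distance,
                "cosine": m.cosine,
                "bc_start": m.bc_start if m.bc_start is not None else -1,
                "expected_pos_dev": m.expected_pos_dev if m.expected_pos_dev is not None else "",
                "umi": m.umi if m.umi is not None else "",
            }
        )
    match_df = pd.DataFrame(
        match_rows,
        columns=[
            "read_id", "barcode", "edit_distance", "cosine",
            "bc_start", "expected_pos_dev", "umi",
        ],
    ).sort_values("read_id")
    outputs["match_table"] = out_dir / "match_table.tsv"
    match_df.to_csv(outputs["match_table"], sep="\t", index=False)
    n_matched = int((match_df["barcode"] != "").sum()) if len(match_df) else 0
    manifest["stages"]["match"] = {
        "alignments": counts,
        "wrong_strand_or_hard_clipped": n_wrong_strand,
        "evaluated": len(match_df),
        "matched": n_matched,
    }

    # ---- stage: molecules (patterns + dedup) --------------------------------
    guides = load_guides(config.guides) if config.guides else []
    ref_seqs = _read_fasta(config.ref_fasta) if config.ref_fasta else {}
    windows = {}
    for g in guides:
        ref = ref_seqs.get(g.chrom)
        windows[g.name] = (
            analysis_window(
                cut_site(g), config.flank, chrom=g.chrom, guide=g.name,
                ref_length=len(ref) if ref else None,
            ),
            ref,
        )

    molecules = []
    for _, row in match_df.iterrows():
        if not row["barcode"] or not row["umi"]:
            continue
        read = reads_by_id[row["read_id"]]
        pattern = call_exon_pattern(read, gene, config.min_overlap_frac)
        mol = Molecule(
            barcode=row["barcode"],
            umi=row["umi"],
            read_id=row["read_id"],
            pattern=pattern.label if anchor_filter(pattern, gene) else None,
        )
        molecules.append(mol)
    deduped = deduplicate(molecules)
    mol_df = pd.DataFrame(
        [
            {
                "barcode": m.barcode,
                "umi": m.umi,
                "read_id": m.read_id,
                "pattern": m.pattern if m.pattern is not None else "",
            }
            for m in deduped
        ],
        columns=["barcode", "umi", "read_id", "pattern"],
    ).sort_values(["barcode", "umi"])
    outputs["molecules"] = out_dir / "molecules.tsv"
    mol_df.to_csv(outputs["molecules"], sep="\t", index=False)
    manifest["stages"]["molecules"] = {
        "input_reads": len(molecules),
        "deduplicated": len(deduped),
        "anchor_filtered_out": int((mol_df["pattern"] == "").sum()),
    }

    # ---- stage: isoform matrix ---------------------------------------------
    kept = [m for m in deduped if m.pattern is not None]
    matrix = build_matrix(kept, min_molecules_per_cell=config.min_molecules_per_cell)
    outputs["isoform_counts"] = out_dir / "isoform_counts.tsv"
    outputs["isoform_proportions"] = out_dir / "isoform_proportions.tsv"
    matrix.counts.to_csv(outputs["isoform_counts"], sep="\t")
    matrix.proportions.to_csv(outputs["isoform_proportions"], sep="\t")
    if matrix.counts.size:
        outputs["isoform_mtx"] = out_dir / "isoform_counts.mtx"
        mmwrite(str(outputs["isoform_mtx"]), sparse.coo_matrix(matrix.counts.values))
        (out_dir / "isoform_barcodes.tsv").write_text(
            "".join(bc + "\n" for bc in matrix.counts.index)
        )
        (out_dir / "isoform_patterns.tsv").write_text(
            "".join(p + "\n" for p in matrix.counts.columns)
        )
    cluster_series = None
    if config.clusters and len(matrix.counts) >= config.clusters:
        cluster_series = cluster_cells(matrix, config.clusters)
        outputs["clusters"] = out_dir / "clusters.tsv"
        cluster_series.to_csv(outputs["clusters"], sep="\t")
    manifest["stages"]["isoform"] = {
        "cells": len(matrix.counts),
        "patterns": len(matrix.counts.columns),
    }

    # ---- stage: mutation genotyping ----------------------------------------
    rates_df = pd.DataFrame()
    if guides and ref_seqs:
        match_by_id = match_df.set_index("read_id")
        calls = []
        for read_id, read in sorted(reads_by_id.items()):
            row = match_by_id.loc[read_id]
            barcode = row["barcode"] or None
            if barcode is None:
                continue
            for g in guides:
                window, ref = windows[g.name]
                if ref is None:
                    continue
                obs = window_bases(read, window)
                ref_window = ref[window.start : window.end]
                calls.append(
                    classify_read(obs, ref_window, barcode=barcode, guide=g.name)
                )
        calls_df = pd.DataFrame(
            [
                {
                    "read_id": c.read_id,
                    "barcode": c.barcode,
                    "guide": c.guide,
                    "status": c.status,
                    "evidence": c.evidence,
                }
                for c in calls
            ],
            columns=["read_id", "barcode", "guide", "status", "evidence"],
        ).sort_values(["read_id", "guide"])
        outputs["mutation_calls"] = out_dir / "mutation_calls.tsv"
        calls_df.to_csv(outputs["mutation_calls"], sep="\t", index=False)
        rates = per_cell_rates(calls)
        rates_df = pd.DataFrame(
            [
                {"barcode": r.barcode, "guide": r.guide, "n_reads": r.n_reads, "rate": r.rate}
                for r in rates
            ],
            columns=["barcode", "guide", "n_reads", "rate"],
        )
        outputs["mutation_rates"] = out_dir / "mutation_rates.tsv"
        rates_df.to_csv(outputs["mutation_rates"], sep="\t", index=False)
        manifest["stages"]["mutation"] = {
            "calls": len(calls_df),
            "cells_with_rates": len(rates_df),
        }
        if config.guide_table:
            assignments = load_guide_assignments(
                config.guide_table, config.min_support, config.min_purity
            )
            assign_map = {a.barcode: a.guide for a in assignments}
            summary = compare_target_vs_other(rates, assign_map)
            summary["test"] = "welch_t_two_sided"
            outputs["mutation_summary"] = out_dir / "mutation_summary.tsv"
            summary.to_csv(outputs["mutation_summary"], sep="\t", index=False)

    # ---- stage: integration -------------------------------------------------
    sources: dict[str, pd.DataFrame | pd.Series] = {}
    if len(matrix.counts):
        iso = pd.DataFrame(
            {"n_molecules": matrix.counts.sum(axis=1)}, index=matrix.counts.index
        )
        if cluster_series is not None:
            iso["cluster"] = cluster_series
        sources["isoform"] = iso
    if len(rates_df):
        sources["mutation"] = (
            rates_df.groupby("barcode")["rate"].mean().rename("mean_mutation_rate")
        )
    assign_map_all: dict[str, str] = {}
    if config.guide_table:
        assignments = load_guide_assignments(
            config.guide_table, config.min_support, config.min_purity
        )
        assign_map_all = {a.barcode: a.guide for a in assignments}
        sources["guide"] = pd.DataFrame(
            [{"barcode": a.barcode, "guide": a.guide, "support": a.support} for a in assignments]
        )
    expr = None
    if config.expr_dir:
        expr = ExpressionMatrix.load(config.expr_dir)
        sources["expression"] = pd.DataFrame(index=pd.Index(expr.barcodes, name="barcode"))
    if sources:
        joined = join_cells(**sources)
        outputs["cells"] = out_dir / "cells.tsv"
        joined.to_csv(outputs["cells"], sep="\t")
        manifest["stages"]["join"] = {"cells": len(joined)}

    if expr is not None and config.contrast_gene and config.contrast_group_a and assign_map_all:
        labels = {}
        for bc, g in assign_map_all.items():
            if g == config.contrast_group_a:
                labels[bc] = "A"
            elif config.contrast_group_b is None or g == config.contrast_group_b:
                labels[bc] = "B"
        result = expression_contrast(expr, labels, config.contrast_gene, "A", "B")
        outputs["expression_contrast"] = out_dir / "expression_contrast.tsv"
        pd.DataFrame([vars(result)]).to_csv(
            outputs["expression_contrast"], sep="\t", index=False
        )

    outputs["manifest"] = out_dir / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("run_pipeline: wrote %d outputs to %s", len(outputs), out_dir)
    return outputs
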