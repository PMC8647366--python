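"""Joining long-read per-cell results with short-read products.

The short-read side of the experiment contributes two things consumed here:
guide assignments per cell (from direct guide capture) and a sparse
gene-expression matrix (from standard droplet preprocessing). Everything is
keyed by the 16-bp cell barcode with gem-group suffixes stripped, so the
long- and short-read worlds join on a common key.

The expression contrast mirrors the conventional droplet workflow: per-cell
counts are library-size normalized to 10^4 and log1p-transformed; the group
fold change is computed on the de-logged scale (ratio of group means of the
normalized counts), and significance from a two-sided Welch t-test on the
log-normalized values.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread
from scipy.stats import ttest_ind

from ._util import strip_gem_suffix

logger = logging.getLogger(__name__)

__all__ = [
    "GuideAssignment",
    "ExpressionMatrix",
    "ContrastResult",
    "load_guide_assignments",
    "join_cells",
    "expression_contrast",
]


@dataclass(frozen=True)
class GuideAssignment:
    """One cell's assigned guide with its supporting UMI count."""

    barcode: str
    guide: str
    support: int


def load_guide_assignments(
    path: str | Path, min_support: int = 3, min_purity: float = 0.8
) -> list[GuideAssignment]:
    """Assign each cell its dominant guide from a capture-count TSV.

    Input columns: barcode, guide, umi_count (one row per observed
    cell-guide pair). A cell is assigned its top-support guide only when
    that support is at least ``min_support`` UMIs and at least
    ``min_purity`` of the cell's total guide UMIs; otherwise the cell stays
    unassigned. Ties on support imply purity <= 0.5 and thus no assignment.
    """
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "guide": str})
    required = ["barcode", "guide", "umi_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: guide assignment table missing columns {missing}")
    bad = df.index[df[required].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {int(bad[0]) + 2}")
    try:
        df["umi_count"] = df["umi_count"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer umi_count") from exc
    df["barcode"] = df["barcode"].map(strip_gem_suffix)
    out: list[GuideAssignment] = []
    for barcode, grp in df.groupby("barcode", sort=True):
        total = grp["umi_count"].sum()
        top = grp.sort_values(["umi_count", "guide"], ascending=[False, True]).iloc[0]
        if top["umi_count"] >= min_support and top["umi_count"] / total >= min_purity:
            out.append(
                GuideAssignment(
                    barcode=barcode, guide=top["guide"], support=int(top["umi_count"])
                )
            )
    return out


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells count matrix with its sidecar name lists."""

    matrix: sparse.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.min() < 0:
            raise ValueError("expression counts must be non-negative")

    @classmethod
    def load(cls, directory: str | Path) -> "ExpressionMatrix":
        """Read an MTX triplet directory (matrix.mtx[.gz] + barcodes/features).

        Accepts both ``features.tsv`` and the older ``genes.tsv`` name, in
        plain or gzipped form; feature files may carry 1-3 columns, with the
        symbol in the second column when present. Barcode gem-group suffixes
        are stripped.
        """
        directory = Path(directory)

        def find(*names: str) -> Path:
            for name in names:
                for cand in (directory / name, directory / (name + ".gz")):
                    if cand.exists():
                        return cand
            raise FileNotFoundError(f"{directory}: none of {names} found")

        def read_lines(p: Path) -> list[str]:
            opener = gzip.open if p.suffix == ".gz" else open
            with opener(p, "rt") as fh:
                return [line.rstrip("\n") for line in fh if line.strip()]

        mat = sparse.csr_matrix(mmread(str(find("matrix.mtx"))))
        barcodes = [strip_gem_suffix(l.split("\t")[0]) for l in read_lines(find("barcodes.tsv"))]
        feat_lines = [l.split("\t") for l in read_lines(find("features.tsv", "genes.tsv"))]
        genes = [f[1] if len(f) > 1 else f[0] for f in feat_lines]
        return cls(matrix=mat, genes=genes, barcodes=barcodes)


def join_cells(**sources: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Outer-join per-cell tables from multiple sources on the barcode key.

    Each keyword argument is a DataFrame/Series either indexed by barcode or
    carrying a ``barcode`` column; a duplicate barcode within any single
    source is an error. The result has one row per barcode seen anywhere,
    an ``in_<source>`` presence flag per source, and is sorted by barcode
    (so permuting input rows cannot change the output). Join cardinality is
    logged.
    """
    frames: dict[str, pd.DataFrame] = {}
    for name, src in sources.items():
        if isinstance(src, pd.Series):
            df = src.to_frame()
        else:
            df = src.copy()
        if "barcode" in df.columns:
            df = df.set_index("barcode")
        df.index = df.index.map(strip_gem_suffix)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"source {name!r}: duplicate barcode {dup!r}")
        df.columns = [f"{name}_{c}" if c in _all_columns(frames) else c for c in df.columns]
        frames[name] = df
    all_barcodes = sorted(set().union(*[set(f.index) for f in frames.values()]))
    out = pd.DataFrame(index=pd.Index(all_barcodes, name="barcode"))
    for name, df in frames.items():
        out = out.join(df, how="left")
        out[f"in_{name}"] = out.index.isin(df.index)
    only_counts = {
        name: int((out[f"in_{name}"] & ~np.logical_or.reduce(
            [out[f"in_{o}"] for o in frames if o != name]
        )).sum()) if len(frames) > 1 else int(out[f"in_{name}"].sum())
        for name in frames
    }
    logger.info(
        "join_cells: %d barcodes total; exclusive per source: %s", len(out), only_counts
    )
    return out


def _all_columns(frames: Mapping[str, pd.DataFrame]) -> set[str]:
    cols: set[str] = set()
    for df in frames.values():
        cols.update(df.columns)
    return cols


@dataclass(frozen=True)
class ContrastResult:
    """Single-gene expression contrast between two cell groups."""

    gene: str
    fold_change: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    reportable: bool


def expression_contrast(
    expr: ExpressionMatrix,
    labels: Mapping[str, str],
    gene: str,
    group_a: str,
    group_b: str,
    min_cells: int = 3,
    scale: float = 1e4,
) -> ContrastResult:
    """Contrast one gene's expression between two labeled cell groups.

    Per-cell normalized expression is ``ln(1 + scale * count / cell_total)``.
    The fold change is the ratio of group means on the de-logged scale
    (i.e. of ``scale * count / cell_total``); the p-value is a two-sided
    Welch t-test on the log-normalized values. Swapping the groups inverts
    the fold change and preserves the p-value.
    """
    if gene not in expr.genes:
        raise ValueError(f"gene {gene!r} not in expression features")
    gi = expr.genes.index(gene)
    totals = np.asarray(expr.matrix.sum(axis=0)).ravel()
    if (totals == 0).any():
        logger.warning("expression_contrast: %d cells with zero total counts", int((totals == 0).sum()))
        totals = np.where(totals == 0, 1, totals)
    gene_counts = np.asarray(expr.matrix[gi].todense()).ravel()
    scaled = scale * gene_counts / totals
    lognorm = np.log1p(scaled)
    idx_a, idx_b = [], []
    for j, bc in enumerate(expr.barcodes):
        grp = labels.get(bc)
        if grp == group_a:
            idx_a.append(j)
        elif grp == group_b:
            idx_b.append(j)
    a_log, b_log = lognorm[idx_a], lognorm[idx_b]
    a_lin, b_lin = scaled[idx_a], scaled[idx_b]
    reportable = len(idx_a) >= min_cells and len(idx_b) >= min_cells
    mean_a = float(a_log.mean()) if len(idx_a) else float("nan")
    mean_b = float(b_log.mean()) if len(idx_b) else float("nan")
    if len(idx_a) >= 2 and len(idx_b) >= 2 and (a_log.std() > 0 or b_log.std() > 0):
        p = float(ttest_ind(a_log, b_log, equal_var=False).pvalue)
    elif reportable and mean_a == mean_b:
        p = 1.0
    else:
        p = float("nan")
    denom = b_lin.mean() if len(idx_b) else float("nan")
    fold = float(a_lin.mean() / denom) if len(idx_a) and denom else float("inf")
    return ContrastResult(
        gene=gene,
        fold_change=fold,
        p_value=p,
        mean_a=mean_a,
        mean_b=mean_b,
        n_a=len(idx_a),
        n_b=len(idx_b),
        reportable=reportable,
    )
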