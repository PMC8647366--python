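"""Per-molecule exon patterns and per-cell isoform summaries.

A full-length read's alignment blocks reveal which annotated exons the
underlying transcript retained. An exon counts as present when at least
``min_overlap_frac`` of its length is covered by alignment-match blocks
(robust to nanopore indel noise at junctions). Patterns are encoded as
compact labels such as ``"1234-678"`` — digits for retained exons, one
``"-"`` per maximal run of skipped exons.

Per-cell pattern counts form a cells x patterns matrix; row-normalized
proportions drive hierarchical clustering (Euclidean distance, complete
linkage — the defaults of the standard clustered-heatmap tools) and
short-isoform ratio statistics, e.g. the fraction of PTPRC molecules that
are RO or RB.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from .alignments import AlignedRead
from .barcode_match import Molecule
from .genemodel import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExonPattern",
    "CellIsoformMatrix",
    "IsoformNaming",
    "GroupComparison",
    "pattern_label",
    "parse_label",
    "call_exon_pattern",
    "anchor_filter",
    "build_matrix",
    "cluster_cells",
    "short_isoform_ratio",
    "compare_ratio_groups",
]


def pattern_label(present: Iterable[int], n_exons: int) -> str:
    """Canonical label for a set of retained exon ordinals.

    Retained exons appear as their ordinals; each maximal run of skipped
    exons collapses to a single ``"-"``: an 8-exon gene retaining everything
    but exon 5 gives ``"1234-678"``. For genes with more than 9 exons,
    ordinals are comma-separated to stay unambiguous.
    """
    present_set = set(present)
    if not present_set <= set(range(1, n_exons + 1)):
        raise ValueError(f"present exons {sorted(present_set)} outside 1..{n_exons}")
    sep = "" if n_exons <= 9 else ","
    parts: list[str] = []
    in_gap = False
    for i in range(1, n_exons + 1):
        if i in present_set:
            parts.append(str(i))
            in_gap = False
        elif not in_gap:
            parts.append("-")
            in_gap = True
    return sep.join(parts)


def parse_label(label: str) -> frozenset[int]:
    """Invert :func:`pattern_label`: recover the set of retained ordinals."""
    if "," in label:
        return frozenset(int(tok) for tok in label.split(",") if tok != "-")
    return frozenset(int(ch) for ch in label if ch.isdigit())


@dataclass(frozen=True)
class ExonPattern:
    """Retained-exon set of one molecule plus its canonical label."""

    present: frozenset[int]
    label: str

    @classmethod
    def from_present(cls, present: Iterable[int], n_exons: int) -> "ExonPattern":
        pres = frozenset(present)
        return cls(present=pres, label=pattern_label(pres, n_exons))


def call_exon_pattern(
    read: AlignedRead, gene: GeneModel, min_overlap_frac: float = 0.5
) -> ExonPattern:
    """Call which exons a read's transcript retained.

    Exon e is present iff the read's alignment blocks cover at least
    ``min_overlap_frac`` of e's length. Block fragmentation (small deletions
    splitting a match run) does not change the call as long as coverage
    stays above the threshold.
    """
    present = []
    for exon in gene.exons:
        covered = sum(exon.overlap(s, e) for s, e in read.blocks)
        if covered / len(exon) >= min_overlap_frac:
            present.append(exon.index)
    return ExonPattern.from_present(present, gene.n_exons)


def anchor_filter(pattern: ExonPattern, gene: GeneModel) -> bool:
    """True iff both anchor exons are present (keeps full-length molecules)."""
    return gene.anchor_first in pattern.present and gene.anchor_last in pattern.present


@dataclass
class CellIsoformMatrix:
    """Cells x isoform-pattern molecule counts with derived proportions."""

    counts: pd.DataFrame  # index: barcode, columns: pattern label, int counts
    proportions: pd.DataFrame
    cluster: pd.Series | None = None

    @property
    def cells(self) -> list[str]:
        return list(self.counts.index)

    @property
    def patterns(self) -> list[str]:
        return list(self.counts.columns)


def build_matrix(
    molecules: Sequence[Molecule], min_molecules_per_cell: int = 5
) -> CellIsoformMatrix:
    """Aggregate deduplicated molecules into a cells x patterns count matrix.

    Cells with fewer than ``min_molecules_per_cell`` molecules are dropped
    (count logged). Rows/columns are sorted, so the result is invariant to
    molecule order.
    """
    rows = [
        (m.barcode, m.pattern) for m in molecules if m.pattern is not None
    ]
    if not rows:
        warnings.warn("build_matrix: no molecules with patterns; empty matrix")
        empty = pd.DataFrame(dtype=int)
        return CellIsoformMatrix(counts=empty, proportions=empty.astype(float))
    df = pd.DataFrame(rows, columns=["barcode", "pattern"])
    counts = (
        df.groupby(["barcode", "pattern"]).size().unstack(fill_value=0).sort_index()
    )
    counts = counts[sorted(counts.columns)]
    totals = counts.sum(axis=1)
    keep = totals >= min_molecules_per_cell
    if (~keep).any():
        logger.info(
            "build_matrix: dropped %d cells with < %d molecules",
            int((~keep).sum()),
            min_molecules_per_cell,
        )
    counts = counts.loc[keep]
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return CellIsoformMatrix(counts=counts.astype(int), proportions=proportions)


def cluster_cells(
    matrix: CellIsoformMatrix,
    k: int,
    collapse_rare_frac: float = 0.005,
) -> pd.Series:
    """Agglomerative clustering of cells on isoform proportions.

    Euclidean distance, complete linkage, tree cut into ``k`` flat clusters.
    Patterns carrying less than ``collapse_rare_frac`` of all molecules are
    pooled into an "other" column for the clustering input only; raw counts
    keep their full labels. The cluster count is an experiment-level choice
    (heatmap cuts in the source analyses were visual), so ``k`` is always
    explicit. Deterministic for fixed input.
    """
    n_cells = len(matrix.counts)
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({n_cells})")
    X = matrix.proportions
    if collapse_rare_frac > 0 and matrix.counts.size:
        pattern_frac = matrix.counts.sum(axis=0) / matrix.counts.values.sum()
        rare = pattern_frac[pattern_frac < collapse_rare_frac].index
        if len(rare):
            X = X.drop(columns=rare).assign(other=X[rare].sum(axis=1))
    Z = linkage(X.to_numpy(), method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(set(labels)) < k:
        warnings.warn(
            f"cluster_cells: degenerate input produced {len(set(labels))} < {k} clusters"
        )
    out = pd.Series(labels, index=matrix.counts.index, name="cluster")
    matrix.cluster = out
    return out


@dataclass(frozen=True)
class IsoformNaming:
    """Pattern-label -> isoform-name map plus the names counted as "short".

    For PTPRC the five highly expressed isoforms are RO, RB, RBC, RAB and
    RABC; RO and RB form the short set enriched in activated T cells.
    """

    mapping: Mapping[str, str]
    short_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        extra = set(self.short_set) - set(self.mapping.values())
        if extra:
            raise ValueError(f"short_set names {sorted(extra)} not in mapping values")


def short_isoform_ratio(
    matrix: CellIsoformMatrix, naming: IsoformNaming
) -> pd.Series:
    """Per-cell fraction of molecules whose pattern maps to a short isoform.

    Patterns without a name still count in the denominator (they are real
    molecules), only never in the numerator.
    """
    short_labels = [
        lab for lab in matrix.counts.columns
        if naming.mapping.get(lab) in naming.short_set
    ]
    short = matrix.counts[short_labels].sum(axis=1)
    total = matrix.counts.sum(axis=1)
    ratio = short / total
    ratio.name = "short_isoform_ratio"
    return ratio


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of per-cell values: fold change of means and
    a two-sided Welch t-test p-value. ``reportable`` is False when either
    group has fewer than the minimum cell count."""

    fold_change: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    reportable: bool


def compare_ratio_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    min_cells: int = 3,
) -> GroupComparison:
    """Compare per-cell ratios between two groups of cells.

    Fold change is mean(a)/mean(b); significance from a two-sided Welch
    t-test on per-cell values (unequal variances assumed). Groups smaller
    than ``min_cells`` are flagged not-reportable but still summarized.
    """
    nan = float("nan")
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    reportable = len(a) >= min_cells and len(b) >= min_cells
    mean_a = float(a.mean()) if len(a) else nan
    mean_b = float(b.mean()) if len(b) else nan
    if len(a) >= 2 and len(b) >= 2:
        if a.std() == 0 and b.std() == 0:
            # Welch statistic undefined at zero variance; identical constant
            # groups are maximally non-significant, distinct ones separated
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            p = float(ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = nan
    if mean_b != 0:
        fold = mean_a / mean_b
    else:
        fold = float("inf") if mean_a > 0 else nan
    return GroupComparison(
        fold_change=fold,
        p_value=p,
        mean_a=mean_a,
        mean_b=mean_b,
        n_a=len(a),
        n_b=len(b),
        reportable=reportable,
    )
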