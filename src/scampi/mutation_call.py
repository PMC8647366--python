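"""CRISPR indel genotyping inside cut-site analysis windows.

Classification follows a strict sequence-identity rule: a read is wild-type
only when the bases it aligns inside the 4-bp window perfectly match the
reference and no insertion or deletion touched the window; any
substitution, insertion or deletion within the window marks it mutated.
Reads that do not fully cover the window — and show no window-internal
deletion — are a third, UNINFORMATIVE class, so partial coverage never
biases rates (a deletion is kept as direct edit evidence even when it
removes the covered bases). Per-cell mutation rates are the MUT fraction of
informative reads, and target-vs-other contrasts use a two-sided Welch
t-test on those per-cell rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .alignments import WindowObservation

__all__ = [
    "MutationCall",
    "CellMutationRate",
    "classify_read",
    "per_cell_rates",
    "compare_target_vs_other",
]

WT = "WT"
MUT = "MUT"
UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class MutationCall:
    """Per-read genotype at one guide's analysis window."""

    read_id: str
    barcode: str | None
    guide: str
    status: str  # WT / MUT / UNINFORMATIVE
    evidence: str  # substitution / insertion / deletion / none


@dataclass(frozen=True)
class CellMutationRate:
    """MUT fraction of a cell's informative reads at one target site."""

    barcode: str
    guide: str
    n_reads: int
    rate: float


def classify_read(
    obs: WindowObservation,
    ref_window_seq: str,
    *,
    barcode: str | None = None,
    guide: str = "",
) -> MutationCall:
    """Classify one window observation as WT, MUT or UNINFORMATIVE.

    Priority: a deletion consuming any window position is MUT (even when it
    spans the whole window); otherwise a read must span and cover the window
    to be informative; then insertions, then substitutions, else WT.
    """
    if obs.has_deletion:
        status, evidence = MUT, "deletion"
    elif not (obs.spans and obs.covered):
        status, evidence = UNINFORMATIVE, "none"
    elif obs.n_insertions > 0:
        status, evidence = MUT, "insertion"
    elif obs.obs_seq != ref_window_seq:
        status, evidence = MUT, "substitution"
    else:
        status, evidence = WT, "none"
    return MutationCall(
        read_id=obs.read_id, barcode=barcode, guide=guide, status=status, evidence=evidence
    )


def per_cell_rates(calls: Sequence[MutationCall]) -> list[CellMutationRate]:
    """Aggregate per-read calls into per-(cell, target site) mutation rates.

    UNINFORMATIVE calls are excluded; cells with zero informative reads at a
    site are omitted. Output is sorted by (barcode, guide) so it is
    independent of call order.
    """
    tally: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        if call.barcode is None or call.status == UNINFORMATIVE:
            continue
        pair = tally.setdefault((call.barcode, call.guide), [0, 0])
        pair[1] += 1
        if call.status == MUT:
            pair[0] += 1
    return [
        CellMutationRate(barcode=bc, guide=g, n_reads=tot, rate=mut / tot)
        for (bc, g), (mut, tot) in sorted(tally.items())
    ]


def compare_target_vs_other(
    rates: Sequence[CellMutationRate],
    guide_assign: Mapping[str, str],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Contrast per-cell mutation rates between on-target and other cells.

    For each target site (guide) with rate measurements, cells whose
    assigned guide is that guide form the target group; cells assigned any
    other guide form the comparison group. Cells without a guide assignment
    are ignored. Returns one row per site with group means, fold and a
    two-sided Welch t-test p; rows with a group below ``min_cells`` are
    flagged not reportable.
    """
    rows = []
    guides = sorted({r.guide for r in rates})
    for guide in guides:
        target, other = [], []
        for r in rates:
            if r.guide != guide:
                continue
            assigned = guide_assign.get(r.barcode)
            if assigned is None:
                continue
            (target if assigned == guide else other).append(r.rate)
        reportable = len(target) >= min_cells and len(other) >= min_cells
        mean_t = float(np.mean(target)) if target else float("nan")
        mean_o = float(np.mean(other)) if other else float("nan")
        if len(target) >= 2 and len(other) >= 2:
            t = np.asarray(target)
            o = np.asarray(other)
            if t.std() == 0 and o.std() == 0:
                p = 1.0 if mean_t == mean_o else 0.0
            else:
                p = float(ttest_ind(t, o, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "guide": guide,
                "n_target_cells": len(target),
                "n_other_cells": len(other),
                "mean_target": mean_t,
                "mean_other": mean_o,
                "fold": mean_t / mean_o if mean_o else float("inf"),
                "p_value": p,
                "reportable": reportable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "guide",
            "n_target_cells",
            "n_other_cells",
            "mean_target",
            "mean_other",
            "fold",
            "p_value",
            "reportable",
        ],
    )
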