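import pytest

from conftest import make_read
from scampi.barcode_match import Molecule
from scampi.isoform_call import (
    ExonPattern,
    IsoformNaming,
    anchor_filter,
    build_matrix,
    call_exon_pattern,
    cluster_cells,
    compare_ratio_groups,
    parse_label,
    pattern_label,
    short_isoform_ratio,
)


class TestPatternLabel:
    def test_skip_exon5_worked_example(self):
        assert pattern_label({1, 2, 3, 4, 6, 7, 8}, 8) == "1234-678"

    def test_full_length_has_no_dash(self):
        assert pattern_label(set(range(1, 9)), 8) == "12345678"

    def test_each_skipped_run_collapses_to_one_dash(self):
        assert pattern_label({1, 4, 8}, 8) == "1-4-8"

    def test_label_roundtrip_exhaustive_over_anchored_subsets(self):
        """parse(label(S)) == S for all 64 subsets of an 8-exon gene that
        contain the first and last exon."""
        for middle in range(64):
            present = {1, 8} | {i + 2 for i in range(6) if middle >> i & 1}
            assert parse_label(pattern_label(present, 8)) == frozenset(present)

    def test_many_exon_gene_uses_separators(self):
        label = pattern_label({1, 10, 12}, 12)
        assert label == "1,-,10,-,12"
        assert parse_label(label) == frozenset({1, 10, 12})


def _blocks_read(blocks, read_id="r1"):
    """Build a read whose match blocks are exactly the given intervals."""
    parts = []
    prev_end = None
    start = blocks[0][0]
    for s, e in blocks:
        if prev_end is not None:
            parts.append(f"{s - prev_end}N")
        parts.append(f"{e - s}M")
        prev_end = e
    qlen = sum(e - s for s, e in blocks)
    return make_read("".join(parts), ref_start=start, seq="A" * qlen, read_id=read_id)


class TestCallExonPattern:
    # toy_gene: exon i occupies [200*(i-1), 200*(i-1)+100)

    def test_blocks_covering_all_but_exon5(self, toy_gene):
        blocks = [(200 * i, 200 * i + 100) for i in range(8) if i != 4]
        pat = call_exon_pattern(_blocks_read(blocks), toy_gene)
        assert pat.label == "1234-678"

    def test_full_coverage_full_length(self, toy_gene):
        blocks = [(200 * i, 200 * i + 100) for i in range(8)]
        assert call_exon_pattern(_blocks_read(blocks), toy_gene).label == "12345678"

    def test_overlap_threshold_edge(self, toy_gene):
        # 40% of exon 5 only -> absent at the default 50% threshold
        blocks = [(200 * i, 200 * i + 100) for i in range(4)] + [(800, 840)] + [
            (200 * i, 200 * i + 100) for i in range(5, 8)
        ]
        pat = call_exon_pattern(_blocks_read(blocks), toy_gene)
        assert 5 not in pat.present
        # exactly 50% counts as present
        blocks[4] = (800, 850)
        pat = call_exon_pattern(_blocks_read(blocks), toy_gene)
        assert 5 in pat.present

    def test_fragmenting_blocks_never_changes_the_pattern(self, toy_gene, rng):
        blocks = [(200 * i, 200 * i + 100) for i in range(8) if i not in (2, 4)]
        base = call_exon_pattern(_blocks_read(blocks), toy_gene)
        fragmented = []
        for s, e in blocks:
            mid = int(rng.integers(s + 1, e))
            fragmented.extend([(s, mid), (mid, e)])
        read = _blocks_read(blocks)
        read.blocks = fragmented  # fragmentation at the block level
        assert call_exon_pattern(read, toy_gene) == base


class TestAnchorFilter:
    def test_both_anchors_present_passes(self, toy_gene):
        pat = ExonPattern.from_present({1, 2, 3, 8}, 8)
        assert anchor_filter(pat, toy_gene)

    def test_missing_last_anchor_fails(self, toy_gene):
        pat = ExonPattern.from_present({1, 2, 3}, 8)
        assert not anchor_filter(pat, toy_gene)

    def test_truncation_missing_first_anchor_fails(self, toy_gene):
        pat = ExonPattern.from_present(set(range(2, 9)), 8)
        assert not anchor_filter(pat, toy_gene)


def _mols(spec):
    """spec: list of (barcode, pattern, count)"""
    out = []
    i = 0
    for bc, pat, n in spec:
        for _ in range(n):
            out.append(Molecule(bc, f"U{i:04d}", f"r{i}", pattern=pat))
            i += 1
    return out


class TestBuildMatrix:
    def test_proportions(self):
        m = build_matrix(_mols([("C1", "12345678", 9), ("C1", "1234-678", 1)]))
        assert m.proportions.loc["C1", "12345678"] == pytest.approx(0.9)
        assert m.proportions.loc["C1", "1234-678"] == pytest.approx(0.1)
        assert m.proportions.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_low_count_cell_dropped(self):
        m = build_matrix(_mols([("C1", "12345678", 4), ("C2", "12345678", 5)]))
        assert list(m.counts.index) == ["C2"]

    def test_molecule_order_invariance(self):
        spec = [("C1", "12345678", 6), ("C2", "1234-678", 7), ("C1", "1-8", 3)]
        mols = _mols(spec)
        a = build_matrix(mols)
        b = build_matrix(list(reversed(mols)))
        assert a.counts.equals(b.counts)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            m = build_matrix([])
        assert m.counts.empty


class TestClusterCells:
    def test_separable_subpopulations_recovered(self):
        mols = _mols(
            [(f"A{i:02d}", "12345678", 10) for i in range(10)]
            + [(f"B{i:02d}", "1234-678", 10) for i in range(10)]
        )
        m = build_matrix(mols)
        labels = cluster_cells(m, k=2)
        a_labels = {labels[f"A{i:02d}"] for i in range(10)}
        b_labels = {labels[f"B{i:02d}"] for i in range(10)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_identical_rows_degenerate_but_labelled(self):
        m = build_matrix(_mols([(f"C{i}", "12345678", 5) for i in range(4)]))
        with pytest.warns(UserWarning, match="degenerate"):
            labels = cluster_cells(m, k=2)
        assert len(labels) == 4

    def test_k_above_cell_count_rejected(self):
        m = build_matrix(_mols([("C1", "12345678", 5)]))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cells(m, k=2)


NAMING = IsoformNaming(
    mapping={"3-7": "RO", "34-7": "RB", "3-567": "RBC", "345-7": "RAB", "34567": "RABC"},
    short_set=frozenset({"RO", "RB"}),
)


class TestShortIsoformRatio:
    def test_ratio_arithmetic(self):
        mols = _mols([("C1", "3-7", 2), ("C1", "34-7", 1), ("C1", "34567", 7)])
        m = build_matrix(mols)
        assert short_isoform_ratio(m, NAMING)["C1"] == pytest.approx(0.3)

    def test_cell_without_short_isoforms_is_zero(self):
        m = build_matrix(_mols([("C1", "34567", 5)]))
        assert short_isoform_ratio(m, NAMING)["C1"] == 0.0

    def test_unmapped_patterns_count_in_denominator_only(self):
        mols = _mols([("C1", "3-7", 2), ("C1", "3--7", 8)])  # second has no name
        m = build_matrix(mols)
        assert short_isoform_ratio(m, NAMING)["C1"] == pytest.approx(0.2)

    def test_short_set_must_be_subset_of_names(self):
        with pytest.raises(ValueError, match="short_set"):
            IsoformNaming(mapping={"3-7": "RO"}, short_set=frozenset({"RX"}))

    def test_ko_shift_recovered_from_binomial_simulation(self, rng):
        """Two arms with true short fractions 0.6 and 0.3: group means land
        within +-0.03 of truth (binomial oracle, 200 cells/arm)."""
        for truth in (0.6, 0.3):
            counts = rng.binomial(30, truth, size=200)
            mols = []
            for c, k in enumerate(counts):
                mols.extend(_mols([(f"C{truth}{c:03d}", "3-7", int(k))]))
                mols.extend(_mols([(f"C{truth}{c:03d}", "34567", 30 - int(k))]))
            m = build_matrix(mols)
            est = short_isoform_ratio(m, NAMING).mean()
            assert abs(est - truth) < 0.03


class TestCompareRatioGroups:
    def test_identical_groups_fold_one_p_one(self):
        a = [0.2, 0.4, 0.6, 0.3]
        res = compare_ratio_groups(a, list(a))
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0.5, 0.05, size=50)
        b = a + 10.0
        res = compare_ratio_groups(a, b)
        assert res.p_value < 1e-6

    def test_simulated_twofold_difference_recovered(self, rng):
        """True fold 2.0 with realistic per-cell noise lands in [1.8, 2.2]."""
        a = rng.binomial(30, 0.6, size=200) / 30
        b = rng.binomial(30, 0.3, size=200) / 30
        res = compare_ratio_groups(a, b)
        assert 1.8 <= res.fold_change <= 2.2
        assert res.p_value < 1e-6

    def test_small_group_flagged_not_reportable(self):
        res = compare_ratio_groups([0.5, 0.6], [0.1, 0.2, 0.3])
        assert not res.reportable
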