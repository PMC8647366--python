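import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import cosine_kmer, exhaustive_best_barcode, levenshtein_recursive
from scampi.alignments import SearchSequence
from scampi.barcode_match import (
    BarcodeWhitelist,
    Molecule,
    build_reference_index,
    cosine_candidates,
    deduplicate,
    edit_distance,
    extract_umi,
    match_barcode,
    umi_distance_profile,
)
from scampi.simulate import PARTIAL_R1, simulate_whitelist

dna = st.text(alphabet="ACGT", max_size=12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(dna, dna)
def test_edit_distance_matches_recursive_definition(a, b):
    assert edit_distance(a, b) == levenshtein_recursive(a, b)


@pytest.mark.parametrize(
    "a,b,expected",
    [("ACGT", "ACGT", 0), ("ACGT", "AGGT", 1), ("", "ACGT", 4), ("AC", "", 2)],
)
def test_edit_distance_examples(a, b, expected):
    assert edit_distance(a, b) == expected


class TestWhitelist:
    def test_length_and_alphabet_enforced(self):
        with pytest.raises(ValueError, match="16 bp"):
            BarcodeWhitelist(("ACGT",))
        with pytest.raises(ValueError, match="non-ACGT"):
            BarcodeWhitelist(("ACGTNCGTACGTACGT",))

    def test_duplicates_rejected(self):
        bc = "ACGTACGTACGTACGT"
        with pytest.raises(ValueError, match="duplicate"):
            BarcodeWhitelist((bc, bc))

    def test_load_strips_gem_group_suffix(self, tmp_path):
        p = tmp_path / "wl.txt"
        p.write_text("ACGTACGTACGTACGT-1\nTTTTACGTACGTACGT\n")
        wl = BarcodeWhitelist.load(p)
        assert wl.barcodes == ("ACGTACGTACGTACGT", "TTTTACGTACGTACGT")


class TestKmerIndex:
    def test_homopolymer_barcode_has_one_token_counted_nine_times(self):
        wl = BarcodeWhitelist(("A" * 16,))
        idx = build_reference_index(wl, k=8)
        assert idx.vocab_size == 1
        raw = idx.vectorizer.transform(["A" * 16]).toarray()
        assert raw[0, 0] == 9

    def test_every_barcode_contributes_nine_tokens(self, rng):
        wl = simulate_whitelist(20, rng=rng)
        idx = build_reference_index(wl)
        raw = idx.vectorizer.transform(wl.barcodes).sum(axis=1)
        assert (np.asarray(raw).ravel() == 9).all()

    def test_k_above_barcode_length_rejected(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            build_reference_index(simulate_whitelist(5, rng=rng), k=17)


class TestCosineCandidates:
    def test_verbatim_barcode_ranks_first(self, rng):
        wl = simulate_whitelist(100, rng=rng, min_pairwise_dist=5)
        idx = build_reference_index(wl)
        target = wl.barcodes[37]
        seq = "ACGTACGTACGTACGTACGTAC" + target + "TTTTTTTTTT"
        cands = cosine_candidates(SearchSequence("r", seq, "left_clip"), idx)
        assert cands[0].barcode == target
        # brute-force cosine over every whitelist row agrees on the winner
        brute = max(wl.barcodes, key=lambda bc: cosine_kmer(seq, bc))
        assert brute == target

    def test_cosine_values_match_raw_kmer_cosine(self, rng):
        wl = simulate_whitelist(50, rng=rng)
        idx = build_reference_index(wl)
        seq = "ACGT" * 10
        for cand in cosine_candidates(SearchSequence("r", seq, "left_clip"), idx):
            assert cand.cosine == pytest.approx(cosine_kmer(seq, cand.barcode))

    def test_no_shared_kmers_gives_empty_list(self, rng):
        wl = simulate_whitelist(10, rng=rng)
        idx = build_reference_index(wl)
        assert cosine_candidates(SearchSequence("r", "N" * 40, "left_clip"), idx) == []

    def test_exact_barcode_alone_scores_cosine_one(self, rng):
        wl = simulate_whitelist(10, rng=rng)
        idx = build_reference_index(wl)
        cands = cosine_candidates(SearchSequence("r", wl.barcodes[3], "left_clip"), idx)
        assert cands[0].barcode == wl.barcodes[3]
        assert cands[0].cosine == pytest.approx(1.0)

    def test_short_sequence_gives_empty_list(self, rng):
        wl = simulate_whitelist(10, rng=rng)
        idx = build_reference_index(wl)
        assert cosine_candidates(SearchSequence("r", "ACGTACG", "left_clip"), idx) == []


def _search(seq):
    return SearchSequence("read1", seq, "left_clip")


@pytest.fixture(scope="module")
def wl_index():
    wl = simulate_whitelist(200, seed=99, min_pairwise_dist=7)
    return wl, build_reference_index(wl)


class TestMatchBarcode:

    def test_error_free_construct_matches_at_adapter_offset(self, wl_index):
        wl, idx = wl_index
        bc = wl.barcodes[11]
        seq = PARTIAL_R1 + bc + "ACGTACGTAC" + "TTTCTT"
        m = match_barcode(_search(seq), idx, expected_offset=22)
        assert m.barcode == bc
        assert m.edit_distance == 0
        assert m.bc_start == 22
        assert m.expected_pos_dev == 0
        assert m.umi == "ACGTACGTAC"

    def test_two_substitutions_still_match(self, wl_index):
        wl, idx = wl_index
        bc = wl.barcodes[42]
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # errors at the ends keep interior 8-mers intact for cosine retrieval
        corrupted = "".join(sub[ch] if i in (0, 15) else ch for i, ch in enumerate(bc))
        assert edit_distance(corrupted, bc) == 2
        seq = PARTIAL_R1 + corrupted + "ACGTACGTAC"
        m = match_barcode(_search(seq), idx)
        assert m.barcode == bc and m.edit_distance == 2
        # exhaustive whitelist x window minimum confirms uniqueness
        d, best = exhaustive_best_barcode(seq, wl.barcodes, edit_distance)
        assert (d, best) == (2, bc)

    def test_three_substitutions_rejected(self, wl_index):
        wl, idx = wl_index
        bc = wl.barcodes[7]
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        corrupted = "".join(
            sub[ch] if i in (2, 8, 14) else ch for i, ch in enumerate(bc)
        )
        seq = PARTIAL_R1 + corrupted + "ACGTACGTAC"
        m = match_barcode(_search(seq), idx)
        assert m.barcode is None
        d, _ = exhaustive_best_barcode(seq, wl.barcodes, edit_distance)
        assert d >= 3  # min pairwise distance 7 keeps other barcodes far

    def test_short_search_sequence_is_unmatched_with_sentinel(self, wl_index):
        _, idx = wl_index
        m = match_barcode(_search("ACGTACGTACG"), idx)
        assert m.barcode is None and m.edit_distance == math.inf

    def test_accepted_matches_always_below_threshold(self, wl_index, rng):
        wl, idx = wl_index
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            m = match_barcode(_search(seq), idx, accept_lt=3)
            if m.barcode is not None:
                assert m.edit_distance < 3

    def test_match_table_independent_of_read_order(self, wl_index, rng):
        wl, idx = wl_index
        seqs = [
            PARTIAL_R1 + wl.barcodes[i] + "".join(rng.choice(list("ACGT"), size=12))
            for i in range(20)
        ]
        forward = [match_barcode(_search(s), idx) for s in seqs]
        backward = [match_barcode(_search(s), idx) for s in reversed(seqs)]
        assert forward == backward[::-1]


class TestUmi:
    def test_umi_taken_after_matched_window(self):
        seq = "X" * 22 + "A" * 16 + "CCCCCCCCCC" + "G" * 5
        match_stub = type("M", (), {"bc_start": 22, "barcode": "A" * 16})
        umi = extract_umi(SearchSequence("r", seq, "left_clip"), match_stub)
        assert umi == "CCCCCCCCCC"

    def test_truncated_search_returns_null_umi(self):
        seq = "X" * 22 + "A" * 16 + "CC"
        match_stub = type("M", (), {"bc_start": 22, "barcode": "A" * 16})
        assert extract_umi(SearchSequence("r", seq, "left_clip"), match_stub) is None


class TestDeduplicate:
    def test_exact_duplicates_collapse_keeping_first(self):
        mols = [
            Molecule("B1", "U1", "r1"),
            Molecule("B1", "U1", "r2"),
            Molecule("B1", "U2", "r3"),
        ]
        kept = deduplicate(mols)
        assert [(m.barcode, m.umi, m.read_id) for m in kept] == [
            ("B1", "U1", "r1"),
            ("B1", "U2", "r3"),
        ]

    def test_same_umi_in_different_cells_is_not_a_duplicate(self):
        mols = [Molecule("B1", "U1", "r1"), Molecule("B2", "U1", "r2")]
        assert len(deduplicate(mols)) == 2

    def test_near_miss_umis_are_both_retained(self):
        mols = [Molecule("B1", "AAAAAAAAAA", "r1"), Molecule("B1", "AAAAAAAAAT", "r2")]
        assert len(deduplicate(mols)) == 2  # no fuzzy collapse

    def test_null_umi_records_excluded(self):
        mols = [Molecule("B1", None, "r1"), Molecule("B1", "U1", "r2")]
        kept = deduplicate(mols)
        assert len(kept) == 1 and kept[0].umi == "U1"

    def test_idempotent(self):
        mols = [Molecule("B1", "U1", "r1"), Molecule("B1", "U1", "r2")]
        once = deduplicate(mols)
        assert deduplicate(once) == once


class TestUmiDistanceProfile:
    def test_single_pair_at_distance_ten(self):
        mols = [Molecule("B1", "AAAAAAAAAA", "r1"), Molecule("B1", "TTTTTTTTTT", "r2")]
        pooled, per_cell = umi_distance_profile(mols)
        assert pooled == {10: 1}
        assert per_cell["B1"] == {10: 1}

    def test_single_umi_has_no_pairs(self):
        pooled, per_cell = umi_distance_profile([Molecule("B1", "AAAAAAAAAA", "r1")])
        assert pooled == {} and per_cell == {}

    def test_random_umis_mode_matches_exhaustive_pairs(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(60)]
        mols = [Molecule("B1", u, f"r{i}") for i, u in enumerate(set(umis))]
        pooled, _ = umi_distance_profile(mols)
        # exhaustive recomputation
        from itertools import combinations

        expected = {}
        for a, b in combinations([m.umi for m in mols], 2):
            d = levenshtein_recursive(a, b)
            expected[d] = expected.get(d, 0) + 1
        assert dict(pooled) == expected
        # random 10-mers are far apart: few pairs below 3 edits
        n_close = sum(v for k, v in pooled.items() if k < 3)
        assert n_close <= 0.01 * sum(pooled.values())
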