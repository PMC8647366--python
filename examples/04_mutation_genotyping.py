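"""Genotype CRISPR indels at the guide cut site, per read and per cell.

A read is wild-type only when its bases inside the 4-bp window around the
blunt cut perfectly match the reference; any substitution, insertion or
deletion marks it mutated. Per-cell mutation rates are then contrasted
between cells carrying the targeting guide and all other cells. Run
01_simulate_dataset.py first.
"""

import pysam

from scampi import (
    BarcodeWhitelist,
    analysis_window,
    build_reference_index,
    classify_read,
    compare_target_vs_other,
    cut_site,
    extract_search_sequence,
    load_gene_model,
    load_guide_assignments,
    load_guides,
    match_barcode,
    per_cell_rates,
    read_alignments,
    window_bases,
)

gene = load_gene_model("example_data/gene_model.json")
index = build_reference_index(BarcodeWhitelist.load("example_data/whitelist.txt"))
(guide,) = load_guides("example_data/guides.tsv")

with pysam.FastxFile("example_data/ref.fasta") as fh:
    ref = {entry.name: entry.sequence.upper() for entry in fh}[guide.chrom]

window = analysis_window(cut_site(guide), flank=2, chrom=guide.chrom, guide=guide.name)
ref_window = ref[window.start : window.end]
print(f"guide {guide.name}: cut at {cut_site(guide)}, window [{window.start},{window.end})")

calls = []
for read in read_alignments("example_data/reads.sam"):
    m = match_barcode(extract_search_sequence(read, gene), index)
    if m.barcode is None:
        continue
    obs = window_bases(read, window)
    calls.append(classify_read(obs, ref_window, barcode=m.barcode, guide=guide.name))

rates = per_cell_rates(calls)
assignments = {a.barcode: a.guide for a in load_guide_assignments("example_data/guide_assignments.tsv")}
summary = compare_target_vs_other(rates, assignments)
row = summary.iloc[0]
print(f"cells with rates:     {len(rates)}")
print(f"mean rate, target:    {row.mean_target:.3f}  (n={row.n_target_cells})")
print(f"mean rate, other:     {row.mean_other:.3f}  (n={row.n_other_cells})")
print(f"Welch t-test p-value: {row.p_value:.3g}")
# Cells whose captured guide targets this site show a much higher fraction
# of mutated reads than cells carrying other guides.
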