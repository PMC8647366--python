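"""Generate a small synthetic targeted single-cell long-read experiment.

Writes a complete bundle — reference FASTA, coordinate-sorted SAM with
soft-clipped 10x 5' constructs, barcode whitelist, gene model, guide table,
per-read truth, guide assignments and an MTX expression matrix — under
./example_data/. Every later example reads from this directory.
"""

from scampi import SimConfig, simulate_experiment

config = SimConfig(seed=42, n_cells=60, whitelist_size=300, mean_molecules_per_cell=12)
bundle = simulate_experiment(config, "example_data")

print(f"cells:          {len(bundle.cells)}")
print(f"reads:          {len(bundle.reads)}")
print(f"gene:           {bundle.gene.name} ({bundle.gene.n_exons} exons, strand {bundle.gene.strand})")
print(f"guide cut site: {bundle.guides[0].name}")
print(f"output:         {bundle.out_dir}/")
# The read counts are molecules plus ~5% PCR duplicates; the two cell groups
# ("edited" with predominant exon-5 skipping and cut-site indels, "unedited"
# with mostly full-length transcripts) are recorded in cells.tsv.
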