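# scampi

**S**ingle-**c**ell **amp**licon **i**soforms: analysis of targeted nanopore
sequencing of single-cell cDNA, for experiments that read out CRISPR edits
directly in full-length transcripts.

## The problem

Droplet-based single-cell RNA-seq reads only the ends of each cDNA, so it
cannot see transcript structure: which exons a molecule retained, or whether
a CRISPR edit actually landed in it. Amplifying a target gene's cDNA from a
10x 5' library and nanopore-sequencing the intact molecules fixes that — a
single long read spans the whole transcript — but creates a new analysis
problem: each read must be traced back to its cell of origin through a
16-bp cell barcode read at nanopore error rates.

`scampi` implements that analysis end to end:

1. **Barcode demultiplexing from soft clips.** The 10x construct
   (22-nt adapter + 16-bp barcode + 10-bp UMI) does not align to the genome
   and survives as a soft clip. The clip (left clip for a plus-strand gene,
   reverse-complemented right clip for a minus-strand gene) is vectorized
   as overlapping 8-mer counts and ranked against the short-read barcode
   whitelist by cosine similarity. For the top 5 candidates with non-zero
   cosine, the Levenshtein distance is computed against every 16-bp window
   of the clip; the candidate with the global minimum distance wins (ties:
   higher cosine, then whitelist order) and is accepted only below 3 edits.
2. **UMI deduplication.** The 10 bp after the matched barcode window are
   the UMI; molecules with identical (barcode, UMI) are collapsed (exact
   match only — targeted amplicons make per-cell UMI space sparse enough
   that fuzzy collapsing is unnecessary).
3. **Isoform exon patterns.** From the alignment's match blocks, exon *e*
   is called present when ≥ 50% of its length is covered; patterns are
   labeled like `1234-678` (a transcript skipping exon 5 of an 8-exon
   gene). Reads must cover both anchor exons (e.g. 1 and 8 for RACK1, 3 and
   7 for PTPRC) to filter truncation artifacts. Per-cell pattern
   proportions feed complete-linkage hierarchical clustering and
   short-isoform ratio statistics (e.g. the RO+RB fraction of PTPRC).
4. **CRISPR indel genotyping.** For each guide, a 4-bp window (± 2 bp
   around the SpCas9 blunt cut, 3 bp 5' of the PAM) is inspected: a read is
   wild-type only if its aligned bases match the reference perfectly with
   no insertion or deletion touching the window; otherwise it is mutated;
   reads not covering the window are uninformative. Per-cell mutation
   rates are contrasted between cells carrying the targeting guide and all
   others with a two-sided Welch *t*-test.
5. **Integration.** Everything joins on the 16-bp barcode with per-cell
   guide assignments and MTX expression matrices from short-read
   processing; single-gene expression contrasts use
   ln(1 + 10⁴·count/total) normalization.

A first-class simulator (`scampi.simulate`) generates complete synthetic
experiments — whitelists, error-corrupted reads with truth-aware CIGARs,
guide assignments, negative-binomial expression — with a truth table for
every read, and drives the whole test suite.

## Worked example

```bash
cd examples
python 01_simulate_dataset.py     # writes example_data/
python 02_barcode_matching.py
python 03_isoform_patterns.py
python 04_mutation_genotyping.py
```

Output of `02_barcode_matching.py` (seed 42, 60 cells, 750 reads at
nanopore-like error rates of 3%/2%/2% sub/ins/del):

```
reads evaluated:     750
assigned to a cell:  586 (78.1%)
mean edit distance:  0.867
mean position dev.:  0.691 bases
```

78% of reads are confidently assigned to a cell; accepted matches average
under one edit from their whitelist barcode, and the matched barcode sits
on average 0.7 bases from where the adapter construct predicts it. Reads
whose barcode region accumulated ≥ 3 edits are discarded rather than
guessed. `03_isoform_patterns.py` then separates the two simulated
subpopulations perfectly (one cluster at 95% full-length `12345678`
molecules, the other at 15%), and `04_mutation_genotyping.py` prints

```
mean rate, target:    0.711  (n=30)
mean rate, other:     0.297  (n=30)
Welch t-test p-value: 4.86e-13
```

— on-target cells show edits in ~71% of reads versus a sequencing-noise
background of ~30% in the 4-bp window (with per-base error rate *e* ≈ 0.07,
a fraction ≈ 1 − (1−*e*)⁴ of truly unedited reads shows an apparent change).

The same pipeline is available as a CLI:

```bash
scampi simulate --out sim --seed 1
scampi run --bam sim/reads.sam --whitelist sim/whitelist.txt \
    --gene-model sim/gene_model.json --guides sim/guides.tsv \
    --ref-fasta sim/ref.fasta --guide-table sim/guide_assignments.tsv \
    --out results/
```

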