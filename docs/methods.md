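# Methods

This note documents the models, parameters and numerical choices behind
`scampi`, and what its synthetic-data tests do and do not demonstrate.

## Barcode matching

Reads are assigned to cells by a two-stage search over the soft-clipped
construct sequence (oriented adapter → barcode → UMI; for minus-strand
genes this means reverse-complementing the right clip).

**Candidate ranking.** Whitelist barcodes and the search sequence are
vectorized as counts of overlapping 8-mers (each 16-bp barcode contributes
exactly 9 token occurrences) and compared by cosine similarity; the top 5
whitelist entries with strictly positive cosine become candidates. Raw
counts are the default; an optional idf weighting (smoothed inverse
document frequency over the whitelist) is available behind the
`use_idf` flag for users who prefer the tf-idf formulation — on 16-bp
barcodes with a near-uniform 8-mer vocabulary the two rankings rarely
differ.

**Windowed refinement.** Each candidate is compared by unit-cost
Levenshtein distance against every 16-bp window of the search sequence
(step 1). The winner has the global minimum distance; ties resolve to the
higher cosine, then to whitelist order, and within one candidate to the
leftmost window — making the output deterministic and independent of read
order. A match is accepted only when the minimum distance is strictly
below `accept_lt = 3`.

Two properties of this scheme are worth knowing. First, an indel inside
the barcode changes the length of the true barcode image, so a fixed 16-bp
window pays roughly two edits per indel (the missing/extra base plus a
flank base); at realistic nanopore rates a substantial minority of reads
therefore exceeds the acceptance threshold and is discarded — by design,
the method prefers dropping a read to guessing its cell. Second, two
well-placed errors can destroy all nine 8-mers of the true barcode, giving
it zero cosine and excluding it from candidates; when another whitelist
entry happens to tie at the same minimal distance, the documented cosine
tie-break decides. Both behaviors are exercised by the test suite.

**Parameters.** `k = 8` (token length), `top_n = 5`, `accept_lt = 3`,
`umi_len = 10`, adapter offset 22 nt (the partial read-1 primer); all
configurable. UMI extraction takes the `umi_len` bases immediately after
the matched window's end; deduplication is exact-match on (barcode, UMI),
keeping the first record — no directional UMI networks, which would be
overkill for the sparse per-cell UMI space of a single amplified gene.

## Isoform calling

Exon presence is decided per exon as
(bases of alignment-match blocks inside the exon) / (exon length) ≥
`min_overlap_frac = 0.5`. The threshold absorbs nanopore indel noise at
junctions while still rejecting marginal carry-over alignments; it is
configurable and recorded in the run manifest. Pattern labels concatenate
retained exon ordinals and collapse each maximal run of skipped exons to a
single dash (`1234-678`); for genes with more than 9 exons, ordinals are
comma-separated to stay unambiguous. Reads must retain both anchor exons
to be counted, which removes reverse-transcription truncations and PCR
artifacts.

Cells with fewer than `min_molecules_per_cell = 5` deduplicated molecules
are dropped from the matrix — below that, per-cell proportions are too
noisy to cluster. Clustering is agglomerative with Euclidean distance and
complete linkage on proportion rows (the defaults of the common clustered
heatmap tools), cut into a user-chosen number of flat clusters; the
cluster count is an experiment-level choice, not a fitted quantity.
Patterns carrying < 0.5% of all molecules can be pooled into an "other"
column for clustering input only; raw counts always keep full labels.
Identical proportion rows make any cut degenerate; the operation still
returns labels and warns.

Group comparisons of per-cell quantities (short-isoform ratios, mutation
rates, normalized expression) all use the fold change of group means and a
two-sided Welch *t*-test; unequal variances are the safe default for
per-cell summaries, and groups under 3 cells are flagged not reportable
rather than silently tested.

## Indel genotyping

The SpCas9 blunt cut sits 3 bp 5' of the PAM (configurable for other
nucleases); the analysis window is `[cut − flank, cut + flank)` with
`flank = 2`, i.e. 2 bp on each side of the cut. "Around the cleavage site"
is interpreted symmetrically; the flank is a parameter for users who want
a different window. Classification is strict sequence identity:
wild-type requires the read to span and cover the window with bases equal
to the reference and no insertion or deletion touching it. A deletion
consuming any window position is mutant evidence even when it removes
coverage (a spanning deletion is the clearest possible edit); insertions
count as inside the window when their inter-base anchor lies on either
boundary, favoring sensitivity at the cut. Reads that do not fully cover
the window without such a deletion are a third class, UNINFORMATIVE, and
are excluded from rates instead of being silently counted as wild-type —
this keeps per-cell rates unbiased when coverage varies. Base qualities
are ignored; the rule is sequence-only.

In a 4-bp window with i.i.d. per-base error rate *e*, a truly unedited
read is misclassified as mutant with probability ≈ 1 − (1−*e*)⁴. At the
simulator defaults (*e* ≈ 0.07 summed across error types) this is a ~25%
apparent background — which is why the target-vs-background contrast, not
the absolute rate, is the meaningful readout on noisy data.

## Integration

All joins are keyed by the 16-bp barcode with `-1`-style gem-group
suffixes stripped. Guide assignment keeps a cell's top-support guide when
it has ≥ 3 supporting UMIs and ≥ 80% of the cell's guide UMIs (ties imply
purity ≤ 0.5 and leave the cell unassigned); these thresholds are this
package's choices, exposed as parameters. Expression uses library-size
normalization to 10⁴ with log1p. The fold change is computed on the
de-logged scale (ratio of group means of 10⁴·count/total), which is
unbiased for a mean shift, while the *t*-test runs on the log-normalized
values where per-cell noise is closer to symmetric. Genome-wide
differential expression is out of scope; only single-gene contrasts are
provided.

## The simulator

The generator emulates: the 10x 5' read structure (22-nt partial read-1
adapter, 16-bp whitelist barcode, 10-bp UMI, a TSO-like spacer, then
cDNA); exon-skipping isoform mixtures that differ between cell
subpopulations; CRISPR indels (sizes −3..+2 by default) injected at the
guide cut with a per-read probability per group; i.i.d. per-base
substitution/insertion/deletion errors at 0.03/0.02/0.02 — a simple but
analytically tractable stand-in for nanopore noise; ~5% PCR duplicates
sharing barcode/UMI/pattern truth with independent errors; and
negative-binomial expression counts (dispersion 0.1) with a configurable
single-gene fold between groups. The default two-arm design mirrors a
splice-site editing experiment: an edited arm (80% exon-5-skipping
molecules, per-read edit probability 0.64 at the cut) versus an unedited
arm (95% full-length), with the target gene 1.5-fold higher in unedited
cells.

Alignments are written with truth-aware CIGARs (soft-clipped construct,
exon match blocks separated by reference skips, errors folded in as
M/I/D operations) rather than by running an external aligner, keeping
tests hermetic and byte-reproducible: all randomness flows from one seed.

What the simulator does **not** model — and what passing tests therefore
do not show about real data: homopolymer-dependent nanopore error
structure (real indels cluster in homopolymers, so real barcode recovery
differs from the i.i.d. prediction), PCR chimeras, ambient RNA
contamination across droplets, variable per-cell amplification depth
beyond a Poisson molecule count, and reads mapping to the wrong locus.
The toy gene (8 exons of 120–160 bp) reproduces the ~1.1 kb amplicon
scale but not real exon-size or splice-site sequence context. The
expression panel holds 200 background genes so that the highly expressed
target gene stays a small fraction (~5%) of each cell's library —
otherwise library-size normalization itself would absorb part of any
single-gene fold change.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on synthetic data at
desk scale: ~5,000 reads for noisy barcode matching, 100 cells × 30 reads
for the mutation contrast, 300 cells for clustering recovery, 1,000 cells
for the expression contrast, and exhaustive enumerations (all 64
anchored exon subsets; 200 random string pairs against the textbook
Levenshtein recursion) where the space is small enough to enumerate. The
exhaustive barcode oracle uses an infix-alignment lower bound to prune
candidates; the bound can never exclude the true minimum, so the search
stays exact. Proportion rows are validated to sum to 1 within 1e−9;
Welch tests on two zero-variance groups (undefined statistic) return
p = 1 for equal means and p = 0 otherwise, with the case noted in output.

## Known limitations

Barcode rescue only uses soft-clipped sequence; reads whose construct was
hard-clipped or aligned in the unexpected orientation are counted and
excluded rather than recovered. No fuzzy UMI collapse means residual
duplicates at UMI sequencing-error rates (~a few percent) survive; the
paper-style exact rule was chosen deliberately. Indel alleles are
classified, not reconstructed — no size spectrum or microhomology
analysis. Multi-gene panels run as independent per-gene analyses; there is
no joint model across target genes.
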