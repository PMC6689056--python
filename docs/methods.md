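# Methods

`scbcr` re-implements a complete single-cell B-cell-receptor sequencing
(scBCR-seq) analysis stack: from barcoded paired-end reads to accurately
paired, full-length heavy/light variable regions per cell, then lineage
clustering and repertoire statistics. A ground-truthed simulator makes every
stage testable without sequencing data. This note documents the models,
parameters, numerical choices and limitations.

## Library model and simulator

The simulator emulates 5'-barcoded droplet libraries in which VH/VL
amplicons are sheared at the 3' end after amplification: all fragments of a
transcript share the transcript 5' start and have variable 3' ends, so
short paired-end reads can reconstruct the full variable region. Read 1 is
a fixed 39 nt tag — 16 nt cell barcode, 10 nt UMI, 13 nt switch oligo —
followed by the fragment 5' insert; read 2 is the reverse complement of the
fragment 3' end. Reads are 2 x 150 nt.

**Germline reference.** Synthetic V segments are 297 nt (97 aa of
FR1/CDR1/FR2/CDR2/FR3 in a fixed column layout plus a 6 nt CDR3 stub),
derived from a common stop-free ancestor with a conserved FR3-terminal
cysteine; per-gene substitution loads are drawn and then locally repaired
until every pairwise nucleotide identity lies inside a configurable range,
0.70–0.95 by default, mimicking the family structure of human IGHV. J
segments are 42 nt (9 nt CDR3 tail + 33 nt FR4 opening with the conserved
Trp/Phe codon); heavy references carry short random D cores. The synthetic
reference stands in for a curated germline database and cannot reproduce a
real species' family structure; only its statistical shape (pairwise
identity range, segment lengths, conserved anchors) is controlled.

**Recombination and SHM.** Each lineage draws one V(D)J recombination per
chain with junctional trimming (0–6 nt of the V stub and J tail, chosen
values — the underlying biology is unquantified here), N additions (0–10 nt
per junction), a frame-preserving pad, and rejection of junctions creating
stop codons. Lineage members accrue independent point substitutions at a
Poisson rate per chain (`shm_rate`; naive mode 1.0, antigen-experienced
12.0), placed at distinct sites with CDR columns weighted 3x the framework
rate (configurable; the bias factor is a design default, not a measured
value) and resampled when they would create a stop. Per-lineage cell counts
follow a Dirichlet-multinomial composition (concentration 0.3) unless an
explicit size distribution is supplied. With `distinct_cdr3` (default),
lineages sharing both V genes are resampled until their CDR-H3s fall
clearly below the 80% clustering threshold, making ground-truth lineages
recoverable by construction.

**Read depths and noise.** Per-cell read counts are Poisson with means 50
(heavy) and 300 (light); the light-over-heavy asymmetry mirrors the strong
per-chain depth imbalance of real libraries. Fragment 3' ends are uniform
between the read length and the transcript end (variable region plus a
255 nt constant-region stub, giving ~600 nt transcripts and a mean
concordant insert near 600). Sequencing errors are uniform substitutions at
0.001/base; ambient (non-cell) barcodes receive 2% of reads with geometric
per-barcode counts — enough to exercise the rank cutoff, with no attempt at
a full droplet-occupancy model. The simulator does not model PCR
duplicates, UMI structure beyond the tag, quality-score variation, indel
errors, isotypes, or lambda light chains (kappa-like light chains only by
default). Passing tests therefore demonstrate correctness of the
computational contracts, not robustness to every artefact of real data.

**Germline-call benchmark.** 2000 random heavy recombinants are each
mutated cumulatively: at every load 1..40 one previously untouched site is
substituted (CDR-biased, stop-free, never reverting), emitting one record
per (base, load). The load-m variant therefore differs from its recombinant
at exactly m sites, every record is in frame and stop-free, and the total
is exactly 2000 x 40 = 80,000. Substitutions are uniform over the three
alternative bases; no transition/transversion bias is applied.

## Cell calling and demultiplexing

Barcode read counts are ranked descending; the cutoff is 0.1x the count at
the rank equal to 2.5% of the targeted cell number (rounded, minimum 1;
rank 150 for 6000 targeted cells, i.e. the 97.5th percentile), and barcodes
strictly above the cutoff are called. The 2.5% rule generalises the standard
6000-cell / rank-150 instance to arbitrary target cell numbers. Demultiplexing requires perfect barcode
matches (no mismatch rescue); a whitelist is optional, defaulting to all
observed barcodes. Bins above 100,000 pairs are uniformly downsampled. UMIs
are carried through but not used for deduplication.

## Assembly and concordant-pair support

Per-barcode reads (read 2 reverse-complemented) are assembled by a
deterministic greedy overlap assembler: k-mer-seeded (k=21) overlaps of
>= 25 nt, extension by highest overlap first, ties broken by lexicographic
read id. Overlaps tolerate one substitution by default
(`max_mismatch_in_overlap=1`): with exact-only overlaps, a single read
error incorporated at the growing tip blocks all further exact extensions
and fragments the assembly at realistic error rates. Contigs are then
polished by per-position majority vote over approximately placed reads
(edlib, substitution placements only), and polished contigs that align
within a longer contig at <= 3 edits are merged so redundant assembly paths
do not double-count read-pair support. With error-free reads tiling a
transcript at >= 25 nt adjacent overlaps, the transcript is reconstructed
exactly and polishing is a no-op.

A read pair is concordant when both mates occur as exact full-length
substrings of the contig in forward–reverse orientation with an implied
insert (read-1 start to read-2 end) within 600 +/- 300 nt; the tolerance is
a design choice around the expected mean insert size. Contigs without concordant pairs
are discarded; the rest are trimmed to the contiguous positive-coverage
island containing the most pairs (ties: longer island, then leftmost).
Coordinates are 0-based half-open internally.

## Annotation

Chain identity is decided by a position-specific log-odds profile (one per
chain) built from the aligned germline V amino-acid sequences, scored in
bits against a uniform background. Because the synthetic germlines are
column-aligned by construction and V-domain indels outside CDR3 are not
modelled, the profile alignment is gapless: the best-scoring contiguous
diagonal segment over all six reading frames. CDR3-length variation is
handled by the junction-aware partition, so insertions in CDR3 do not
perturb framework boundaries. The acceptance threshold is 30 score units
(inclusive), calibrated so that random nucleotide sequences score below it
(empirically, 100/100 random 350-mers score < 30 while germline domains
score > 250); the unit is not transferable to other profile
implementations, only the threshold's role is preserved.

Framework/CDR boundaries come from the profile's fixed column map; CDR3
runs from the column after the conserved FR3-terminal cysteine to the FR4
start located via the J alignment, and is kept a whole number of codons.
Residue numbering is profile-column numbering; insertion-code lettering is
out of scope (CDR boundaries, the only downstream consumer, are
preserved). Germline V and J calls are the highest-scoring local alignments
(biopython PairwiseAligner; match +2, mismatch -2, gap open -3, extend -1,
all configurable; ties go to the lexicographically lower gene name). A
domain is complete when all of FR1 is present and the first four FR4
codons match the assigned J without frameshift. SHM is the mismatch count
against the assigned V germline over FR1..FR3 only (each gap run counts
one); CDR3 and J-derived positions are excluded. D segments are not called.

## Pairing and quality filters

Per cell, the complete heavy and light domain with the most concordant
pairs is reported (kappa and lambda compete in one light class; ties by
profile score, then contig id). Certainty is the top contig's concordant
pairs divided by the concordant pairs of all chain-identified contigs of
that class — including incomplete ones, the conservative reading, since
contamination usually assembles incompletely. Filters (all inclusive): top
heavy >= 10 pairs, top light >= 100 pairs, certainty >= 0.8 for both.

## Lineages and repertoire statistics

Lineages are connected components under: identical V_H and V_L gene
(alleles ignored), identical CDR-H3 nucleotide length, and >= 80% CDR-H3
identity (equal lengths, so Hamming). Single linkage realises the pairwise
grouping rule as its transitive closure. J genes are ignored. Expanded
means size >= 2.

Light-chain concordance — the pairing-accuracy proxy — groups cells by
exact (V_H gene, CDR-H3) match, restricts to multi-cell groups, and scores
the modal V_L gene; this is deliberately distinct from the 80% lineage
rule. Gene usage is tallied per lineage. Pairing enrichment compares each
observed (V_H, V_L) count with the independence expectation
N·f(V_H)·f(V_L) via a one-sided binomial exceedance p-value and
Benjamini–Hochberg adjustment, with the observed/expected ratio exposed
directly. With plug-in marginal estimates the test is conservative (the
expectation co-varies with the observed count); known generating margins
can be supplied for calibration studies, where the null rejection rate at
p<0.05 is ~5%. Usage tables are compared by Spearman rank correlation over
the gene union (absent = 0). Cells can be matched against a reference
panel of VH–VL pairs by total nucleotide mismatches over both chains,
anchored at FR1 with 3' truncation tolerated (length differences beyond
10% of the reference are non-comparable); classes are exact (0), near
(1–2) and unmatched.

## Problem sizes used in tests

The shipped tests run the full pipeline on a 200-cell clean simulation
(no errors, no SHM, 2% ambient reads), benchmark germline calls on 200
base recombinants at load 40, SHM recovery on 500 cells, and enrichment
calibration on 20 x 2000 simulated lineage tables; the acceptance script
runs the benchmark generator at its full 2000 x 40 scale. These sizes were
chosen so the whole suite completes in a few minutes on one CPU while
leaving the statistical checks well-powered.

## Known limitations

- The synthetic reference has a single fixed V column layout per chain; no
  V-length polymorphism or allelic series is generated (alleles can be
  added by hand for allele-collapsing tests).
- Indel sequencing errors and V-domain indels (outside CDR3) are neither
  simulated nor handled by the gapless profile alignment.
- The chain-score threshold of 30 is meaningful only for this profile
  implementation.
- Plug-in pairing enrichment is conservative; it flags strong pairings
  reliably but its p-values are not exactly calibrated.
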