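# scbcr

Single-cell B-cell-receptor sequencing (scBCR-seq) analysis toolkit:
from barcoded paired-end reads to accurately paired, full-length heavy- and
light-chain variable regions per cell, with lineage clustering and
repertoire statistics — plus a ground-truthed simulator so the whole stack
is testable without any sequencing data.

## The problem

Antibody specificity is determined by the *pair* of variable regions, VH
and VL, expressed by one B cell. Droplet scBCR-seq libraries tag all cDNA
of a cell with a 16 nt barcode (plus a 10 nt UMI and 13 nt switch oligo on
read 1) and shear amplicons at the 3' end, so every fragment keeps the
transcript 5' start while 3' ends vary — short 2x150 reads can then be
assembled de novo into full-length variable regions, per cell. Recovering
trustworthy VH–VL pairs from such data requires: calling cell-containing
barcodes, per-cell assembly with read-pair-support filtering, variable
domain annotation (chain, FR/CDR boundaries, germline V/J, somatic
hypermutation), and doublet/contamination-aware chain pairing.

## The method

- **Cell calling**: barcodes with read count above 0.1x the count at the
  rank equal to 2.5% of targeted cells (rank 150 for 6000 cells).
- **Assembly**: deterministic greedy overlap assembly per barcode; a read
  pair is *concordant* when both mates are fully embedded in the contig in
  forward–reverse orientation at a plausible insert (600 +/- 300 nt).
  Contigs without concordant pairs are discarded; the rest are trimmed to
  the supported region with most pairs.
- **Annotation**: chain identity and FR/CDR boundaries from a
  position-specific germline profile (score >= 30 accepts); germline V/J
  calls by best local alignment (match +2 / mismatch -2 / gap -3/-1); a
  domain is *complete* if it spans all of FR1 through the first four FR4
  codons; SHM = mismatches vs the assigned V germline over FR1..FR3 only.
- **Pairing**: per cell, the complete VH and VL with most concordant pairs;
  *certainty* = top-contig pairs / all same-chain contig pairs. Quality
  filters: VH >= 10 pairs, VL >= 100 pairs, certainty >= 80% for both.
- **Lineages**: single-linkage clusters over identical V_H and V_L genes
  (allele ignored), identical CDR-H3 length and >= 80% CDR-H3 identity;
  expansion, V-gene usage, VH–VL pairing enrichment (binomial exceedance +
  Benjamini–Hochberg) and light-chain concordance on top.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 30-cell repertoire (10 clonal lineages) and run the full
pipeline on it:

```bash
scbcr simulate --out-dir sim --n-cells 30 --n-lineages 10 \
    --n-v-genes 15 --n-j-genes 3 --seed 3
scbcr all --r1 sim/sim_R1.fastq.gz --r2 sim/sim_R2.fastq.gz \
    --reference sim/germline_H.fasta --reference sim/germline_K.fasta \
    --out-dir run --targeted-cells 1200 --seed 0
```

The run prints (abridged):

```json
{
  "read_pairs": 10704,
  "cells_called": 30,
  "cells_with_pairing": 30,
  "cells_passing_filters": 30,
  "n_lineages": 10,
  "expanded_cell_fraction": 0.8,
  "vl_concordance_pct": 100.0
}
```

All 30 simulated cells are called from their barcodes, every cell yields a
complete VH+VL pair passing the read-support and certainty filters, the 10
simulated lineages are recovered exactly, 80% of cells sit in
expanded (size >= 2) lineages, and within clonal groups the light-chain
germline is 100% concordant — the pairing-accuracy proxy. Full per-cell
results are in `run/rearrangements.tsv` (AIRR-style columns) and
`run/lineages.tsv`; `run/scbcr.log` records counts at every filter step.

The germline-call benchmark is available as a subcommand:

```bash
scbcr benchmark --out-dir bench --n-base 200 --seed 1
```

writing V/J gene-call error rates by mutational load (1..40) for simulated
VH sequences; at 40 mutations the V-gene error rate stays at or below 0.5%.

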