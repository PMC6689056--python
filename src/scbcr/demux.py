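"""Read-1 parsing, cell calling by rank cutoff, and demultiplexing.

Read 1 of each pair opens with a fixed 39 nt tag: a 16 nt cell barcode, a
10 nt UMI and a 13 nt switch oligo; the remainder is transcript insert.
Cell-containing barcodes are called with a rank-based rule: the read-count
cutoff is 0.1 times the count of the barcode at the rank corresponding to
the 97.5th percentile of the targeted cell number (rank 150 for 6000
targeted cells), and barcodes above the cutoff are kept. Demultiplexing
assigns read pairs only on perfect barcode matches; oversized per-barcode
bins are downsampled to a fixed cap.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

BARCODE_LEN = 16
UMI_LEN = 10
SWITCH_LEN = 13
TAG_LEN = BARCODE_LEN + UMI_LEN + SWITCH_LEN  # 39

RANK_FRACTION = 0.025  # rank = 2.5% of targeted cells (97.5th percentile)
CUTOFF_MULTIPLIER = 0.1
DOWNSAMPLE_CAP = 100_000


@dataclass
class TaggedReadPair:
    """A parsed read pair: barcode/UMI stripped from read 1."""

    barcode: str
    umi: str
    insert1: str
    read2: str
    qual1: str = ""
    qual2: str = ""
    read_id: str = ""


@dataclass
class CellSet:
    """Barcodes called as cells, with the cutoff used to call them."""

    cells: set[str]
    cutoff_value: float
    rank_used: int

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.cells

    def __len__(self) -> int:
        return len(self.cells)


def split_read1(seq: str) -> tuple[str, str, str] | None:
    """Split read 1 into (barcode, umi, insert); the switch oligo is dropped.

    Returns None for reads too short to hold the 39 nt tag plus at least one
    insert base; callers count and log discards rather than raising.
    """
    if len(seq) < TAG_LEN + 1:
        return None
    return seq[:BARCODE_LEN], seq[BARCODE_LEN : BARCODE_LEN + UMI_LEN], seq[TAG_LEN:]


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq_pair(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[TaggedReadPair]:
    """Stream tagged read pairs from a FASTQ pair; short read 1s are skipped."""
    n_short = 0
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            parts = split_read1(s1)
            if parts is None:
                n_short += 1
                continue
            bc, umi, insert = parts
            yield TaggedReadPair(
                barcode=bc,
                umi=umi,
                insert1=insert,
                read2=s2,
                qual1=q1[TAG_LEN:],
                qual2=q2,
                read_id=t1.split()[0],
            )
    if n_short:
        log.info("discarded %d read pairs with read 1 shorter than %d nt",
                 n_short, TAG_LEN + 1)


def count_barcodes(
    pairs: Iterable[TaggedReadPair], whitelist: set[str] | None = None
) -> Counter:
    """Tally read-pair counts per (optionally whitelisted) barcode."""
    counts: Counter = Counter()
    for pair in pairs:
        if whitelist is None or pair.barcode in whitelist:
            counts[pair.barcode] += 1
    return counts


def cell_rank_cutoff(table: Counter | dict, targeted_cells: int) -> CellSet:
    """Call cell barcodes with the rank-based read-count cutoff.

    The rank is 2.5% of the targeted cell number (rounded, minimum 1; 150
    for 6000 targeted cells), the cutoff is 0.1x the read count at that rank
    in descending order, and cells are the barcodes strictly above it.
    """
    if not table:
        raise ValueError("empty barcode table")
    if targeted_cells < 40:
        raise ValueError("targeted_cells must be at least 40")
    rank = max(1, int(np.floor(RANK_FRACTION * targeted_cells + 0.5)))
    counts = sorted(table.values(), reverse=True)
    if rank > len(counts):
        log.warning(
            "barcode table (%d) smaller than rank %d; using last rank",
            len(counts), rank,
        )
        rank = len(counts)
    cutoff = CUTOFF_MULTIPLIER * counts[rank - 1]
    cells = {bc for bc, c in table.items() if c > cutoff}
    return CellSet(cells=cells, cutoff_value=cutoff, rank_used=rank)


def demultiplex(
    pairs: Iterable[TaggedReadPair], cells: CellSet | set[str]
) -> tuple[dict[str, list[TaggedReadPair]], int]:
    """Bin read pairs by called barcode; perfect matches only.

    Returns (bins, n_unassigned). A pair is assigned iff its barcode exactly
    equals a called barcode — no mismatch rescue.
    """
    members = cells.cells if isinstance(cells, CellSet) else cells
    if not members:
        log.warning("empty cell set: all reads unassigned")
    bins: dict[str, list[TaggedReadPair]] = {bc: [] for bc in members}
    n_unassigned = 0
    for pair in pairs:
        if pair.barcode in bins:
            bins[pair.barcode].append(pair)
        else:
            n_unassigned += 1
    if n_unassigned:
        log.info("%d read pairs unassigned to any called barcode", n_unassigned)
    return bins, n_unassigned


def downsample_bin(
    bin_pairs: list[TaggedReadPair], cap: int = DOWNSAMPLE_CAP, seed: int = 0
) -> list[TaggedReadPair]:
    """Uniformly downsample a bin to at most ``cap`` pairs (order preserved)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    if len(bin_pairs) <= cap:
        return bin_pairs
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(bin_pairs), size=cap, replace=False))
    return [bin_pairs[i] for i in keep]
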