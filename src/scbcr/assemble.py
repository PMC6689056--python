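"""Per-barcode de novo assembly and concordant-pair contig trimming.

Reads from one cell barcode are assembled by deterministic greedy overlap
extension: contigs grow from k-mer-seeded suffix/prefix overlaps of at
least ``min_overlap`` nt (at most ``max_mismatch_in_overlap`` substitutions
per overlap), taking the longest overlap first (ties broken by
lexicographic read id). Read 2 is reverse-complemented before overlap
search, so contigs come out in transcript orientation. Contigs are then
polished to the per-position majority of the bin's reads and near-duplicate
contigs are merged.

Assembly support is then quantified with concordant read pairs: a pair is
concordant when both mates are fully embedded in the contig in
forward-reverse orientation with an implied insert size inside the expected
window. Contigs without concordant pairs are discarded; contigs with
support are trimmed to the contiguous supported region containing the most
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .demux import TaggedReadPair
from .reference import revcomp


@dataclass
class AssemblyParams:
    min_overlap: int = 25
    max_mismatch_in_overlap: int = 1
    expected_insert: int = 600
    insert_tolerance: int = 300
    k_seed: int = 21
    polish_max_edits: int = 2  # per-read edit budget for consensus voting
    polish_rounds: int = 2
    merge_max_edits: int = 3  # contigs within this distance of a longer one merge

    def __post_init__(self) -> None:
        if self.k_seed > self.min_overlap:
            raise ValueError("k_seed must not exceed min_overlap")


@dataclass
class Contig:
    """An assembled sequence with concordant-read-pair support."""

    barcode: str
    contig_id: str
    sequence: str
    concordant_pairs: int = 0
    support_intervals: list[tuple[int, int]] = field(default_factory=list)
    per_position_coverage: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# greedy overlap assembly
# ---------------------------------------------------------------------------


def _oriented_reads(bin_pairs: list[TaggedReadPair]) -> list[tuple[str, str]]:
    """Collect (id, sequence) in transcript orientation: read-1 inserts
    forward, read 2 reverse-complemented."""
    reads = []
    for i, pair in enumerate(bin_pairs):
        rid = pair.read_id or str(i)
        if pair.insert1:
            reads.append((f"{rid}/1", pair.insert1))
        if pair.read2:
            reads.append((f"{rid}/2", revcomp(pair.read2)))
    return reads


def _best_overlap(
    contig: str, read: str, min_overlap: int, right: bool, max_mismatch: int = 0
) -> int:
    """Longest overlap (contig suffix vs read prefix if ``right``, read
    suffix vs contig prefix otherwise) with at most ``max_mismatch``
    substitutions, that extends the contig."""
    limit = min(len(contig), len(read) - 1)
    for o in range(limit, min_overlap - 1, -1):
        a = contig[-o:] if right else read[-o:]
        b = read[:o] if right else contig[:o]
        if max_mismatch == 0:
            if a == b:
                return o
            continue
        mismatches = 0
        for x, y in zip(a, b):
            if x != y:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            return o
    return 0


def assemble_bin(
    bin_pairs: list[TaggedReadPair], params: AssemblyParams | None = None,
    barcode: str = "",
) -> list[Contig]:
    """Greedy overlap assembly of one barcode's reads into raw contigs.

    Deterministic: seeds are taken longest-read-first (ties by lexicographic
    read id); extension always takes the candidate with the longest
    admissible overlap. Reads identical to or contained in a contig are
    consumed by it.
    Given error-free reads tiling a transcript with adjacent overlaps of at
    least ``min_overlap``, the transcript is reconstructed exactly.
    """
    params = params or AssemblyParams()
    reads = _oriented_reads(bin_pairs)
    if not reads:
        return []

    # deduplicate identical sequences, keeping the lexicographically first id
    by_seq: dict[str, str] = {}
    for rid, seq in sorted(reads, key=lambda r: r[0]):
        if seq not in by_seq:
            by_seq[seq] = rid
    unique = sorted(by_seq.items(), key=lambda kv: (-len(kv[0]), kv[1]))
    seqs = [s for s, _ in unique]
    ids = [r for _, r in unique]

    k = params.k_seed
    kmer_index: dict[str, set[int]] = {}
    for i, seq in enumerate(seqs):
        for p in range(len(seq) - k + 1):
            kmer_index.setdefault(seq[p : p + k], set()).add(i)

    used = [False] * len(seqs)
    contigs: list[str] = []

    def _candidates(segment: str) -> list[int]:
        found: set[int] = set()
        for p in range(len(segment) - k + 1):
            found |= kmer_index.get(segment[p : p + k], set())
        return sorted(i for i in found if not used[i])

    for start in range(len(seqs)):
        if used[start]:
            continue
        used[start] = True
        contig = seqs[start]
        # absorb contained reads and extend until fixpoint
        progress = True
        while progress:
            progress = False
            # mark reads contained in the contig as used
            for i in _candidates(contig):
                if seqs[i] in contig:
                    used[i] = True
            # rightward extension
            tail = contig[-(max(len(s) for s in seqs)) :]
            best_i, best_o = -1, 0
            for i in _candidates(tail):
                o = _best_overlap(contig, seqs[i], params.min_overlap, right=True,
                                  max_mismatch=params.max_mismatch_in_overlap)
                if o > best_o or (o == best_o and o > 0 and ids[i] < ids[best_i]):
                    best_i, best_o = i, o
            if best_o > 0:
                contig = contig + seqs[best_i][best_o:]
                used[best_i] = True
                progress = True
                continue
            # leftward extension
            head = contig[: max(len(s) for s in seqs)]
            best_i, best_o = -1, 0
            for i in _candidates(head):
                o = _best_overlap(contig, seqs[i], params.min_overlap, right=False,
                                  max_mismatch=params.max_mismatch_in_overlap)
                if o > best_o or (o == best_o and o > 0 and ids[i] < ids[best_i]):
                    best_i, best_o = i, o
            if best_o > 0:
                contig = seqs[best_i][: len(seqs[best_i]) - best_o] + contig
                used[best_i] = True
                progress = True
        contigs.append(contig)

    contigs.sort(key=lambda s: (-len(s), s))
    return [
        Contig(barcode=barcode, contig_id=f"{barcode}_contig{j}", sequence=s)
        for j, s in enumerate(contigs)
    ]


_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def polish_contig(
    contig: str, read_seqs: list[str], max_edits: int = 2, rounds: int = 2
) -> str:
    """Correct sequencing errors absorbed by greedy extension.

    Each read is placed on the contig by approximate matching (at most
    ``max_edits`` substitutions; indel placements are skipped) and votes on
    the bases it covers; the consensus takes the majority base per position,
    keeping the current base on ties or zero coverage. Error-free inputs are
    returned unchanged.
    """
    for _ in range(rounds):
        votes = np.zeros((len(contig), 4), dtype=np.int32)
        for seq in read_seqs:
            if not seq or len(seq) > len(contig):
                continue
            hit = edlib.align(seq, contig, mode="HW", task="locations", k=max_edits)
            if hit["editDistance"] < 0 or not hit["locations"]:
                continue
            s, e = hit["locations"][0]
            e += 1
            if e - s != len(seq):  # alignment used indels; skip
                continue
            idx = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
            ok = idx >= 0
            np.add.at(votes[s:e], (np.flatnonzero(ok), idx[ok]), 1)
        arr = np.frombuffer(contig.encode(), dtype=np.uint8).copy()
        best = votes.argmax(axis=1)
        best_count = votes.max(axis=1)
        cur_idx = _BASE_INDEX[arr]
        cur_count = np.where(
            cur_idx >= 0, votes[np.arange(len(arr)), np.maximum(cur_idx, 0)], 0
        )
        replace = best_count > cur_count
        arr[replace] = _BASES[best[replace]]
        polished = arr.tobytes().decode()
        if polished == contig:
            break
        contig = polished
    return contig


# ---------------------------------------------------------------------------
# concordant-pair support
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    p = haystack.find(needle)
    while p != -1:
        out.append(p)
        p = haystack.find(needle, p + 1)
    return out


def count_concordant_pairs(
    contig: Contig, bin_pairs: list[TaggedReadPair],
    params: AssemblyParams | None = None,
) -> tuple[int, list[tuple[int, int]], np.ndarray]:
    """Count read pairs concordantly supporting a contig.

    A pair is concordant iff read 1 occurs as an exact forward substring,
    the reverse complement of read 2 occurs as an exact substring starting
    at or after read 1, and the implied insert (read-1 start to read-2 end)
    is within ``expected_insert +/- insert_tolerance``. The support interval
    of a pair is [read-1 start, read-2 end); coverage counts covering pairs
    per position.
    """
    params = params or AssemblyParams()
    seq = contig.sequence
    lo = params.expected_insert - params.insert_tolerance
    hi = params.expected_insert + params.insert_tolerance
    intervals: list[tuple[int, int]] = []
    for pair in bin_pairs:
        if not pair.insert1 or not pair.read2:
            continue
        p1s = _find_all(seq, pair.insert1)
        if not p1s:
            continue
        r2 = revcomp(pair.read2)
        p2s = _find_all(seq, r2)
        if not p2s:
            continue
        placed = None
        for p1 in p1s:
            for p2 in p2s:
                end = p2 + len(r2)
                if p2 >= p1 and lo <= end - p1 <= hi:
                    placed = (p1, end)
                    break
            if placed:
                break
        if placed:
            intervals.append(placed)
    coverage = np.zeros(len(seq), dtype=int)
    for s, e in intervals:
        coverage[s:e] += 1
    return len(intervals), intervals, coverage


def trim_to_support(
    contig: Contig, bin_pairs: list[TaggedReadPair],
    params: AssemblyParams | None = None,
) -> Contig | None:
    """Trim a contig to its best concordantly supported region.

    Contigs with no concordant pairs are discarded (None). Otherwise the
    contig is cropped to the contiguous positive-coverage island containing
    the most pairs; ties go to the longer island, then the leftmost.
    """
    n, intervals, coverage = count_concordant_pairs(contig, bin_pairs, params)
    if n == 0:
        return None
    covered = coverage > 0
    islands: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            islands.append((start, i))
            start = None
    if start is not None:
        islands.append((start, len(covered)))

    def _pairs_in(island: tuple[int, int]) -> int:
        s, e = island
        return sum(1 for (a, b) in intervals if a >= s and b <= e)

    best = max(islands, key=lambda isl: (_pairs_in(isl), isl[1] - isl[0], -isl[0]))
    s, e = best
    kept = [(a - s, b - s) for (a, b) in intervals if a >= s and b <= e]
    return Contig(
        barcode=contig.barcode,
        contig_id=contig.contig_id,
        sequence=contig.sequence[s:e],
        concordant_pairs=len(kept),
        support_intervals=kept,
        per_position_coverage=coverage[s:e].copy(),
    )


def assemble_and_trim(
    bin_pairs: list[TaggedReadPair], params: AssemblyParams | None = None,
    barcode: str = "",
) -> list[Contig]:
    """Full per-barcode assembly: contigs, consensus polish, trim.

    Raw greedy contigs are polished by per-position majority vote over the
    bin's reads before the concordance filter, so isolated read errors
    absorbed during extension do not fragment the supported region.
    """
    params = params or AssemblyParams()
    read_seqs = [s for _, s in _oriented_reads(bin_pairs)]
    polished: list[Contig] = []
    for contig in assemble_bin(bin_pairs, params, barcode=barcode):
        contig.sequence = polish_contig(
            contig.sequence, read_seqs,
            max_edits=params.polish_max_edits, rounds=params.polish_rounds,
        )
        # redundant assembly paths converge after polishing; a contig that
        # aligns within a longer kept contig would double-count pair support
        absorbed = False
        for kept in polished:
            hit = edlib.align(contig.sequence, kept.sequence, mode="HW",
                              k=params.merge_max_edits)
            if hit["editDistance"] >= 0:
                absorbed = True
                break
        if not absorbed:
            polished.append(contig)
    out = []
    for contig in polished:
        trimmed = trim_to_support(contig, bin_pairs, params)
        if trimmed is not None:
            out.append(trimmed)
    return out
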