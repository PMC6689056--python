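"""Greedy assembly, concordant-pair accounting, support trimming."""

import numpy as np
import pytest

from scbcr.assemble import (
    AssemblyParams,
    Contig,
    assemble_bin,
    count_concordant_pairs,
    trim_to_support,
)
from scbcr.demux import TaggedReadPair
from scbcr.reference import revcomp


def _transcript(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _read_pair(contig, start, end, i=0, flip_r2=True):
    """A concordant pair covering [start, end): read1 forward at start,
    read2 sequenced from the 3' end."""
    r1 = contig[start : start + 111]
    r2_fwd = contig[max(start, end - 150) : end]
    return TaggedReadPair(
        barcode="A" * 16, umi="C" * 10, insert1=r1,
        read2=revcomp(r2_fwd) if flip_r2 else r2_fwd, read_id=f"r{i:04d}")


class TestAssembleBin:
    def test_tiling_windows_reconstruct_transcript(self):
        transcript = _transcript(400)
        pairs = []
        for i, s in enumerate(range(0, 301, 10)):
            pairs.append(TaggedReadPair(
                barcode="A" * 16, umi="C" * 10,
                insert1=transcript[s : s + 100], read2="", read_id=f"w{i:03d}"))
        contigs = assemble_bin(pairs)
        assert len(contigs) == 1
        assert contigs[0].sequence == transcript

    def test_single_read_returns_itself(self):
        pairs = [TaggedReadPair(barcode="A" * 16, umi="C" * 10,
                                insert1="ACGT" * 30, read2="", read_id="r0")]
        contigs = assemble_bin(pairs)
        assert len(contigs) == 1
        assert contigs[0].sequence == "ACGT" * 30

    def test_unrelated_transcripts_stay_separate(self):
        t1, t2 = _transcript(300, seed=1), _transcript(300, seed=2)
        pairs = []
        i = 0
        for t in (t1, t2):
            for s in range(0, 201, 25):
                pairs.append(TaggedReadPair(
                    barcode="A" * 16, umi="C" * 10, insert1=t[s : s + 100],
                    read2="", read_id=f"r{i:03d}"))
                i += 1
        contigs = assemble_bin(pairs)
        assert len(contigs) == 2
        assert {c.sequence for c in contigs} == {t1, t2}

    def test_read2_is_reverse_complemented_before_overlap(self):
        transcript = _transcript(260, seed=3)
        pairs = [
            TaggedReadPair(barcode="A" * 16, umi="C" * 10,
                           insert1=transcript[:150], read2="", read_id="a"),
            TaggedReadPair(barcode="A" * 16, umi="C" * 10, insert1="",
                           read2=revcomp(transcript[110:260]), read_id="b"),
        ]
        contigs = assemble_bin(pairs)
        assert len(contigs) == 1
        assert contigs[0].sequence == transcript


class TestConcordance:
    def setup_method(self):
        self.seq = _transcript(700, seed=5)
        self.contig = Contig(barcode="A" * 16, contig_id="c0", sequence=self.seq)

    def test_proper_pair_at_expected_insert_is_concordant(self):
        pair = _read_pair(self.seq, 0, 600)
        n, intervals, cov = count_concordant_pairs(self.contig, [pair])
        assert n == 1
        assert intervals == [(0, 600)]
        assert cov[:600].min() == 1 and cov[600:].max() == 0

    def test_wrong_orientation_not_concordant(self):
        pair = _read_pair(self.seq, 0, 600, flip_r2=False)
        n, _, _ = count_concordant_pairs(self.contig, [pair])
        assert n == 0

    def test_mate_not_embedded_not_concordant(self):
        pair = _read_pair(self.seq, 0, 600)
        truncated = Contig(barcode="A" * 16, contig_id="c0",
                           sequence=self.seq[:500])
        n, _, _ = count_concordant_pairs(truncated, [pair])
        assert n == 0

    def test_insert_outside_tolerance_not_concordant(self):
        # implied insert 200 < 600 - 300
        pair = _read_pair(self.seq, 0, 200)
        n, _, _ = count_concordant_pairs(self.contig, [pair])
        assert n == 0


class TestTrimToSupport:
    def test_zero_pairs_discards_contig(self):
        seq = _transcript(700, seed=6)
        contig = Contig(barcode="A" * 16, contig_id="c0", sequence=seq)
        assert trim_to_support(contig, []) is None

    def test_full_coverage_unchanged(self):
        seq = _transcript(620, seed=7)
        contig = Contig(barcode="A" * 16, contig_id="c0", sequence=seq)
        pairs = [_read_pair(seq, 0, 620, i=i) for i in range(3)]
        trimmed = trim_to_support(contig, pairs)
        assert trimmed.sequence == seq
        assert trimmed.concordant_pairs == 3

    def test_island_with_most_pairs_selected(self):
        seq = _transcript(1500, seed=8)
        contig = Contig(barcode="A" * 16, contig_id="c0", sequence=seq)
        pairs = [_read_pair(seq, 0, 400, i=i) for i in range(5)]
        pairs += [_read_pair(seq, 1000, 1400, i=10 + i) for i in range(3)]
        trimmed = trim_to_support(contig, pairs)
        assert trimmed.sequence == seq[0:400]
        assert trimmed.concordant_pairs == 5
        # brute-force oracle: recompute islands from raw coverage
        n, intervals, cov = count_concordant_pairs(contig, pairs)
        islands = []
        start = None
        for i, c in enumerate(cov > 0):
            if c and start is None:
                start = i
            if not c and start is not None:
                islands.append((start, i))
                start = None
        if start is not None:
            islands.append((start, len(cov)))
        best = max(islands, key=lambda isl: sum(
            1 for a, b in intervals if a >= isl[0] and b <= isl[1]))
        assert trimmed.sequence == seq[best[0] : best[1]]

    def test_trimmed_contig_is_substring_with_island_pair_count(self):
        seq = _transcript(900, seed=9)
        contig = Contig(barcode="A" * 16, contig_id="c0", sequence=seq)
        pairs = [_read_pair(seq, s, s + 450, i=i)
                 for i, s in enumerate((0, 100, 200, 400))]
        trimmed = trim_to_support(contig, pairs)
        assert trimmed is not None
        assert trimmed.sequence in seq
        assert trimmed.concordant_pairs == len(trimmed.support_intervals)
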