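"""Chain identification, region partition, germline assignment, SHM."""

import numpy as np
import pytest

from scbcr.annotate import (
    AlignmentScoring,
    annotate_contig,
    assign_germline,
    count_shm,
    identify_chain,
    is_complete,
)
from scbcr.reference import V_NT_REGIONS, revcomp
from scbcr.simulate import make_vh_benchmark


@pytest.fixture(scope="module")
def vdj(ref_h):
    """Unmutated germline V+J construct (no junction trimming)."""
    v = ref_h.v_segments()[0]
    j = ref_h.j_segments()[0]
    return v.nt_seq + j.nt_seq, v, j


class TestIdentifyChain:
    def test_germline_v_identified_with_high_score(self, ref, ref_h, ref_l):
        for seg, chain in ((ref_h.v_segments()[0], "H"),
                           (ref_l.v_segments()[0], "K")):
            hit = identify_chain(seg.nt_seq, ref)
            assert hit is not None
            assert hit.chain_type == chain
            assert hit.profile_score > 100
            assert hit.frame_offset == 0 and hit.strand == "+"

    def test_reverse_complement_recovered(self, ref, ref_h):
        seg = ref_h.v_segments()[0]
        hit = identify_chain(revcomp(seg.nt_seq), ref)
        assert hit is not None and hit.strand == "-" and hit.chain_type == "H"

    def test_random_sequences_score_below_threshold(self, ref):
        rng = np.random.default_rng(0)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=350))
            assert identify_chain(seq, ref) is None

    def test_threshold_is_inclusive(self, ref, ref_h):
        seg = ref_h.v_segments()[0]
        score = identify_chain(seg.nt_seq, ref).profile_score
        assert identify_chain(seg.nt_seq, ref, min_score=score) is not None
        assert identify_chain(seg.nt_seq, ref, min_score=score + 0.1) is None

    def test_short_contig_rejected(self, ref):
        assert identify_chain("ACGT" * 20, ref) is None


class TestPartition:
    def test_germline_construct_round_trips_reference_boundaries(self, ref, vdj):
        seq, v, j = vdj
        ann = annotate_contig(seq, ref)
        for name, bounds in V_NT_REGIONS.items():
            assert ann.regions[name] == bounds
        assert ann.regions["cdr3"] == (291, 306)  # 6 nt V stub + 9 nt J tail
        assert ann.regions["fr4"] == (306, len(seq))
        assert ann.complete

    def test_cdr3_insertion_shifts_only_cdr3(self, ref, vdj):
        seq, _, _ = vdj
        inserted = seq[:294] + "GGTGGT" + seq[294:]  # +2 aa inside CDR3
        base = annotate_contig(seq, ref)
        ann = annotate_contig(inserted, ref)
        for name in ("fr1", "cdr1", "fr2", "cdr2", "fr3"):
            assert ann.regions[name] == base.regions[name]
        s, e = ann.regions["cdr3"]
        assert (e - s) == (base.regions["cdr3"][1] - base.regions["cdr3"][0]) + 6

    def test_truncation_before_fr3_is_non_annotatable(self, ref, vdj):
        seq, _, _ = vdj
        ann = annotate_contig(seq[:150], ref)
        if ann is not None:  # chain may be identified, but not annotatable
            assert not ann.annotatable
            assert not ann.complete


class TestCompleteness:
    def test_ending_at_fr4_position_four_is_complete(self, ref, vdj):
        seq, _, _ = vdj
        fr4_start = 306
        ann = annotate_contig(seq[: fr4_start + 12], ref)
        assert ann.complete and is_complete(ann)

    def test_ending_at_fr4_position_three_is_incomplete(self, ref, vdj):
        seq, _, _ = vdj
        ann = annotate_contig(seq[: 306 + 9], ref)
        assert ann is not None and not ann.complete

    def test_missing_fr1_start_is_incomplete(self, ref, vdj):
        seq, _, _ = vdj
        ann = annotate_contig(seq[3:], ref)
        assert ann is not None and not ann.complete

    def test_germline_v_alone_incomplete_until_j_appended(self, ref, ref_h):
        j = ref_h.j_segments()[0]
        for v in ref_h.v_segments():
            alone = annotate_contig(v.nt_seq, ref)
            assert alone.v_call == v.name
            assert alone.shm_nt == 0
            assert not alone.complete
            joined = annotate_contig(v.nt_seq + j.nt_seq, ref)
            assert joined.complete and joined.v_call == v.name


class TestAssignGermline:
    def test_exact_germline_scores_twice_its_length(self, ref_h):
        v = ref_h.v_segments()[2]
        seg, score, _ = assign_germline(v.nt_seq, ref_h, "V", "H")
        assert seg.name == v.name
        assert score == 2 * len(v.nt_seq)

    def test_mutated_germline_still_assigned_against_score_table(self, ref_h):
        v = ref_h.v_segments()[4]
        seq = list(v.nt_seq)
        for pos in (10, 50, 120, 200, 260):  # 5 substitutions, stop-safe
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        query = "".join(seq)
        seg, score, _ = assign_germline(query, ref_h, "V", "H")
        aligner = AlignmentScoring().aligner()
        table = {s.name: aligner.score(s.nt_seq, query)
                 for s in ref_h.v_segments()}
        assert seg.name == max(table, key=table.get) == v.name
        assert score == table[v.name]

    def test_mutations_never_increase_score_against_source(self, ref_h):
        records = make_vh_benchmark(ref_h, n_base=1, max_mutations=15, seed=4)
        source = ref_h.get(records[0].source_v)
        aligner = AlignmentScoring().aligner()
        scores = [aligner.score(source.nt_seq, r.seq_nt) for r in records]
        assert all(b <= a for a, b in zip(scores, scores[1:]))


class TestCountShm:
    def test_unmutated_sequence_counts_zero(self, ref, vdj):
        seq, v, _ = vdj
        assert count_shm(seq, v) == 0

    def test_only_v_region_mutations_counted(self, ref, vdj):
        seq, v, _ = vdj
        mutated = list(seq)
        for pos in (105, 120, 140):  # FR2 (nt 102..153)
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        for pos in (294, 297):  # CDR3: must be excluded
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        assert count_shm("".join(mutated), v) == 3
        ann = annotate_contig("".join(mutated), ref)
        assert ann.shm_nt == 3
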