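"""Variable-domain annotation: chain identity, regions, germlines, SHM.

A trimmed contig is translated in all six frames and scored against each
chain's position-specific germline profile; the best frame and chain are
accepted when the profile score reaches the acceptance threshold (30 score
units by default, inclusive). The profile's fixed column map yields the
FR1..FR3 / CDR1-2 boundaries; CDR3 runs from the column after the conserved
FR3-terminal cysteine to the start of FR4, which is located by aligning the
query to the assigned J germline. V and J germline calls are the
highest-scoring local alignments against the reference (affine-gap,
match +2 / mismatch -2 / gap open -3 / extend -1 by default). A domain is
complete when all of FR1 and the first four FR4 positions are present, the
latter matching the assigned J without frameshift. Somatic hypermutation is
counted as nucleotide mismatches (gaps count one each) against the assigned
V germline over the V-encoded region only, ending at the FR3/CDR3 boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .reference import (
    CYS_COLUMN,
    GermlineReference,
    GermlineSegment,
    HEAVY,
    V_AA_LEN,
    V_AA_REGIONS,
    V_NT_LEN,
    ChainProfile,
    revcomp,
    translate,
)

log = logging.getLogger(__name__)

CHAIN_SCORE_THRESHOLD = 30.0
FR4_COMPLETE_NT = 12  # first four FR4 codons must match the J germline


@dataclass
class AlignmentScoring:
    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def aligner(self) -> Align.PairwiseAligner:
        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.match_score = self.match
        aln.mismatch_score = self.mismatch
        aln.open_gap_score = self.gap_open
        aln.extend_gap_score = self.gap_extend
        return aln


@dataclass
class ChainCall:
    chain_type: str
    profile_score: float
    frame_offset: int
    strand: str  # '+' or '-'


@dataclass
class DomainAnnotation:
    """A chain-typed, region-partitioned, germline-assigned variable domain.

    ``nt_seq`` is the in-frame coding sequence (contig oriented to the
    coding strand, clipped to ``frame_offset``); all region coordinates are
    0-based half-open on ``nt_seq`` (``regions``) or its translation
    (``regions_aa``).
    """

    chain_type: str
    profile_score: float
    frame_offset: int
    strand: str
    nt_seq: str
    aa_seq: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    regions_aa: dict[str, tuple[int, int]] = field(default_factory=dict)
    complete: bool = False
    annotatable: bool = False
    v_call: str | None = None
    j_call: str | None = None
    v_score: float = 0.0
    j_score: float = 0.0
    shm_nt: int = 0
    contig_id: str = ""
    concordant_pairs: int = 0

    @property
    def cdr3_nt(self) -> str | None:
        if "cdr3" not in self.regions:
            return None
        s, e = self.regions["cdr3"]
        return self.nt_seq[s:e]

    @property
    def cdr3_aa(self) -> str | None:
        nt = self.cdr3_nt
        return translate(nt) if nt is not None else None

    @property
    def vdj_nt(self) -> str | None:
        """Variable-region nucleotide sequence FR1..FR4 (as covered)."""
        if "fr1" not in self.regions or "fr4" not in self.regions:
            return None
        return self.nt_seq[self.regions["fr1"][0] : self.regions["fr4"][1]]

    @property
    def v_gene(self) -> str | None:
        return self.v_call.rsplit("*", 1)[0] if self.v_call else None

    @property
    def j_gene(self) -> str | None:
        return self.j_call.rsplit("*", 1)[0] if self.j_call else None


# ---------------------------------------------------------------------------
# chain identification
# ---------------------------------------------------------------------------


def identify_chain(
    contig_nt: str,
    reference: GermlineReference,
    min_score: float = CHAIN_SCORE_THRESHOLD,
) -> ChainCall | None:
    """Identify chain type, reading frame and strand of a contig.

    All six translation frames are scored against every chain profile; the
    best-scoring combination is returned if its score meets ``min_score``
    (inclusive), else None. Contigs shorter than 90 nt are not considered.
    """
    if len(contig_nt) < 90:
        return None
    best: ChainCall | None = None
    for strand, seq in (("+", contig_nt), ("-", revcomp(contig_nt))):
        for frame in range(3):
            aa = translate(seq[frame:])
            if not aa:
                continue
            for chain in reference.chains:
                hit = reference.profile(chain).best_alignment(aa)
                if best is None or hit.score > best.profile_score:
                    best = ChainCall(chain, hit.score, frame, strand)
    if best is not None and best.profile_score >= min_score:
        return best
    return None


# ---------------------------------------------------------------------------
# region partition
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """Profile-column anchoring of a translated query."""

    diag: int  # profile column c sits at query aa position c + diag
    regions_aa: dict[str, tuple[int, int]]
    cys_aa: int  # query aa position of the conserved FR3-terminal Cys
    fr1_complete: bool


def partition_regions(aa_seq: str, profile: ChainProfile) -> Partition | None:
    """Map FR/CDR1-2 boundaries onto a translated query via the profile.

    Returns None (non-annotatable) when the conserved anchor columns are
    missing: the alignment must reach the FR3-terminal cysteine column and
    the query residue there must be a cysteine.
    """
    hit = profile.best_alignment(aa_seq)
    if hit.score <= 0:
        return None
    cys_q = CYS_COLUMN + hit.diag
    if hit.col_end <= CYS_COLUMN or cys_q >= len(aa_seq) or cys_q < 0:
        return None
    if aa_seq[cys_q] != "C":
        return None
    m = len(aa_seq)
    regions_aa: dict[str, tuple[int, int]] = {}
    for name, s, e in V_AA_REGIONS:
        qs, qe = s + hit.diag, e + hit.diag
        regions_aa[name] = (max(0, min(qs, m)), max(0, min(qe, m)))
    fr1_complete = (0 + hit.diag) >= 0 and all(
        0 <= c + hit.diag < m for c in range(*_region_cols("fr1"))
    )
    return Partition(
        diag=hit.diag, regions_aa=regions_aa, cys_aa=cys_q, fr1_complete=fr1_complete
    )


def _region_cols(name: str) -> tuple[int, int]:
    for n, s, e in V_AA_REGIONS:
        if n == name:
            return s, e
    raise KeyError(name)


# ---------------------------------------------------------------------------
# germline assignment
# ---------------------------------------------------------------------------


def assign_germline(
    nt_seq: str,
    reference: GermlineReference,
    segment_class: str,
    chain: str | None = None,
    scoring: AlignmentScoring | None = None,
) -> tuple[GermlineSegment | None, float, Align.Alignment | None]:
    """Assign the highest-scoring germline segment by local alignment.

    Ties are broken by the lexicographically lower gene name (logged).
    Returns (segment, score, alignment); (None, 0, None) when nothing
    aligns with positive score.
    """
    scoring = scoring or AlignmentScoring()
    aligner = scoring.aligner()
    if chain in ("K", "L"):
        pool = reference._select(segment_class, "K") + reference._select(segment_class, "L")
    else:
        pool = reference._select(segment_class, chain)
    best_seg, best_score = None, 0.0
    ties: list[str] = []
    for seg in sorted(pool, key=lambda s: (s.gene, s.allele)):
        score = aligner.score(seg.nt_seq, nt_seq)
        if score > best_score:
            best_score = score
            best_seg = seg
            ties = []
        elif best_seg is not None and score == best_score:
            ties.append(seg.name)
    if best_seg is None:
        return None, 0.0, None
    if ties:
        log.debug("germline tie for %s broken to %s over %s",
                  segment_class, best_seg.name, ties)
    best_aln = aligner.align(best_seg.nt_seq, nt_seq)[0]
    return best_seg, best_score, best_aln


def _map_target_to_query(aln: Align.Alignment, t_pos: int) -> int | None:
    """Query coordinate aligned to target position ``t_pos`` (block-wise)."""
    t_blocks, q_blocks = aln.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts <= t_pos < te:
            return qs + (t_pos - ts)
    return None


def _alignment_covers_gapless(aln: Align.Alignment, t_start: int, t_end: int) -> bool:
    """True when [t_start, t_end) lies inside one aligned (gap-free) block."""
    t_blocks, _ = aln.aligned
    return any(ts <= t_start and t_end <= te for ts, te in t_blocks)


def count_shm(
    nt_seq: str,
    v_segment: GermlineSegment,
    alignment: Align.Alignment | None = None,
    scoring: AlignmentScoring | None = None,
) -> int:
    """Somatic mutation count over the V-encoded region (FR1..FR3).

    Nucleotide mismatches against the assigned V germline are counted over
    germline positions before the FR3/CDR3 boundary; each alignment gap
    (run) inside that region counts as one event. CDR3 and J-derived
    positions are excluded.
    """
    fr3_end = v_segment.regions.get("fr3", (0, V_NT_LEN))[1]
    if alignment is None:
        scoring = scoring or AlignmentScoring()
        alns = scoring.aligner().align(v_segment.nt_seq, nt_seq)
        if len(alns) == 0:
            return 0
        alignment = alns[0]
    t_blocks, q_blocks = alignment.aligned
    n = 0
    target = v_segment.nt_seq
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        stop = min(te, fr3_end)
        for k in range(ts, stop):
            if target[k] != nt_seq[qs + (k - ts)]:
                n += 1
    # gaps between consecutive blocks, attributed to the target position
    for i in range(1, len(t_blocks)):
        gap_at = t_blocks[i - 1][1]
        if gap_at < fr3_end:
            n += 1
    return n


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------


def is_complete(annotation: DomainAnnotation) -> bool:
    """True iff all of FR1 and the first four FR4 positions are present.

    Recomputed from the stored regions: FR1 must be fully occupied and the
    FR4 range must extend at least four codons past the CDR3.
    """
    if "fr1" not in annotation.regions or "fr4" not in annotation.regions:
        return False
    fr1_s, fr1_e = annotation.regions["fr1"]
    if fr1_e - fr1_s < V_AA_REGIONS[0][2] * 3:
        return False
    fr4_s, fr4_e = annotation.regions["fr4"]
    return fr4_e - fr4_s >= FR4_COMPLETE_NT


# ---------------------------------------------------------------------------
# full annotation
# ---------------------------------------------------------------------------


def annotate_contig(
    contig_nt: str,
    reference: GermlineReference,
    min_score: float = CHAIN_SCORE_THRESHOLD,
    scoring: AlignmentScoring | None = None,
    contig_id: str = "",
    concordant_pairs: int = 0,
) -> DomainAnnotation | None:
    """Annotate one contig end to end; None when no chain is identified.

    Contigs that are chain-identified but fail region anchoring are
    returned with ``annotatable=False`` (they still count toward pairing
    certainty denominators).
    """
    call = identify_chain(contig_nt, reference, min_score=min_score)
    if call is None:
        return None
    oriented = contig_nt if call.strand == "+" else revcomp(contig_nt)
    coding = oriented[call.frame_offset :]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = translate(coding)
    ann = DomainAnnotation(
        chain_type=call.chain_type,
        profile_score=call.profile_score,
        frame_offset=call.frame_offset,
        strand=call.strand,
        nt_seq=coding,
        aa_seq=aa,
        contig_id=contig_id,
        concordant_pairs=concordant_pairs,
    )
    part = partition_regions(aa, reference.profile(call.chain_type))
    if part is None:
        return ann

    v_seg, v_score, v_aln = assign_germline(coding, reference, "V", call.chain_type, scoring)
    j_seg, j_score, j_aln = assign_germline(coding, reference, "J", call.chain_type, scoring)
    if v_seg is not None:
        ann.v_call = v_seg.name
        ann.v_score = v_score

    for name in ("fr1", "cdr1", "fr2", "cdr2", "fr3"):
        s, e = part.regions_aa[name]
        ann.regions_aa[name] = (s, e)
        ann.regions[name] = (3 * s, 3 * e)

    cdr3_start = 3 * (part.cys_aa + 1)
    fr4_start = None
    fr4_gapless = False
    if j_seg is not None and j_aln is not None:
        ann.j_call = j_seg.name
        ann.j_score = j_score
        j_fr4 = j_seg.regions.get("fr4", (0, len(j_seg.nt_seq)))[0]
        fr4_start = _map_target_to_query(j_aln, j_fr4)
        if fr4_start is None:
            # J alignment may start inside FR4 (heavily trimmed CDR3 tail)
            t_blocks, q_blocks = j_aln.aligned
            if len(t_blocks) and t_blocks[0][0] >= j_fr4:
                fr4_start = int(q_blocks[0][0]) - (int(t_blocks[0][0]) - j_fr4)
        if fr4_start is not None:
            # keep CDR3 a whole number of codons
            fr4_start = max(cdr3_start, fr4_start)
            fr4_start -= (fr4_start - cdr3_start) % 3
            fr4_gapless = _alignment_covers_gapless(
                j_aln, j_fr4, j_fr4 + FR4_COMPLETE_NT
            )
    if fr4_start is not None:
        fr4_end = min(len(coding), fr4_start + (len(j_seg.nt_seq) - j_seg.regions.get("fr4", (0, 0))[0]))
        ann.regions["cdr3"] = (cdr3_start, fr4_start)
        ann.regions["fr4"] = (fr4_start, fr4_end)
        ann.regions_aa["cdr3"] = (cdr3_start // 3, fr4_start // 3)
        ann.regions_aa["fr4"] = (fr4_start // 3, fr4_end // 3)

    ann.annotatable = True
    ann.complete = (
        part.fr1_complete
        and fr4_start is not None
        and len(coding) >= fr4_start + FR4_COMPLETE_NT
        and fr4_gapless
    )
    if v_seg is not None:
        ann.shm_nt = count_shm(coding, v_seg, alignment=v_aln)
    return ann
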