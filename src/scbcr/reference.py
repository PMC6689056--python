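"""Germline gene-segment references and per-chain scoring profiles.

An antibody variable domain is encoded by recombined germline gene segments:
a variable (V) segment covering framework regions FR1-FR3 and the first two
CDRs, an optional diversity (D) segment (heavy chain only), and a joining (J)
segment contributing the end of CDR3 and all of FR4. This module holds the
in-memory representation of a germline reference — segments with gene/allele
naming and, for V segments, region boundaries — plus FASTA round-tripping
with a structured header grammar, and the position-specific scoring profile
used to identify chain type and framework/CDR boundaries in assembled
contigs.

FASTA header grammar (0-based half-open nt coordinates on the segment)::

    ><gene>*<allele>|<segment:V|D|J>|<chain:H|K|L>|fr1=0:78|cdr1=78:102|...

V segments carry ``fr1``..``fr3`` fields; J segments carry ``fr4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

HEAVY = "H"
KAPPA = "K"
LAMBDA = "L"
LIGHT_CHAINS = (KAPPA, LAMBDA)
CHAINS = (HEAVY, KAPPA, LAMBDA)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_UNKNOWN_AA = len(AA_ALPHABET)  # column for X / stop / ambiguity

#: Fixed column layout of the V-encoded part of a variable domain, in amino
#: acids.  All synthetic V segments of a chain share this layout, so profile
#: columns map directly onto framework/CDR boundaries.
V_AA_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("fr1", 0, 26),
    ("cdr1", 26, 34),
    ("fr2", 34, 51),
    ("cdr2", 51, 59),
    ("fr3", 59, 97),
)
V_AA_LEN = 97
V_NT_LEN = 3 * V_AA_LEN  # 291
V_NT_REGIONS = {name: (3 * s, 3 * e) for name, s, e in V_AA_REGIONS}
CYS_COLUMN = 96  # conserved cysteine terminating FR3; CDR3 starts after it

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def translate(nt: str) -> str:
    """Translate ``nt`` (frame 0; trailing partial codon dropped)."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def has_stop(nt: str) -> bool:
    usable = len(nt) - len(nt) % 3
    return any(nt[i : i + 3] in STOP_CODONS for i in range(0, usable, 3))


@dataclass
class GermlineSegment:
    """One germline V, D or J gene segment.

    ``gene`` excludes the allele suffix (e.g. ``IGHV1-3``); ``name`` is the
    full ``gene*allele`` identifier. ``regions`` holds 0-based half-open nt
    coordinates on the segment: fr1..fr3 for V, fr4 for J.
    """

    gene: str
    allele: int
    segment_class: str  # V | D | J
    chain: str  # H | K | L
    nt_seq: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.gene}*{self.allele:02d}"

    @property
    def aa_seq(self) -> str:
        return translate(self.nt_seq)

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"bad segment class {self.segment_class!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"bad chain {self.chain!r}")

    def header(self) -> str:
        parts = [self.name, self.segment_class, self.chain]
        for key in ("fr1", "cdr1", "fr2", "cdr2", "fr3", "fr4"):
            if key in self.regions:
                s, e = self.regions[key]
                parts.append(f"{key}={s}:{e}")
        return "|".join(parts)

    @classmethod
    def from_header(cls, header: str, nt_seq: str) -> "GermlineSegment":
        fields = header.strip().split("|")
        if len(fields) < 3 or "*" not in fields[0]:
            raise ValueError(f"malformed germline FASTA header: {header!r}")
        gene, allele = fields[0].rsplit("*", 1)
        regions: dict[str, tuple[int, int]] = {}
        for extra in fields[3:]:
            key, _, span = extra.partition("=")
            s, _, e = span.partition(":")
            regions[key] = (int(s), int(e))
        return cls(
            gene=gene,
            allele=int(allele),
            segment_class=fields[1],
            chain=fields[2],
            nt_seq=nt_seq.upper(),
            regions=regions,
        )


@dataclass
class ProfileHit:
    """Best gapless local alignment of a translated query to a V profile.

    ``diag`` is the offset such that profile column ``c`` aligns to query
    amino-acid position ``c + diag``; ``col_start``/``col_end`` delimit the
    scored segment (half-open, profile columns).
    """

    score: float
    diag: int
    col_start: int
    col_end: int


class ChainProfile:
    """Position-specific log-odds profile over a chain's germline V domains.

    Columns are the fixed V layout (FR1..FR3); scores are log2 odds against
    a uniform amino-acid background. Queries are scored by the best-scoring
    contiguous gapless diagonal segment (a local alignment without indels),
    in bits. Stop codons and unknown residues score a fixed penalty, so
    out-of-frame translations fall well below the acceptance threshold.
    """

    GAPCHAR_SCORE = -6.0

    def __init__(self, chain: str, aa_seqs: list[str], pseudocount: float = 0.5):
        if not aa_seqs:
            raise ValueError("no sequences to build profile from")
        self.chain = chain
        n = len(aa_seqs)
        counts = np.zeros((V_AA_LEN, len(AA_ALPHABET)))
        for seq in aa_seqs:
            for c in range(V_AA_LEN):
                idx = AA_INDEX.get(seq[c])
                if idx is not None:
                    counts[c, idx] += 1
        probs = (counts + pseudocount) / (n + pseudocount * len(AA_ALPHABET))
        background = 1.0 / len(AA_ALPHABET)
        matrix = np.log2(probs / background)
        self.matrix = np.hstack(
            [matrix, np.full((V_AA_LEN, 1), self.GAPCHAR_SCORE)]
        )

    @property
    def n_columns(self) -> int:
        return V_AA_LEN

    def best_alignment(self, query_aa: str) -> ProfileHit:
        m = len(query_aa)
        if m == 0:
            return ProfileHit(0.0, 0, 0, 0)
        idx = np.fromiter(
            (AA_INDEX.get(a, _UNKNOWN_AA) for a in query_aa), dtype=np.intp, count=m
        )
        scores = self.matrix[:, idx]  # (columns, query)
        best = ProfileHit(0.0, 0, 0, 0)
        for diag in range(-(V_AA_LEN - 1), m):
            v = np.diagonal(scores, offset=diag)
            if v.size == 0:
                continue
            cs = np.cumsum(v)
            prefix = np.concatenate(([0.0], cs[:-1]))
            prev_min = np.minimum.accumulate(prefix)
            seg = cs - prev_min
            j = int(np.argmax(seg))
            score = float(seg[j])
            if score > best.score:
                i = int(np.argmax(prefix[: j + 1] == prev_min[j]))
                col0 = max(0, -diag)  # first profile column on this diagonal
                best = ProfileHit(score, diag, col0 + i, col0 + j + 1)
        return best


class GermlineReference:
    """A set of germline segments for one or more chains, with V profiles."""

    def __init__(self, segments: list[GermlineSegment]):
        self.segments = list(segments)
        self._profiles: dict[str, ChainProfile] = {}

    def __len__(self) -> int:
        return len(self.segments)

    def _select(self, segment_class: str, chain: str | None) -> list[GermlineSegment]:
        return [
            s
            for s in self.segments
            if s.segment_class == segment_class and (chain is None or s.chain == chain)
        ]

    def v_segments(self, chain: str | None = None) -> list[GermlineSegment]:
        return self._select("V", chain)

    def d_segments(self, chain: str | None = None) -> list[GermlineSegment]:
        return self._select("D", chain)

    def j_segments(self, chain: str | None = None) -> list[GermlineSegment]:
        return self._select("J", chain)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            if s.segment_class == "V" and s.chain not in seen:
                seen.append(s.chain)
        return seen

    def profile(self, chain: str) -> ChainProfile:
        if chain not in self._profiles:
            vs = self.v_segments(chain)
            if not vs:
                raise ValueError(f"no V segments for chain {chain!r}")
            self._profiles[chain] = ChainProfile(
                chain, [s.aa_seq[:V_AA_LEN] for s in vs]
            )
        return self._profiles[chain]

    def get(self, name: str) -> GermlineSegment:
        for s in self.segments:
            if s.name == name or s.gene == name:
                return s
        raise KeyError(name)

    def merged(self, other: "GermlineReference") -> "GermlineReference":
        return GermlineReference(self.segments + other.segments)

    # -- FASTA I/O -----------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f">{seg.header()}\n{seg.nt_seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GermlineReference":
        segments = []
        header = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if header is not None:
                        segments.append(
                            GermlineSegment.from_header(header, "".join(chunks))
                        )
                    header = line[1:]
                    chunks = []
                else:
                    chunks.append(line)
        if header is not None:
            segments.append(GermlineSegment.from_header(header, "".join(chunks)))
        return cls(segments)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / len(a)
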