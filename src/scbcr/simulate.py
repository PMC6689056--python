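"""Synthetic germline references, repertoires and barcoded read pairs.

The simulator emulates the structure of 5'-barcoded single-cell BCR
sequencing libraries: each cell's heavy- and light-chain transcripts are
V(D)J recombinants with junctional trimming and N-nucleotide addition,
somatically mutated at a configurable rate with elevated probability in CDR
columns. Sequencing fragments share the transcript 5' start and have
variable 3' ends (mimicking post-amplification shearing), so read 1 carries
the 16 nt cell barcode + 10 nt UMI + 13 nt switch oligo followed by the
constant 5' insert, and read 2 is the reverse complement of the fragment 3'
end. Ambient (non-cell) barcodes receive low geometric read counts to
exercise the rank-based cell-calling cutoff.

Also provided is the germline-call benchmark generator: a set of simulated
heavy-chain recombinants, each mutated cumulatively up to a maximum load
with CDR-biased, stop-free substitutions, one record per (base, load).
"""

from __future__ import annotations

import gzip
import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    CYS_COLUMN,
    HEAVY,
    KAPPA,
    STOP_CODONS,
    GermlineReference,
    GermlineSegment,
    V_AA_LEN,
    V_NT_LEN,
    V_NT_REGIONS,
    has_stop,
    revcomp,
    translate,
)

BARCODE_LEN = 16
UMI_LEN = 10
SWITCH_OLIGO = "TTTCTTATATGGG"  # 13 nt, constant across reads
TAG_LEN = BARCODE_LEN + UMI_LEN + len(SWITCH_OLIGO)  # 39

BASES = "ACGT"
_CODONS61 = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]

#: nt appended to V after FR3 (start of CDR3, subject to junctional trimming)
V_CDR3_STUB_NT = 6
V_SEG_NT_LEN = V_NT_LEN + V_CDR3_STUB_NT  # 297

#: J layout: 9 nt of CDR3 tail followed by a 33 nt FR4
J_CDR3_NT = 9
_FR4_HEAVY = "TGGGGTCAAGGTACCCTGGTCACCGTCTCCTCA"  # WGQGTLVTVSS
_FR4_LIGHT = "TTTGGTGGTGGTACCAAAGTCGAAATCAAACGT"  # FGGGTKVEIKR
J_FR4_NT = len(_FR4_HEAVY)  # 33
J_SEG_NT_LEN = J_CDR3_NT + J_FR4_NT  # 42

CONSTANT_REGION_LEN = 255  # 3' constant-region stub appended to transcripts


# ---------------------------------------------------------------------------
# germline reference generation
# ---------------------------------------------------------------------------


def _random_stopfree_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_CODONS61, size=n))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(3)]


def _codon_safe_positions(seq_len: int, frozen_codons: set[int]) -> np.ndarray:
    return np.array(
        [p for p in range(seq_len) if p // 3 not in frozen_codons], dtype=int
    )


def _apply_point_mutation(
    rng: np.random.Generator,
    seq: list[str],
    positions: np.ndarray,
    weights: np.ndarray | None = None,
) -> int:
    """Mutate one position, rejecting stop-creating substitutions.

    Returns the mutated position. ``positions`` are the candidate sites;
    ``weights`` optional unnormalised sampling weights of the same length.
    """
    p = weights / weights.sum() if weights is not None else None
    for _ in range(200):
        pos = int(rng.choice(positions, p=p))
        old = seq[pos]
        new = _mutate_base(rng, old)
        codon_start = pos - pos % 3
        codon = "".join(seq[codon_start : codon_start + 3])
        mutated = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if mutated in STOP_CODONS:
            continue
        seq[pos] = new
        return pos
    raise RuntimeError("could not place a stop-free mutation")


def make_germline_reference(
    n_v_genes: int,
    n_j_genes: int,
    chain: str,
    divergence: tuple[float, float] = (0.70, 0.95),
    seed: int = 0,
    n_d_genes: int | None = None,
) -> GermlineReference:
    """Generate a synthetic germline reference for one chain.

    V segments are 297 nt (FR1..FR3 plus a 6 nt CDR3 stub), derived from a
    common stop-free ancestor so that all pairwise nucleotide identities lie
    inside ``divergence`` (a closed identity range, e.g. ``(0.70, 0.95)``
    mimicking human IGHV family structure). J segments are 42 nt (9 nt CDR3
    tail + 33 nt FR4 opening with the conserved Trp/Phe codon). Heavy-chain
    references also carry short random D cores. Deterministic given ``seed``.
    """
    lo, hi = divergence
    if not (0.5 < lo <= hi < 1.0):
        raise ValueError(f"infeasible divergence range ({lo}, {hi}); need 0.5 < lo <= hi < 1.0")
    if n_v_genes < 2:
        raise ValueError("need at least 2 V genes")
    rng = np.random.default_rng(seed)

    n_codons = V_SEG_NT_LEN // 3  # 99
    codons = [str(c) for c in rng.choice(_CODONS61, size=n_codons)]
    codons[CYS_COLUMN] = "TGT"  # conserved FR3-terminal cysteine
    ancestor_nt = list("".join(codons))
    L = V_SEG_NT_LEN
    frozen = {CYS_COLUMN}
    sites = _codon_safe_positions(L, frozen)

    dmin = math.ceil((1.0 - hi) * L)
    dmax = math.floor((1.0 - lo) * L)
    if dmin > dmax:
        raise ValueError("divergence range narrower than one substitution")

    # Initial per-gene divergence from the ancestor; chosen so expected
    # pairwise distances land inside [dmin, dmax], then locally repaired.
    def _solve(target: float) -> float:
        # pairwise divergence of two genes at per-gene rate x:
        # 2x - (4/3)x^2 = target
        disc = 4.0 - (16.0 / 3.0) * target
        return (2.0 - math.sqrt(max(disc, 0.0))) / (8.0 / 3.0)

    t_lo = dmin / L + 0.25 * (dmax - dmin) / L
    t_hi = dmax / L - 0.25 * (dmax - dmin) / L
    g_lo, g_hi = _solve(t_lo), _solve(max(t_hi, t_lo))

    seqs: list[list[str]] = []
    for _ in range(n_v_genes):
        d = rng.uniform(g_lo, g_hi)
        k = max(1, round(d * L))
        seq = ancestor_nt.copy()
        chosen = rng.choice(sites, size=min(k, sites.size), replace=False)
        for pos in chosen:
            _apply_point_mutation(rng, seq, np.array([pos]))
        seqs.append(seq)

    arr = np.array([[ord(c) for c in s] for s in seqs], dtype=np.uint8)

    def _dist(i: int, j: int) -> int:
        return int((arr[i] != arr[j]).sum())

    for _ in range(20000):
        worst = None
        for i in range(n_v_genes):
            for j in range(i + 1, n_v_genes):
                d = _dist(i, j)
                if d < dmin:
                    worst = (i, j, "close")
                    break
                if d > dmax:
                    worst = (i, j, "far")
                    break
            if worst:
                break
        if worst is None:
            break
        i, j, kind = worst
        seq = [chr(c) for c in arr[i]]
        if kind == "close":
            # push i away from j at a position where they agree
            agree = np.flatnonzero(arr[i] == arr[j])
            agree = np.array([p for p in agree if p // 3 not in frozen], dtype=int)
            pos = _apply_point_mutation(rng, seq, agree)
        else:
            # pull i back toward the ancestor at a disagreeing position
            diff = np.flatnonzero(arr[i] != np.array([ord(c) for c in ancestor_nt]))
            diff = np.array([p for p in diff if p // 3 not in frozen], dtype=int)
            pos = int(rng.choice(diff))
            cand = seq.copy()
            cand[pos] = ancestor_nt[pos]
            cs = pos - pos % 3
            if "".join(cand[cs : cs + 3]) in STOP_CODONS:
                continue
            seq = cand
        arr[i] = [ord(c) for c in seq]
    else:
        raise RuntimeError("divergence repair did not converge")

    prefix = f"IG{chain}"
    segments: list[GermlineSegment] = []
    v_regions = dict(V_NT_REGIONS)
    for i in range(n_v_genes):
        segments.append(
            GermlineSegment(
                gene=f"{prefix}V1-{i + 1}",
                allele=1,
                segment_class="V",
                chain=chain,
                nt_seq="".join(chr(c) for c in arr[i]),
                regions=v_regions,
            )
        )

    fr4 = _FR4_HEAVY if chain == HEAVY else _FR4_LIGHT
    j_ancestor = _random_stopfree_codons(rng, J_CDR3_NT // 3) + fr4
    for i in range(n_j_genes):
        seq = list(j_ancestor)
        n_mut = int(rng.integers(1, 4))
        # keep the conserved FR4-opening codon (Trp/Phe anchor)
        j_sites = _codon_safe_positions(len(seq), {J_CDR3_NT // 3})
        for _ in range(n_mut):
            _apply_point_mutation(rng, seq, j_sites)
        segments.append(
            GermlineSegment(
                gene=f"{prefix}J{i + 1}",
                allele=1,
                segment_class="J",
                chain=chain,
                nt_seq="".join(seq),
                regions={"fr4": (J_CDR3_NT, J_SEG_NT_LEN)},
            )
        )

    if n_d_genes is None:
        n_d_genes = 8 if chain == HEAVY else 0
    for i in range(n_d_genes):
        length = int(rng.integers(12, 19))
        segments.append(
            GermlineSegment(
                gene=f"{prefix}D{i + 1}",
                allele=1,
                segment_class="D",
                chain=chain,
                nt_seq="".join(rng.choice(list(BASES), size=length)),
            )
        )

    return GermlineReference(segments)


# ---------------------------------------------------------------------------
# V(D)J recombination
# ---------------------------------------------------------------------------


@dataclass
class Recombinant:
    """An unmutated V(D)J recombinant with its germline provenance."""

    nt: str
    v: GermlineSegment
    d: GermlineSegment | None
    j: GermlineSegment
    cdr3_start: int  # = V_NT_LEN
    fr4_start: int  # nt position where the J FR4 begins

    @property
    def cdr3_nt(self) -> str:
        return self.nt[self.cdr3_start : self.fr4_start]


def _recombine(
    rng: np.random.Generator,
    reference: GermlineReference,
    chain: str,
    max_trim: int = 6,
    max_n: int = 10,
) -> Recombinant:
    """Draw one recombination with junctional trimming and N addition.

    V 3' trimming (0..max_trim nt, confined to the CDR3 stub), J 5' trimming
    (0..max_trim, confined to the CDR3 tail), optional D with end trimming,
    N additions 0..max_n per junction, adjusted so the recombinant stays in
    frame; junctions creating stop codons are resampled.
    """
    vs = reference.v_segments(chain)
    js = reference.j_segments(chain)
    ds = reference.d_segments(chain)
    if not vs or not js:
        raise ValueError(f"reference lacks V or J segments for chain {chain}")
    v = vs[int(rng.integers(len(vs)))]
    j = js[int(rng.integers(len(js)))]
    d = ds[int(rng.integers(len(ds)))] if ds else None
    for _ in range(200):
        tv = int(rng.integers(0, min(max_trim, V_CDR3_STUB_NT) + 1))
        tj = int(rng.integers(0, min(max_trim, J_CDR3_NT) + 1))
        v_part = v.nt_seq[: V_SEG_NT_LEN - tv]
        j_part = j.nt_seq[tj:]
        if d is not None:
            td1 = int(rng.integers(0, 4))
            td2 = int(rng.integers(0, 4))
            core = d.nt_seq[td1 : len(d.nt_seq) - td2]
            n1 = int(rng.integers(0, max_n + 1))
            n2 = int(rng.integers(0, max_n + 1))
            middle = (
                "".join(rng.choice(list(BASES), size=n1))
                + core
                + "".join(rng.choice(list(BASES), size=n2))
            )
        else:
            n1 = int(rng.integers(0, max_n + 1))
            middle = "".join(rng.choice(list(BASES), size=n1))
        total = len(v_part) + len(middle) + len(j_part)
        pad = (3 - total % 3) % 3
        middle += "".join(rng.choice(list(BASES), size=pad))
        nt = v_part + middle + j_part
        if has_stop(nt):
            continue
        fr4_start = len(nt) - J_FR4_NT
        return Recombinant(nt=nt, v=v, d=d, j=j, cdr3_start=V_NT_LEN, fr4_start=fr4_start)
    raise RuntimeError("could not build a stop-free recombinant")


def _cdr_weights(length: int, fr4_start: int, bias: float) -> np.ndarray:
    """Per-site mutation weights: CDR columns get ``bias`` x the FR rate."""
    w = np.ones(length)
    for name in ("cdr1", "cdr2"):
        s, e = V_NT_REGIONS[name]
        w[s:e] = bias
    w[V_NT_LEN:fr4_start] = bias  # CDR3
    return w


# ---------------------------------------------------------------------------
# repertoire simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for the synthetic repertoire and read simulator.

    ``shm_rate`` is the expected number of point mutations per chain
    sequence; if None it is set by ``mode`` (naive: 1.0, antigen_experienced:
    12.0). Light-chain read depth exceeds heavy-chain depth by default,
    mirroring the strong per-chain depth asymmetry of real libraries.
    """

    n_cells: int = 200
    n_lineages: int = 50
    cells_per_lineage: dict[int, float] | None = None
    lineage_concentration: float = 0.3
    mode: str = "naive"
    shm_rate: float | None = None
    cdr_bias: float = 3.0
    reads_per_cell_heavy: int = 50
    reads_per_cell_light: int = 300
    read_length: int = 150
    mean_insert: int = 600
    ambient_barcode_fraction: float = 0.02
    sequencing_error_rate: float = 0.001
    distinct_cdr3: bool = True
    seed: int = 0

    def resolved_shm_rate(self) -> float:
        if self.shm_rate is not None:
            return float(self.shm_rate)
        return 12.0 if self.mode == "antigen_experienced" else 1.0

    def validate(self) -> None:
        for name in ("n_cells", "n_lineages", "reads_per_cell_heavy",
                     "reads_per_cell_light", "read_length", "mean_insert"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ambient_barcode_fraction", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_lineages > self.n_cells:
            raise ValueError("n_lineages cannot exceed n_cells")


@dataclass
class SimCell:
    """Ground truth for one simulated cell."""

    barcode: str
    lineage_id: int
    true_vh_nt: str
    true_vl_nt: str
    true_v_h_gene: str
    true_j_h_gene: str
    true_v_l_gene: str
    true_j_l_gene: str
    true_shm_h: int
    true_shm_l: int
    cdr_h3_nt: str = ""
    fr4_start_h: int = 0
    fr4_start_l: int = 0


def _lineage_sizes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    n, k = config.n_cells, config.n_lineages
    if config.cells_per_lineage:
        sizes_choices = np.array(sorted(config.cells_per_lineage), dtype=int)
        probs = np.array([config.cells_per_lineage[s] for s in sizes_choices], float)
        probs = probs / probs.sum()
        sizes = rng.choice(sizes_choices, size=k, p=probs).astype(int)
        sizes = np.maximum(sizes, 1)
        while sizes.sum() > n:
            sizes[int(np.argmax(sizes))] -= 1
            sizes = np.maximum(sizes, 1)
            if sizes.sum() == k:
                break
        while sizes.sum() < n:
            sizes[int(rng.integers(k))] += 1
        return sizes
    weights = rng.dirichlet(np.full(k, config.lineage_concentration))
    extra = rng.multinomial(n - k, weights)
    return 1 + extra


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(list(BASES), size=BARCODE_LEN))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _mutate_sequence(
    rng: np.random.Generator,
    recomb: Recombinant,
    n_mut: int,
    bias: float,
) -> tuple[str, int]:
    """Apply ``n_mut`` CDR-biased stop-free substitutions at distinct sites.

    Returns the mutated sequence and the count of mutations that landed in
    the V-encoded FR1..FR3 region (the region where SHM is later counted).
    """
    seq = list(recomb.nt)
    weights = _cdr_weights(len(seq), recomb.fr4_start, bias)
    available = np.arange(len(seq))
    shm_v = 0
    for _ in range(min(n_mut, len(seq))):
        w = weights[available]
        pos = _apply_point_mutation(rng, seq, available, w)
        available = available[available != pos]
        if pos < V_NT_LEN:
            shm_v += 1
    return "".join(seq), shm_v


def simulate_repertoire(
    reference_h: GermlineReference,
    reference_l: GermlineReference,
    config: SimConfig,
) -> tuple[list[SimCell], pd.DataFrame]:
    """Simulate a clonally structured repertoire with ground truth.

    Each lineage draws one heavy and one light recombination; members accrue
    independent CDR-biased point mutations at the configured rate. Returns
    the cells and a per-lineage table. With ``distinct_cdr3`` (default),
    lineages sharing both V genes are resampled until their CDR-H3s are
    clearly below the 80% lineage-clustering identity, so ground-truth
    lineages are recoverable by clustering.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chain_h = reference_h.chains[0]
    chain_l = reference_l.chains[0]
    shm = config.resolved_shm_rate()

    sizes = _lineage_sizes(rng, config)
    lineages: list[tuple[Recombinant, Recombinant]] = []
    for _ in range(config.n_lineages):
        for _ in range(200):
            rh = _recombine(rng, reference_h, chain_h)
            rl = _recombine(rng, reference_l, chain_l)
            if not config.distinct_cdr3:
                break
            clash = False
            for ph, pl in lineages:
                if ph.v.gene == rh.v.gene and pl.v.gene == rl.v.gene:
                    a, b = ph.cdr3_nt, rh.cdr3_nt
                    if len(a) == len(b) and len(a) > 0:
                        ident = sum(x == y for x, y in zip(a, b)) / len(a)
                        if ident >= 0.75:
                            clash = True
                            break
            if not clash:
                break
        lineages.append((rh, rl))

    barcodes = _random_barcodes(rng, config.n_cells)
    cells: list[SimCell] = []
    idx = 0
    rows = []
    for lid, ((rh, rl), size) in enumerate(zip(lineages, sizes)):
        for _ in range(int(size)):
            nm_h = int(rng.poisson(shm)) if shm > 0 else 0
            nm_l = int(rng.poisson(shm)) if shm > 0 else 0
            vh_nt, shm_h = _mutate_sequence(rng, rh, nm_h, config.cdr_bias)
            vl_nt, shm_l = _mutate_sequence(rng, rl, nm_l, config.cdr_bias)
            cells.append(
                SimCell(
                    barcode=barcodes[idx],
                    lineage_id=lid,
                    true_vh_nt=vh_nt,
                    true_vl_nt=vl_nt,
                    true_v_h_gene=rh.v.gene,
                    true_j_h_gene=rh.j.gene,
                    true_v_l_gene=rl.v.gene,
                    true_j_l_gene=rl.j.gene,
                    true_shm_h=shm_h,
                    true_shm_l=shm_l,
                    cdr_h3_nt=vh_nt[rh.cdr3_start : rh.fr4_start],
                    fr4_start_h=rh.fr4_start,
                    fr4_start_l=rl.fr4_start,
                )
            )
            idx += 1
        rows.append(
            {
                "lineage_id": lid,
                "size": int(size),
                "v_h_gene": rh.v.gene,
                "j_h_gene": rh.j.gene,
                "v_l_gene": rl.v.gene,
                "j_l_gene": rl.j.gene,
                "cdr_h3_nt": rh.cdr3_nt,
                "cdr_h3_length": len(rh.cdr3_nt),
            }
        )
    return cells, pd.DataFrame(rows)


def ground_truth_table(cells: list[SimCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "barcode": c.barcode,
                "lineage_id": c.lineage_id,
                "vh_nt": c.true_vh_nt,
                "vl_nt": c.true_vl_nt,
                "v_h_gene": c.true_v_h_gene,
                "j_h_gene": c.true_j_h_gene,
                "v_l_gene": c.true_v_l_gene,
                "j_l_gene": c.true_j_l_gene,
                "shm_h": c.true_shm_h,
                "shm_l": c.true_shm_l,
            }
            for c in cells
        ]
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPairRecord:
    name: str
    seq1: str
    seq2: str


def _constant_region(config_seed: int, chain_tag: int) -> str:
    rng = np.random.default_rng([config_seed, 977, chain_tag])
    return "".join(rng.choice(list(BASES), size=CONSTANT_REGION_LEN))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for p in hits:
        arr[p] = ord(_mutate_base(rng, chr(arr[p])))
    return arr.tobytes().decode()


def _fragment_reads(
    rng: np.random.Generator,
    transcript: str,
    barcode: str,
    config: SimConfig,
) -> tuple[str, str]:
    """One read pair from a 5'-anchored fragment with a random 3' end."""
    rl = config.read_length
    frag_end = int(rng.integers(rl, len(transcript) + 1))
    fragment = transcript[:frag_end]
    umi = "".join(rng.choice(list(BASES), size=UMI_LEN))
    insert1 = fragment[: rl - TAG_LEN]
    read1 = barcode + umi + SWITCH_OLIGO + insert1
    read2 = revcomp(fragment[-rl:])
    e = config.sequencing_error_rate
    return _apply_errors(rng, read1, e), _apply_errors(rng, read2, e)


def simulate_reads(
    cells: list[SimCell], config: SimConfig
) -> list[ReadPairRecord]:
    """Emit barcoded paired-end reads for a simulated repertoire.

    Per cell, heavy and light transcripts (variable region + 3' constant
    stub) are sampled at the configured per-chain depths; a configurable
    fraction of reads is assigned to ambient barcodes absent from the cell
    set, with geometric per-barcode counts. Deterministic given the seed.
    """
    if not cells:
        raise ValueError("no cells to simulate reads for")
    if config.read_length < TAG_LEN + 1:
        raise ValueError(
            f"read_length {config.read_length} cannot hold the {TAG_LEN} nt "
            "barcode+UMI+switch-oligo tag"
        )
    rng = np.random.default_rng([config.seed, 1])
    const_h = _constant_region(config.seed, 0)
    const_l = _constant_region(config.seed, 1)

    records: list[ReadPairRecord] = []
    i = 0
    for cell in cells:
        th = cell.true_vh_nt + const_h
        tl = cell.true_vl_nt + const_l
        n_h = int(rng.poisson(config.reads_per_cell_heavy))
        n_l = int(rng.poisson(config.reads_per_cell_light))
        for transcript, n in ((th, n_h), (tl, n_l)):
            for _ in range(n):
                r1, r2 = _fragment_reads(rng, transcript, cell.barcode, config)
                records.append(ReadPairRecord(f"sim:{i}", r1, r2))
                i += 1

    f = config.ambient_barcode_fraction
    if f > 0:
        n_cell_reads = len(records)
        n_ambient = int(round(n_cell_reads * f / (1.0 - f)))
        cell_barcodes = {c.barcode for c in cells}
        remaining = n_ambient
        while remaining > 0:
            bc = "".join(rng.choice(list(BASES), size=BARCODE_LEN))
            if bc in cell_barcodes:
                continue
            count = min(remaining, int(rng.geometric(0.5)))
            for _ in range(count):
                src = cells[int(rng.integers(len(cells)))]
                transcript = (
                    src.true_vh_nt + const_h
                    if rng.random() < 0.5
                    else src.true_vl_nt + const_l
                )
                r1, r2 = _fragment_reads(rng, transcript, bc, config)
                records.append(ReadPairRecord(f"sim:{i}", r1, r2))
                i += 1
            remaining -= count

    order = rng.permutation(len(records))
    return [records[k] for k in order]


def write_fastq_pair(
    records: list[ReadPairRecord], prefix: str | Path
) -> tuple[Path, Path]:
    """Write records as gzipped ``<prefix>_R1.fastq.gz`` / ``_R2.fastq.gz``."""
    prefix = Path(prefix)
    p1 = prefix.parent / (prefix.name + "_R1.fastq.gz")
    p2 = prefix.parent / (prefix.name + "_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for rec in records:
            f1.write(f"@{rec.name}\n{rec.seq1}\n+\n{'I' * len(rec.seq1)}\n")
            f2.write(f"@{rec.name}\n{rec.seq2}\n+\n{'I' * len(rec.seq2)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# germline-call benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkRecord:
    """One simulated VH variant at a fixed mutational load."""

    seq_nt: str
    source_v: str
    source_d: str
    source_j: str
    n_mutations: int


def make_vh_benchmark(
    reference: GermlineReference,
    n_base: int = 2000,
    max_mutations: int = 40,
    seed: int = 0,
    cdr_bias: float = 3.0,
) -> list[BenchmarkRecord]:
    """Simulated-VH germline-call benchmark set.

    Builds ``n_base`` random V(D)J recombinants and, for each, a cumulative
    mutation path of length ``max_mutations``: every step substitutes one
    previously untouched site (CDR sites at ``cdr_bias`` x the framework
    rate), resampling any substitution that would create a stop codon, and
    emits one record per load 1..max_mutations. The load-m variant therefore
    differs from its recombinant at exactly m sites and every record is
    in frame and stop-free; the total is exactly n_base x max_mutations.
    """
    if n_base < 1 or max_mutations < 1:
        raise ValueError("n_base and max_mutations must be positive")
    chain = reference.chains[0]
    rng = np.random.default_rng(seed)
    use_random_d = not reference.d_segments(chain)
    records: list[BenchmarkRecord] = []
    for _ in range(n_base):
        if use_random_d:
            core_len = int(rng.integers(10, 21))
            d_seg = GermlineSegment(
                gene="D-random",
                allele=1,
                segment_class="D",
                chain=chain,
                nt_seq="".join(rng.choice(list(BASES), size=core_len)),
            )
            ref = GermlineReference(reference.segments + [d_seg])
        else:
            ref = reference
        recomb = _recombine(rng, ref, chain)
        seq = list(recomb.nt)
        weights = _cdr_weights(len(seq), recomb.fr4_start, cdr_bias)
        available = np.arange(len(seq))
        d_name = recomb.d.gene if recomb.d is not None else ""
        for load in range(1, max_mutations + 1):
            w = weights[available]
            pos = _apply_point_mutation(rng, seq, available, w)
            available = available[available != pos]
            records.append(
                BenchmarkRecord(
                    seq_nt="".join(seq),
                    source_v=recomb.v.gene,
                    source_d=d_name,
                    source_j=recomb.j.gene,
                    n_mutations=load,
                )
            )
    return records
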