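"""Per-cell VH/VL selection, certainty scores and quality filters.

For each cell the complete heavy- and light-chain domain with the most
concordant read pairs is reported. Each reported domain carries a certainty
score: its concordant-pair count divided by the concordant pairs of all
chain-identified contigs of that class in the cell (complete or not) — a
guard against doublets and ambient contamination. High-quality pairings
require a top heavy chain with >=10 read pairs, a top light chain with
>=100 read pairs, and certainty >=80% for both chains (all inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotate import DomainAnnotation
from .reference import HEAVY

log = logging.getLogger(__name__)

MIN_HEAVY_PAIRS = 10
MIN_LIGHT_PAIRS = 100
MIN_CERTAINTY = 0.8


def _chain_class(annotation: DomainAnnotation) -> str:
    """Heavy vs light: kappa and lambda compete in one light class."""
    return "H" if annotation.chain_type == HEAVY else "L"


@dataclass
class CellPairing:
    """One cell's selected heavy + light domains with quality metrics."""

    barcode: str
    heavy: DomainAnnotation | None = None
    light: DomainAnnotation | None = None
    certainty_h: float = 0.0
    certainty_l: float = 0.0
    passes_filter: bool = False
    filter_reasons: list[str] = field(default_factory=list)


def select_top_domains(
    annotations: list[DomainAnnotation],
) -> tuple[DomainAnnotation | None, DomainAnnotation | None]:
    """Pick the complete heavy and light domain with most concordant pairs.

    Only complete domains are eligible; ties are broken by higher profile
    score, then lexicographic contig id.
    """
    top: dict[str, DomainAnnotation | None] = {"H": None, "L": None}
    for ann in annotations:
        if not ann.complete:
            continue
        cls = _chain_class(ann)
        cur = top[cls]
        if cur is None:
            top[cls] = ann
            continue
        key = (ann.concordant_pairs, ann.profile_score)
        cur_key = (cur.concordant_pairs, cur.profile_score)
        if key > cur_key or (key == cur_key and ann.contig_id < cur.contig_id):
            if key == cur_key:
                log.debug("top-domain tie broken by contig id: %s", ann.contig_id)
            top[cls] = ann
    return top["H"], top["L"]


def certainty(
    top: DomainAnnotation, annotations: list[DomainAnnotation]
) -> float:
    """Fraction of same-class concordant pairs supporting the top contig.

    The denominator sums concordant pairs over ALL contigs identified as
    that chain class, including incomplete ones.
    """
    cls = _chain_class(top)
    denom = sum(
        a.concordant_pairs for a in annotations if _chain_class(a) == cls
    )
    if denom == 0:
        raise ValueError("certainty undefined: no supporting pairs")
    return top.concordant_pairs / denom


def apply_filters(
    pairing: CellPairing,
    min_h: int = MIN_HEAVY_PAIRS,
    min_l: int = MIN_LIGHT_PAIRS,
    min_certainty: float = MIN_CERTAINTY,
) -> CellPairing:
    """Set ``passes_filter`` from the three quality clauses (inclusive).

    Clauses: heavy support >= min_h, light support >= min_l, and certainty
    >= min_certainty for both chains. Every failed clause is recorded in
    ``filter_reasons``; missing chains fail with reason "unpaired".
    """
    reasons: list[str] = []
    if pairing.heavy is None or pairing.light is None:
        reasons.append("unpaired")
    else:
        if pairing.heavy.concordant_pairs < min_h:
            reasons.append("min_h")
        if pairing.light.concordant_pairs < min_l:
            reasons.append("min_l")
        if pairing.certainty_h < min_certainty:
            reasons.append("certainty_h")
        if pairing.certainty_l < min_certainty:
            reasons.append("certainty_l")
    pairing.filter_reasons = reasons
    pairing.passes_filter = not reasons
    return pairing


def pair_cell(
    barcode: str,
    annotations: list[DomainAnnotation],
    min_h: int = MIN_HEAVY_PAIRS,
    min_l: int = MIN_LIGHT_PAIRS,
    min_certainty: float = MIN_CERTAINTY,
) -> CellPairing:
    """Full pairing for one cell: selection, certainty, filters."""
    heavy, light = select_top_domains(annotations)
    pairing = CellPairing(barcode=barcode, heavy=heavy, light=light)
    if heavy is not None:
        pairing.certainty_h = certainty(heavy, annotations)
    if light is not None:
        pairing.certainty_l = certainty(light, annotations)
    return apply_filters(pairing, min_h, min_l, min_certainty)


# ---------------------------------------------------------------------------
# AIRR-style rearrangement export
# ---------------------------------------------------------------------------

_LOCUS = {"H": "IGH", "K": "IGK", "L": "IGL"}


def to_airr(pairings: list[CellPairing]) -> pd.DataFrame:
    """Rearrangement table (AIRR-style columns, 1-based closed coordinates).

    One row per reported domain of each cell; ``consensus_count`` carries
    the concordant-pair support.
    """
    rows = []
    for p in pairings:
        for ann, cert in ((p.heavy, p.certainty_h), (p.light, p.certainty_l)):
            if ann is None:
                continue
            cdr3 = ann.cdr3_nt or ""
            cdr3_range = ann.regions.get("cdr3")
            rows.append(
                {
                    "cell_id": p.barcode,
                    "locus": _LOCUS.get(ann.chain_type, ann.chain_type),
                    "v_call": ann.v_call or "",
                    "j_call": ann.j_call or "",
                    "sequence": ann.nt_seq,
                    "sequence_aa": ann.aa_seq,
                    "cdr3": cdr3,
                    "cdr3_aa": ann.cdr3_aa or "",
                    "cdr3_start": cdr3_range[0] + 1 if cdr3_range else "",
                    "cdr3_end": cdr3_range[1] if cdr3_range else "",
                    "junction_length": len(cdr3),
                    "consensus_count": ann.concordant_pairs,
                    "certainty": cert,
                    "complete": ann.complete,
                    "shm_nt": ann.shm_nt,
                    "passes_filter": p.passes_filter,
                    "filter_reasons": ";".join(p.filter_reasons),
                }
            )
    return pd.DataFrame(rows)
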