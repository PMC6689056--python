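"""Lineage clustering and repertoire statistics.

B-cell lineages (clonal families) are recovered by single-linkage
clustering: two cells join when they share the germline V_H and V_L gene
(allele ignored), have equal CDR-H3 nucleotide length and are at least 80%
identical over the CDR-H3. On top of the lineages this module computes
clonal-expansion summaries, light-chain germline concordance (a pairing
accuracy proxy over exact V_H + CDR-H3 groups), per-chain germline usage,
V_H-V_L pairing enrichment against an independence null, rank correlation
of usage tables, and matching of cells to a reference panel of VH-VL pairs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

LINEAGE_IDENTITY = 0.80
REFERENCE_MAX_MISMATCH = 2


@dataclass
class LineageInput:
    """The per-cell fields the lineage rule needs."""

    barcode: str
    v_h_gene: str
    v_l_gene: str
    cdr_h3_nt: str


@dataclass
class Lineage:
    lineage_id: int
    members: list[str]
    v_h_gene: str
    v_l_gene: str
    cdr_h3_length: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def expanded(self) -> bool:
        return self.size >= 2


def _strip_allele(call: str) -> str:
    return call.rsplit("*", 1)[0]


def records_from_pairings(pairings) -> list[LineageInput]:
    """Adapt filtered CellPairing objects to lineage-clustering inputs."""
    records = []
    for p in pairings:
        if p.heavy is None or p.light is None:
            continue
        cdr3 = p.heavy.cdr3_nt
        if not cdr3 or not p.heavy.v_call or not p.light.v_call:
            log.info("cell %s missing CDR-H3 or V calls; excluded", p.barcode)
            continue
        records.append(
            LineageInput(
                barcode=p.barcode,
                v_h_gene=_strip_allele(p.heavy.v_call),
                v_l_gene=_strip_allele(p.light.v_call),
                cdr_h3_nt=cdr3,
            )
        )
    return records


def same_lineage(a: LineageInput, b: LineageInput,
                 min_identity: float = LINEAGE_IDENTITY) -> bool:
    """The pairwise grouping rule: same V genes, equal CDR-H3 length,
    Hamming identity >= min_identity."""
    if a.v_h_gene != b.v_h_gene or a.v_l_gene != b.v_l_gene:
        return False
    if len(a.cdr_h3_nt) != len(b.cdr_h3_nt) or not a.cdr_h3_nt:
        return False
    same = sum(x == y for x, y in zip(a.cdr_h3_nt, b.cdr_h3_nt))
    return same / len(a.cdr_h3_nt) >= min_identity


def cluster_lineages(
    records: list[LineageInput], min_identity: float = LINEAGE_IDENTITY
) -> list[Lineage]:
    """Single-linkage lineage clustering (connected components).

    Cells are bucketed by (V_H gene, V_L gene, CDR-H3 length) — the rule
    cannot join across buckets — and edges within buckets follow the
    pairwise identity rule. J genes are ignored.
    """
    records = [r for r in records if r.cdr_h3_nt]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    buckets: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        buckets.setdefault((r.v_h_gene, r.v_l_gene, len(r.cdr_h3_nt)), []).append(i)
    for idxs in buckets.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                if same_lineage(records[i], records[j], min_identity):
                    graph.add_edge(i, j)
    lineages = []
    components = sorted(nx.connected_components(graph),
                        key=lambda c: min(records[i].barcode for i in c))
    for lid, comp in enumerate(components):
        members = sorted(records[i].barcode for i in comp)
        first = records[min(comp)]
        lineages.append(
            Lineage(
                lineage_id=lid,
                members=members,
                v_h_gene=first.v_h_gene,
                v_l_gene=first.v_l_gene,
                cdr_h3_length=len(first.cdr_h3_nt),
            )
        )
    return lineages


# ---------------------------------------------------------------------------
# expansion and concordance
# ---------------------------------------------------------------------------


def expansion_summary(lineages: list[Lineage], top_n: int = 50) -> dict:
    """Fraction of cells in expanded (size >= 2) lineages, size histogram,
    and the top-N lineages by size."""
    total = sum(l.size for l in lineages)
    expanded_cells = sum(l.size for l in lineages if l.expanded)
    hist = Counter(l.size for l in lineages)
    top = sorted(lineages, key=lambda l: (-l.size, l.lineage_id))[:top_n]
    return {
        "n_cells": total,
        "n_lineages": len(lineages),
        "expanded_cell_fraction": expanded_cells / total if total else 0.0,
        "size_histogram": dict(sorted(hist.items())),
        "top_lineages": [
            {"lineage_id": l.lineage_id, "size": l.size,
             "v_h_gene": l.v_h_gene, "v_l_gene": l.v_l_gene}
            for l in top
        ],
    }


def vl_concordance(records: list[LineageInput]) -> float | None:
    """Percentage of cells with the modal V_L in multi-cell clonal groups.

    Cells are grouped by exact (V_H gene, CDR-H3 nt) match — the pairing
    accuracy proxy — restricted to groups with more than one cell; within
    each group the modal V_L gene is the consensus. None when no multi-cell
    group exists.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for r in records:
        groups.setdefault((r.v_h_gene, r.cdr_h3_nt), []).append(r.v_l_gene)
    total = 0
    concordant = 0
    for vls in groups.values():
        if len(vls) < 2:
            continue
        total += len(vls)
        concordant += Counter(vls).most_common(1)[0][1]
    if total == 0:
        return None
    return 100.0 * concordant / total


# ---------------------------------------------------------------------------
# gene usage and pairing enrichment
# ---------------------------------------------------------------------------


def gene_usage(lineages: list[Lineage]) -> tuple[pd.Series, pd.Series]:
    """Marginal V_H and V_L gene frequencies, counted per lineage."""
    vh = Counter(l.v_h_gene for l in lineages)
    vl = Counter(l.v_l_gene for l in lineages)
    n = len(lineages)
    f_vh = pd.Series({g: c / n for g, c in sorted(vh.items())}, dtype=float)
    f_vl = pd.Series({g: c / n for g, c in sorted(vl.items())}, dtype=float)
    return f_vh, f_vl


def pairing_enrichment(
    lineages: list[Lineage],
    margins: tuple[pd.Series, pd.Series] | None = None,
) -> pd.DataFrame:
    """V_H-V_L pairing enrichment against the usage-independence null.

    For each observed gene pairing the expected lineage count under
    independence is N * f(V_H) * f(V_L); the one-sided exceedance p-value is
    binomial and q-values are Benjamini-Hochberg across observed pairings.

    ``margins`` optionally supplies the marginal gene frequencies (e.g.
    known generating frequencies in a calibration study). By default they
    are estimated from the lineages themselves, which makes the binomial
    test conservative: the plug-in expectation co-varies with each observed
    count, so null exceedance rates fall below the nominal level.
    """
    n = len(lineages)
    f_vh, f_vl = margins if margins is not None else gene_usage(lineages)
    if len(f_vh) < 2 or len(f_vl) < 2:
        log.warning("fewer than 2 distinct V_H or V_L genes; ratios degenerate")
    obs = Counter((l.v_h_gene, l.v_l_gene) for l in lineages)
    rows = []
    for (vh, vl), count in sorted(obs.items()):
        p = float(f_vh[vh] * f_vl[vl])
        expected = n * p
        pval = float(stats.binom.sf(count - 1, n, p))
        rows.append(
            {
                "v_h_gene": vh,
                "v_l_gene": vl,
                "observed": count,
                "expected": expected,
                "ratio": count / expected if expected > 0 else np.inf,
                "p_value": pval,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def pairing_matrix(lineages: list[Lineage]) -> pd.DataFrame:
    """Percentage of lineages per (V_H, V_L) pairing (heatmap export)."""
    n = len(lineages)
    obs = Counter((l.v_h_gene, l.v_l_gene) for l in lineages)
    vhs = sorted({k[0] for k in obs})
    vls = sorted({k[1] for k in obs})
    mat = pd.DataFrame(0.0, index=vhs, columns=vls)
    for (vh, vl), c in obs.items():
        mat.loc[vh, vl] = 100.0 * c / n
    return mat


def usage_correlation(usage_a: pd.Series, usage_b: pd.Series) -> float | None:
    """Spearman rank correlation of two usage tables over the gene union.

    Genes absent from one table count as frequency 0; None with fewer than
    three shared genes.
    """
    genes = sorted(set(usage_a.index) | set(usage_b.index))
    if len(genes) < 3:
        return None
    a = usage_a.reindex(genes, fill_value=0.0)
    b = usage_b.reindex(genes, fill_value=0.0)
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


# ---------------------------------------------------------------------------
# reference-panel matching
# ---------------------------------------------------------------------------


def _anchored_mismatches(query: str, ref: str) -> int | None:
    """Mismatches between sequences anchored at FR1 (position 0).

    The longer sequence is trimmed at the 3' end (FR4 truncation is
    tolerated); a length difference beyond 10% of the reference means the
    sequences are not comparable (None).
    """
    if not query or not ref:
        return None
    n = min(len(query), len(ref))
    if max(len(query), len(ref)) - n > 0.1 * len(ref):
        return None
    return sum(1 for x, y in zip(query[:n], ref[:n]) if x != y)


def match_to_reference(
    cells: list[tuple[str, str, str]],
    reference_pairs: list[tuple[str, str, str]],
    max_mismatch: int = REFERENCE_MAX_MISMATCH,
) -> pd.DataFrame:
    """Match each cell's VH+VL to the best reference pair by mismatches.

    ``cells`` and ``reference_pairs`` are (id, vh_nt, vl_nt) triples. The
    per-cell class is ``exact`` (0 mismatches), ``near`` (1..max_mismatch)
    or ``unmatched``; mismatches sum over both chains.
    """
    rows = []
    for cell_id, vh, vl in cells:
        best_ref, best_mm = None, None
        for ref_id, rh, rl in reference_pairs:
            mh = _anchored_mismatches(vh, rh)
            ml = _anchored_mismatches(vl, rl)
            if mh is None or ml is None:
                continue
            mm = mh + ml
            if best_mm is None or mm < best_mm:
                best_ref, best_mm = ref_id, mm
        if best_mm is None:
            cls = "unmatched"
        elif best_mm == 0:
            cls = "exact"
        elif best_mm <= max_mismatch:
            cls = "near"
        else:
            cls = "unmatched"
        rows.append(
            {"cell_id": cell_id, "best_reference": best_ref,
             "mismatches": best_mm, "match_class": cls}
        )
    return pd.DataFrame(rows)


def lineages_table(lineages: list[Lineage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage_id": l.lineage_id,
                "size": l.size,
                "v_h_gene": l.v_h_gene,
                "v_l_gene": l.v_l_gene,
                "cdr_h3_length": l.cdr_h3_length,
                "member_barcodes": ",".join(l.members),
            }
            for l in lineages
        ]
    )
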