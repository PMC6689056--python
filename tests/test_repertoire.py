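"""Lineage clustering, expansion, concordance, usage and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scbcr.repertoire import (
    Lineage,
    LineageInput,
    cluster_lineages,
    expansion_summary,
    gene_usage,
    match_to_reference,
    pairing_enrichment,
    usage_correlation,
    vl_concordance,
)


def _rec(bc, vh="IGHV1-1", vl="IGKV1-1", cdr3="ATGCATGCAT"):
    return LineageInput(barcode=bc, v_h_gene=vh, v_l_gene=vl, cdr_h3_nt=cdr3)


def _partition(lineages):
    return {frozenset(l.members) for l in lineages}


class TestClusterLineages:
    def test_allele_is_ignored_upstream_of_clustering(self):
        # allele stripping happens when adapting pairings; gene-level inputs
        # with identical genes and CDR-H3 must merge
        recs = [_rec("a"), _rec("b")]
        assert len(cluster_lineages(recs)) == 1

    def test_identity_boundary_at_80_percent(self):
        base = "ATGCATGCAT"  # 10 nt
        two_mm = "TTGCATGCAC"  # identity 0.8 -> grouped
        three_mm = "TTGCATGCCC"  # identity 0.7 -> split
        assert len(cluster_lineages([_rec("a", cdr3=base),
                                     _rec("b", cdr3=two_mm)])) == 1
        assert len(cluster_lineages([_rec("a", cdr3=base),
                                     _rec("b", cdr3=three_mm)])) == 2

    def test_different_genes_never_grouped(self):
        assert len(cluster_lineages([_rec("a"), _rec("b", vh="IGHV1-2")])) == 2
        assert len(cluster_lineages([_rec("a"), _rec("b", vl="IGKV1-2")])) == 2

    def test_components_match_transitive_closure_oracle(self):
        rng = np.random.default_rng(17)
        vhs = [f"IGHV1-{i}" for i in range(1, 4)]
        vls = [f"IGKV1-{i}" for i in range(1, 3)]
        recs = []
        for i in range(30):
            cdr3 = "".join(rng.choice(list("ACGT"), size=12))
            recs.append(_rec(f"bc{i:02d}", vh=str(rng.choice(vhs)),
                             vl=str(rng.choice(vls)), cdr3=cdr3))
        # seed some near-identical CDR3s to create edges
        for i in range(0, 20, 2):
            mutated = list(recs[i].cdr_h3_nt)
            mutated[0] = "A" if mutated[0] != "A" else "C"
            recs.append(_rec(f"bc{30 + i}", vh=recs[i].v_h_gene,
                             vl=recs[i].v_l_gene, cdr3="".join(mutated)))

        def linked(a, b):
            return (a.v_h_gene == b.v_h_gene and a.v_l_gene == b.v_l_gene
                    and len(a.cdr_h3_nt) == len(b.cdr_h3_nt)
                    and sum(x == y for x, y in zip(a.cdr_h3_nt, b.cdr_h3_nt))
                    / len(a.cdr_h3_nt) >= 0.8)

        groups = [{i} for i in range(len(recs))]
        merged = True
        while merged:
            merged = False
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    if any(linked(recs[i], recs[j])
                           for i in groups[gi] for j in groups[gj]):
                        groups[gi] |= groups[gj]
                        del groups[gj]
                        merged = True
                        break
                if merged:
                    break
        oracle = {frozenset(recs[i].barcode for i in g) for g in groups}
        assert _partition(cluster_lineages(recs)) == oracle

    def test_permutation_invariant_and_sizes_sum(self):
        rng = np.random.default_rng(5)
        recs = [_rec(f"bc{i}", cdr3="".join(rng.choice(list("ACGT"), size=9)))
                for i in range(25)]
        lineages = cluster_lineages(recs)
        assert sum(l.size for l in lineages) == len(recs)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        assert _partition(cluster_lineages(shuffled)) == _partition(lineages)


class TestExpansion:
    def test_all_singletons_zero_percent(self):
        lineages = [Lineage(i, [f"b{i}"], "IGHV1-1", "IGKV1-1", 9)
                    for i in range(5)]
        assert expansion_summary(lineages)["expanded_cell_fraction"] == 0.0

    def test_three_one_one_gives_sixty_percent(self):
        lineages = [
            Lineage(0, ["a", "b", "c"], "IGHV1-1", "IGKV1-1", 9),
            Lineage(1, ["d"], "IGHV1-2", "IGKV1-1", 9),
            Lineage(2, ["e"], "IGHV1-3", "IGKV1-1", 9),
        ]
        summary = expansion_summary(lineages)
        assert summary["expanded_cell_fraction"] == pytest.approx(0.6)
        assert summary["size_histogram"] == {1: 2, 3: 1}


class TestVlConcordance:
    def test_unanimous_groups_are_100_percent(self):
        recs = [_rec("a"), _rec("b"), _rec("c", vh="IGHV1-2", cdr3="ACGTACGTA")]
        assert vl_concordance(recs) == pytest.approx(100.0)

    def test_modal_fraction_two_of_three(self):
        recs = [_rec("a"), _rec("b"), _rec("c", vl="IGKV1-9")]
        assert vl_concordance(recs) == pytest.approx(100 * 2 / 3)

    def test_no_multicell_groups_is_not_applicable(self):
        recs = [_rec("a"), _rec("b", cdr3="ACGTACGTA")]
        assert vl_concordance(recs) is None


class TestUsageAndEnrichment:
    def _make(self, counts):
        lineages = []
        i = 0
        for (vh, vl), n in counts.items():
            for _ in range(n):
                lineages.append(Lineage(i, [f"b{i}"], vh, vl, 9))
                i += 1
        return lineages

    def test_single_lineage_usage_is_one(self):
        f_vh, f_vl = gene_usage(self._make({("IGHV1-1", "IGKV1-1"): 1}))
        assert f_vh["IGHV1-1"] == 1.0 and f_vl["IGKV1-1"] == 1.0

    def test_marginals_match_bruteforce_tally(self):
        rng = np.random.default_rng(2)
        counts = {}
        for i in range(6):
            for j in range(4):
                counts[(f"IGHV1-{i}", f"IGKV1-{j}")] = int(rng.integers(0, 20))
        lineages = self._make(counts)
        f_vh, _ = gene_usage(lineages)
        n = len(lineages)
        for gene in f_vh.index:
            tally = sum(1 for l in lineages if l.v_h_gene == gene)
            assert f_vh[gene] == pytest.approx(tally / n)
        assert f_vh.sum() == pytest.approx(1.0)

    def test_single_vh_gene_ratios_degenerate_to_one(self):
        counts = {("IGHV1-1", "IGKV1-1"): 10, ("IGHV1-1", "IGKV1-2"): 30}
        df = pairing_enrichment(self._make(counts))
        assert np.allclose(df["ratio"], 1.0)

    def test_null_calibration_around_five_percent(self):
        """Under independent gene assignment with known marginal
        frequencies, ~5% of pairings reject at p<0.05."""
        rng = np.random.default_rng(42)
        vhs = [f"IGHV1-{i}" for i in range(5)]
        vls = [f"IGKV1-{i}" for i in range(5)]
        margins = (pd.Series(0.2, index=vhs), pd.Series(0.2, index=vls))
        fractions = []
        for _ in range(20):
            lineages = [
                Lineage(i, [f"b{i}"], str(rng.choice(vhs)),
                        str(rng.choice(vls)), 9)
                for i in range(2000)
            ]
            df = pairing_enrichment(lineages, margins=margins)
            fractions.append((df["p_value"] < 0.05).mean())
        assert abs(float(np.mean(fractions)) - 0.05) <= 0.02

    def test_plugin_margins_are_conservative_under_null(self):
        rng = np.random.default_rng(41)
        vhs = [f"IGHV1-{i}" for i in range(5)]
        vls = [f"IGKV1-{i}" for i in range(5)]
        fractions = []
        for _ in range(10):
            lineages = [
                Lineage(i, [f"b{i}"], str(rng.choice(vhs)),
                        str(rng.choice(vls)), 9)
                for i in range(2000)
            ]
            df = pairing_enrichment(lineages)
            fractions.append((df["p_value"] < 0.05).mean())
        assert float(np.mean(fractions)) <= 0.05

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(7)
        vhs = [f"IGHV1-{i}" for i in range(10)]
        vls = [f"IGKV1-{i}" for i in range(10)]
        hits = 0
        for _ in range(20):
            lineages = [
                Lineage(i, [f"b{i}"], str(rng.choice(vhs)),
                        str(rng.choice(vls)), 9)
                for i in range(950)
            ]
            # plant IGHV1-0:IGKV1-0 at ~5x its expected frequency
            lineages += [Lineage(950 + i, [f"p{i}"], "IGHV1-0", "IGKV1-0", 9)
                         for i in range(50)]
            df = pairing_enrichment(lineages).set_index(["v_h_gene", "v_l_gene"])
            if df.loc[("IGHV1-0", "IGKV1-0"), "q_value"] < 0.05:
                hits += 1
        assert hits >= 19


class TestUsageCorrelation:
    def test_identical_tables_rho_one(self):
        a = pd.Series({"g1": 0.5, "g2": 0.3, "g3": 0.2})
        assert usage_correlation(a, a) == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = pd.Series({"g1": 0.5, "g2": 0.3, "g3": 0.2})
        b = pd.Series({"g1": 0.2, "g2": 0.3, "g3": 0.5})
        assert usage_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_direct_rank_pearson(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(12)]
        a = pd.Series(rng.random(12), index=genes)
        b = pd.Series(rng.random(12), index=genes)
        rho = usage_correlation(a, b)
        expected = stats.pearsonr(stats.rankdata(a), stats.rankdata(b))[0]
        assert rho == pytest.approx(expected)

    def test_too_few_genes_not_applicable(self):
        a = pd.Series({"g1": 0.6, "g2": 0.4})
        assert usage_correlation(a, a) is None


class TestMatchToReference:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.refs = [(f"ref{i}", "".join(rng.choice(list("ACGT"), size=330)),
                      "".join(rng.choice(list("ACGT"), size=320)))
                     for i in range(5)]

    def _mutate(self, seq, positions):
        out = list(seq)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)

    def test_exact_near_unmatched_classes(self):
        _, vh, vl = self.refs[0]
        cells = [
            ("exact", vh, vl),
            ("near", self._mutate(vh, [5]), self._mutate(vl, [7])),
            ("far", self._mutate(vh, [5, 9]), self._mutate(vl, [7])),
        ]
        df = match_to_reference(cells, self.refs).set_index("cell_id")
        assert df.loc["exact", "match_class"] == "exact"
        assert df.loc["exact", "mismatches"] == 0
        assert df.loc["near", "match_class"] == "near"
        assert df.loc["near", "mismatches"] == 2
        assert df.loc["far", "match_class"] == "unmatched"

    def test_best_reference_matches_bruteforce_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            ref_id, vh, vl = self.refs[int(rng.integers(len(self.refs)))]
            cell_vh = self._mutate(vh, rng.choice(330, size=2, replace=False))
            df = match_to_reference([("c", cell_vh, vl)], self.refs)
            brute = min(
                self.refs,
                key=lambda r: sum(x != y for x, y in zip(r[1], cell_vh))
                + sum(x != y for x, y in zip(r[2], vl)))
            assert df.iloc[0]["best_reference"] == brute[0] == ref_id
            assert df.iloc[0]["mismatches"] == 2

    def test_3prime_truncation_tolerated(self):
        ref_id, vh, vl = self.refs[1]
        df = match_to_reference([("c", vh[:315], vl)], self.refs)
        assert df.iloc[0]["match_class"] == "exact"
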