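"""Cross-contrast reversal screen: worked examples, fixtures, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from phosphopipe.fixtures import build_differential_fixture, load_dopaminergic_sites
from phosphopipe.reversal import (
    classify_proteins,
    find_reversed_sites,
    restrict_to_pathways,
)
from phosphopipe.tables import Contrast, DataError, DifferentialTable, GeneSetCollection

HC = Contrast("H/C", "H", "C")
SH = Contrast("S/H", "S", "H")


def diff_table(contrast, sites, source_hash="run1"):
    """sites: list of (gene, position, call) with call in up/down/ns."""
    rows = []
    for gene, pos, call in sites:
        rows.append({
            "protein_id": gene, "gene_name": gene, "position": pos,
            "residue": "S", "multiplicity": "1", "contrast": contrast.name,
            "log2fc": {"up": 1.0, "down": -1.0, "ns": 0.0}[call],
            "t_stat": 0.0, "p_value": 0.01 if call != "ns" else 0.5,
            "call": call,
        })
    cols = ["protein_id", "gene_name", "position", "residue", "multiplicity",
            "contrast", "log2fc", "t_stat", "p_value", "call"]
    return DifferentialTable(contrast, pd.DataFrame(rows, columns=cols),
                             source_hash=source_hash)


class TestFindReversedSites:
    def test_protein_level_reversal_at_different_positions(self):
        """Down at Ser802 in disease, Up at Ser869 under treatment → reversal."""
        sites = load_dopaminergic_sites()
        hc = sites[sites["contrast"] == "H/C"].iloc[0]
        sh = sites[sites["contrast"] == "S/H"].iloc[0]
        d = diff_table(HC, [("CACNA1D", int(hc["position"]),
                             hc["regulated_type"].lower())])
        t = diff_table(SH, [("CACNA1D", int(sh["position"]),
                             sh["regulated_type"].lower())])
        pairs = find_reversed_sites(d, t)
        assert len(pairs) == 1
        assert pairs.iloc[0]["pattern"] == "down_up"
        assert pairs.iloc[0]["disease_position"] == 802
        assert pairs.iloc[0]["treatment_position"] == 869
        hits = classify_proteins(pairs)
        assert hits.iloc[0]["class"] == "down_up"

    def test_same_direction_not_reversed(self):
        d = diff_table(HC, [("G1", 10, "down")])
        t = diff_table(SH, [("G1", 20, "down")])
        assert len(find_reversed_sites(d, t)) == 0

    def test_site_mode_requires_same_position(self):
        d = diff_table(HC, [("G1", 10, "down")])
        t = diff_table(SH, [("G1", 20, "up")])
        assert len(find_reversed_sites(d, t, mode="site")) == 0
        t2 = diff_table(SH, [("G1", 10, "up")])
        assert len(find_reversed_sites(d, t2, mode="site")) == 1

    def test_provenance_mismatch_rejected(self):
        d = diff_table(HC, [("G1", 10, "down")], source_hash="runA")
        t = diff_table(SH, [("G1", 20, "up")], source_hash="runB")
        with pytest.raises(DataError, match="processing runs"):
            find_reversed_sites(d, t)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(12)]
        calls = ["up", "down", "ns"]

        def random_sites(n):
            return [(rng.choice(genes), int(rng.integers(1, 200)),
                     str(rng.choice(calls))) for _ in range(n)]

        d_sites, t_sites = random_sites(60), random_sites(60)
        # unique (protein, position) per table
        d_sites = list({(g, p): (g, p, c) for g, p, c in d_sites}.values())
        t_sites = list({(g, p): (g, p, c) for g, p, c in t_sites}.values())
        d = diff_table(HC, d_sites)
        t = diff_table(SH, t_sites)
        got = find_reversed_sites(d, t)
        expected = set()
        for g1, p1, c1 in d_sites:
            for g2, p2, c2 in t_sites:
                if g1 == g2 and {c1, c2} == {"up", "down"}:
                    expected.add((g1, p1, p2))
        assert set(zip(got["gene_name"], got["disease_position"],
                       got["treatment_position"])) == expected


class TestClassification:
    def test_only_down_up(self):
        pairs = find_reversed_sites(diff_table(HC, [("G1", 10, "down")]),
                                    diff_table(SH, [("G1", 20, "up")]))
        assert classify_proteins(pairs).iloc[0]["class"] == "down_up"

    def test_both_patterns_mixed(self):
        d = diff_table(HC, [("G1", 10, "up"), ("G1", 30, "down")])
        t = diff_table(SH, [("G1", 20, "down"), ("G1", 40, "up")])
        hits = classify_proteins(find_reversed_sites(d, t))
        assert hits.iloc[0]["class"] == "mixed"
        assert hits.iloc[0]["disease_direction"] == "Up/down"

    def test_no_pairs_absent(self):
        d = diff_table(HC, [("G1", 10, "ns")])
        t = diff_table(SH, [("G1", 20, "up")])
        assert len(classify_proteins(find_reversed_sites(d, t))) == 0

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(21)
        genes = [f"G{i}" for i in range(8)]
        sites_a = [(g, 10 + i, str(rng.choice(["up", "down", "ns"])))
                   for i, g in enumerate(genes)]
        sites_b = [(g, 50 + i, str(rng.choice(["up", "down", "ns"])))
                   for i, g in enumerate(genes)]
        d, t = diff_table(HC, sites_a), diff_table(SH, sites_b)
        fwd = classify_proteins(find_reversed_sites(d, t))
        rev = classify_proteins(find_reversed_sites(t, d))
        swap = {"down_up": "up_down", "up_down": "down_up", "mixed": "mixed"}
        fwd_map = dict(zip(fwd["gene_name"], fwd["class"]))
        rev_map = dict(zip(rev["gene_name"], rev["class"]))
        assert {g: swap[c] for g, c in fwd_map.items()} == rev_map

    def test_hits_significant_in_both_contrasts(self):
        d = diff_table(HC, [("G1", 10, "down"), ("G2", 11, "down")])
        t = diff_table(SH, [("G1", 20, "up")])
        hits = classify_proteins(find_reversed_sites(d, t))
        assert set(hits["gene_name"]) <= {"G1"}


class TestPathwayRestriction:
    def _all_inclusive(self, genes):
        coll = GeneSetCollection()
        coll.add("ALL", "all proteins", "KEGG", genes)
        return coll

    @pytest.mark.parametrize("treatment,expected", [
        ("semaglutide", 44), ("empagliflozin", 60)])
    def test_published_direction_fixtures(self, treatment, expected):
        """Direction fixtures reproduce the published reversed-protein counts."""
        d, t = build_differential_fixture(treatment)
        hits = classify_proteins(find_reversed_sites(d, t))
        final = restrict_to_pathways(hits, self._all_inclusive(hits["gene_name"]))
        assert len(final) == expected

    def test_semaglutide_class_blocks(self):
        d, t = build_differential_fixture("semaglutide")
        hits = classify_proteins(find_reversed_sites(d, t))
        counts = hits["class"].value_counts()
        assert counts["down_up"] == 24
        assert counts["up_down"] == 16
        assert counts["mixed"] == 4

    def test_restriction_and_pathway_column(self):
        d = diff_table(HC, [("G1", 10, "down"), ("G2", 11, "down")])
        t = diff_table(SH, [("G1", 20, "up"), ("G2", 21, "up")])
        hits = classify_proteins(find_reversed_sites(d, t))
        coll = GeneSetCollection()
        coll.add("path1", "p", "KEGG", ["G1"])
        final = restrict_to_pathways(hits, coll)
        assert list(final["gene_name"]) == ["G1"]
        assert final.iloc[0]["pathways"] == "path1"

    def test_empty_top20_empty_output(self):
        d = diff_table(HC, [("G1", 10, "down")])
        t = diff_table(SH, [("G1", 20, "up")])
        hits = classify_proteins(find_reversed_sites(d, t))
        final = restrict_to_pathways(hits, GeneSetCollection())
        assert len(final) == 0
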