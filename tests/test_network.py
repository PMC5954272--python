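import math

import networkx as nx
import pytest

from orcel.annotation import CircIsoform
from orcel.io import BackSplicedJunction
from orcel.network import (
    OrcelTriple,
    TargetEdge,
    build_graph,
    detect_orcel,
    export_network,
    geneset_enrichment,
    read_targets,
    summarize,
    write_targets,
)
from orcel.sponge import SpongeResult


def sponge_result(iso, mirna, p=0.001, is_sponge=True):
    return SpongeResult(
        isoform_id=iso, mirna_id=mirna, seed_counts={}, z={}, p={},
        combined_p=p, is_sponge=is_sponge,
    )


def iso(iso_id, host):
    j = BackSplicedJunction("chr1", 0, 8, "+", name=iso_id)
    return CircIsoform(
        isoform_id=iso_id, junction=j, host_gene=host, source_transcript=None,
        blocks=((0, 8),), sequence="ACGTACGT", rule_applied="exact_exon",
    )


class TestDetectOrcel:
    def test_sponge_plus_matching_target_yields_triple(self):
        triples = detect_orcel(
            [sponge_result("C1", "miR-X")],
            [iso("C1", "G")],
            [TargetEdge("miR-X", "G", "luciferase")],
        )
        assert triples == [
            OrcelTriple("G", "C1", "miR-X", 0.001, "luciferase")
        ]

    def test_target_to_other_gene_yields_nothing(self):
        assert detect_orcel(
            [sponge_result("C1", "miR-X")],
            [iso("C1", "G")],
            [TargetEdge("miR-X", "H")],
        ) == []

    def test_non_sponge_pairs_never_join(self):
        assert detect_orcel(
            [sponge_result("C1", "miR-X", p=0.5, is_sponge=False)],
            [iso("C1", "G")],
            [TargetEdge("miR-X", "G")],
        ) == []

    def test_intergenic_isoforms_never_loop(self):
        assert detect_orcel(
            [sponge_result("C1", "miR-X")],
            [iso("C1", "intergenic")],
            [TargetEdge("miR-X", "intergenic")],
        ) == []

    def test_gene_matching_is_case_insensitive(self):
        triples = detect_orcel(
            [sponge_result("C1", "miR-X")],
            [iso("C1", "Abc1")],
            [TargetEdge("MIR-x", "ABC1")],
        )
        assert len(triples) == 1 and triples[0].gene_id == "Abc1"

    def test_unresolvable_isoform_rejected(self):
        with pytest.raises(KeyError):
            detect_orcel([sponge_result("ghost", "miR-X")], [], [])

    def test_output_sorted_by_gene_isoform_mirna(self):
        sponges = [
            sponge_result("C2", "miR-B"), sponge_result("C1", "miR-A"),
            sponge_result("C1", "miR-B"),
        ]
        isoforms = [iso("C1", "G2"), iso("C2", "G1")]
        targets = [TargetEdge("miR-A", "G2"), TargetEdge("miR-B", "G1"),
                   TargetEdge("miR-B", "G2")]
        keys = [(t.gene_id, t.isoform_id, t.mirna_id)
                for t in detect_orcel(sponges, isoforms, targets)]
        assert keys == sorted(keys) and len(keys) == 3


class TestSummarize:
    def test_empty(self):
        assert tuple(summarize([])) == (0, 0, 0)

    def test_distinct_counts(self):
        triples = [
            OrcelTriple("G", "C1", "miR-1", 0.001),
            OrcelTriple("G", "C1", "miR-2", 0.001),
            OrcelTriple("G", "C2", "miR-3", 0.001),
        ]
        assert tuple(summarize(triples)) == (1, 2, 3)


class TestExport:
    def test_single_triple_graph_shape(self):
        g = build_graph([OrcelTriple("G", "C1", "miR-1", 0.001)])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert {d["node_type"] for _, d in g.nodes(data=True)} == {
            "gene", "circRNA", "miRNA"
        }
        assert {d["edge_type"] for _, _, d in g.edges(data=True)} == {
            "origin", "sponge", "target"
        }

    def test_graphml_round_trip_preserves_counts(self, tmp_path):
        triples = [
            OrcelTriple("G1", "C1", "miR-1", 0.001),
            OrcelTriple("G2", "C2", "miR-1", 0.002),
        ]
        p = tmp_path / "net.graphml"
        export_network(triples, p, format="graphml")
        g = nx.read_graphml(p)
        orig = build_graph(triples)
        assert g.number_of_nodes() == orig.number_of_nodes()
        assert g.number_of_edges() == orig.number_of_edges()

    def test_sif_lines(self, tmp_path):
        p = tmp_path / "net.sif"
        export_network([OrcelTriple("G", "C1", "miR-1", 0.001)], p, format="sif")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 3 and all(len(l.split("\t")) == 3 for l in lines)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network([OrcelTriple("G", "C1", "m", 0.1)], tmp_path / "x", format="xml")


class TestTargetsIO:
    def test_round_trip_and_dedup(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_targets(
            [TargetEdge("miR-1", "G1", "assay"), TargetEdge("MIR-1", "g1", "other"),
             TargetEdge("miR-2", "G2", "x")],
            p,
        )
        edges = read_targets(p)
        assert len(edges) == 2  # case-normalized duplicate removed
        assert edges[0].evidence == "assay"


def exact_hypergeom_tail(k, M, K, N):
    """Exact upper-tail P[X >= k] by direct summation with integer binomials."""
    den = math.comb(M, N)
    num = sum(math.comb(K, i) * math.comb(M - K, N - i)
              for i in range(max(k, N - (M - K)), min(K, N) + 1))
    return num / den


class TestEnrichment:
    def test_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        df = geneset_enrichment(universe, {"all": set(universe)}, universe)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_set_has_zero_overlap_and_high_p(self):
        universe = {f"g{i}" for i in range(100)}
        drawn = {f"g{i}" for i in range(10)}
        df = geneset_enrichment(drawn, {"s": {f"g{i}" for i in range(50, 60)}}, universe)
        assert df.loc[0, "overlap"] == 0 and df.loc[0, "p"] > 0.5

    def test_matches_exact_tail_summation(self):
        universe = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(50)}
        drawn = {f"g{i}" for i in range(40, 60)}  # 10 inside the set, 20 drawn
        df = geneset_enrichment(drawn, {"s": gene_set}, universe)
        assert df.loc[0, "overlap"] == 10
        assert df.loc[0, "p"] == pytest.approx(
            exact_hypergeom_tail(10, 1000, 50, 20), abs=1e-12
        )

    def test_bh_adjustment_bounds(self):
        universe = {f"g{i}" for i in range(200)}
        drawn = {f"g{i}" for i in range(20)}
        sets = {f"s{j}": {f"g{i}" for i in range(j, j + 30)} for j in range(0, 100, 10)}
        df = geneset_enrichment(drawn, sets, universe)
        assert ((df["p_adj"] >= df["p"] - 1e-15) & (df["p_adj"] <= 1.0)).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment(set(), {}, set())
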