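"""Graph construction, invariants, traversal, spelling and GFA round trips."""

import itertools

import pytest

from conftest import make_random_graph
from snpgraph.graph_model import (
    GfaParseError,
    GraphConstructionError,
    Node,
    SnpRecord,
    build_graph,
    haplotype_walk,
    read_gfa,
    reverse_complement,
    spell_path,
    successors,
    validate_graph,
    write_gfa,
)


class TestBuildGraph:
    def test_toy_construction(self, toy_graph):
        assert {i: n.sequence for i, n in toy_graph.nodes.items()} == {
            1: "AAAATG",
            2: "C",
            3: "T",
            4: "TT",
        }
        assert toy_graph.edges == {(1, 2), (1, 3), (2, 4), (3, 4)}
        assert toy_graph.paths["chr1"].steps == [(1, False), (2, False), (4, False)]
        assert toy_graph.snp_table == [SnpRecord("chr1", 7, "C", "T", 2, 3)]
        assert toy_graph.paths["alt_chr1_7_0"].steps == [(2, False)]
        assert toy_graph.paths["alt_chr1_7_1"].steps == [(3, False)]

    def test_long_run_is_chunked_at_32(self):
        graph = build_graph({"chr1": "A" * 40}, [])
        seqs = [graph.nodes[i].sequence for i in sorted(graph.nodes)]
        assert seqs == ["A" * 32, "A" * 8]
        assert graph.edges == {(1, 2)}
        assert not [n for n in graph.paths if n.startswith("alt_")]

    def test_snp_at_chromosome_end_has_no_successor(self):
        graph = build_graph({"chr1": "AC"}, [("chr1", 2, "C", "G")])
        assert {i: n.sequence for i, n in graph.nodes.items()} == {1: "A", 2: "C", 3: "G"}
        assert graph.edges == {(1, 2), (1, 3)}

    def test_snp_at_chromosome_start_has_no_predecessor(self):
        graph = build_graph({"chr1": "GA"}, [("chr1", 1, "G", "T")])
        assert {i: n.sequence for i, n in graph.nodes.items()} == {1: "G", 2: "T", 3: "A"}
        assert graph.edges == {(1, 3), (2, 3)}
        assert validate_graph(graph) == []

    def test_adjacent_snps_form_connected_diamonds(self):
        graph = build_graph(
            {"chr1": "AACGTT"}, [("chr1", 3, "C", "G"), ("chr1", 4, "G", "A")]
        )
        # allele diamonds at positions 3 and 4 are wired directly
        assert (2, 4) in graph.edges and (2, 5) in graph.edges
        assert (3, 4) in graph.edges and (3, 5) in graph.edges
        assert validate_graph(graph) == []
        chrom = graph.paths["chr1"].steps
        assert spell_path(
            graph, [(nid, rev, 0, len(graph.nodes[nid].sequence)) for nid, rev in chrom]
        ) == "AACGTT"

    @pytest.mark.parametrize(
        "snps,message",
        [
            ([("chr1", 7, "G", "T")], "does not match"),
            ([("chr1", 7, "C", "T"), ("chr1", 7, "C", "G")], "duplicate"),
            ([("chr1", 99, "C", "T")], "outside"),
            ([("chr1", 7, "CC", "T")], "single character"),
            ([("chr1", 7, "C", "C")], "equal"),
        ],
    )
    def test_construction_errors(self, snps, message):
        with pytest.raises(GraphConstructionError, match=message):
            build_graph({"chr1": "AAAATGCTT"}, snps)

    def test_snp_on_n_base_rejected(self):
        with pytest.raises(GraphConstructionError, match="N reference base"):
            build_graph({"chr1": "ANA"}, [("chr1", 2, "N", "T")])

    def test_invalid_reference_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid characters"):
            build_graph({"chr1": "ACXGT"}, [])

    def test_n_bases_kept_in_nodes(self):
        graph = build_graph({"chr1": "ANNGT"}, [("chr1", 5, "T", "A")])
        assert graph.nodes[1].sequence == "ANNG"


class TestInvariants:
    def test_reference_reconstruction_and_monotonic_ids(self):
        for seed in range(5):
            graph, reference, panel, _, _ = make_random_graph(seed)
            assert validate_graph(graph) == []
            assert all(u < v for u, v in graph.edges)
            assert max(len(n.sequence) for n in graph.nodes.values()) <= 32
            for chrom, seq in reference.items():
                steps = [
                    (nid, rev, 0, len(graph.nodes[nid].sequence))
                    for nid, rev in graph.paths[chrom].steps
                ]
                assert spell_path(graph, steps) == seq

    def test_haplotype_completeness_by_enumeration(self):
        """Every ref/alt choice over all SNPs spells the expected haplotype."""
        reference = {"chr1": "ACGTACGTAC"}
        snps = [("chr1", 3, "G", "T"), ("chr1", 6, "C", "A"), ("chr1", 9, "A", "G")]
        graph = build_graph(reference, snps)
        for subset in itertools.chain.from_iterable(
            itertools.combinations([s[1] for s in snps], k) for k in range(4)
        ):
            walk = haplotype_walk(graph, "chr1", subset)
            steps = [
                (nid, rev, 0, len(graph.nodes[nid].sequence)) for nid, rev in walk
            ]
            expected = list(reference["chr1"])
            for chrom, pos, _ref, alt in snps:
                if pos in subset:
                    expected[pos - 1] = alt
            assert spell_path(graph, steps) == "".join(expected)

    def test_validate_reports_monotonicity_violation(self):
        graph = build_graph({"chr1": "AAAATGCTT"}, [("chr1", 7, "C", "T")])
        graph.edges.add((4, 1))
        graph._invalidate()
        assert any("ID monotonicity" in v for v in validate_graph(graph))

    def test_validate_reports_snp_record_inconsistency(self):
        graph = build_graph({"chr1": "AAAATGCTT"}, [("chr1", 7, "C", "T")])
        graph.nodes[2] = Node(2, "G")
        graph._invalidate()
        assert any("SnpRecord consistency" in v for v in validate_graph(graph))

    def test_validate_reports_node_off_path(self):
        graph = build_graph({"chr1": "AAAA"}, [])
        graph.nodes[9] = Node(9, "T")
        graph._invalidate()
        assert any("lies on no path" in v for v in validate_graph(graph))


class TestTraversal:
    def test_successors_forward_ascending(self, toy_graph):
        assert successors(toy_graph, 1, False) == [(2, False), (3, False)]
        assert successors(toy_graph, 4, False) == []

    def test_successors_reverse_descending(self, toy_graph):
        assert successors(toy_graph, 4, True) == [(3, True), (2, True)]
        assert successors(toy_graph, 1, True) == []

    def test_successors_unknown_node(self, toy_graph):
        with pytest.raises(KeyError):
            successors(toy_graph, 99, False)

    def test_spell_forward_and_reverse(self, toy_graph):
        assert spell_path(toy_graph, [(1, False, 3, 3), (3, False, 0, 1), (4, False, 0, 1)]) == "ATGTT"
        assert spell_path(toy_graph, [(2, False, 0, 1)]) == "C"
        # the same walk read right-to-left on the complementary strand
        assert spell_path(toy_graph, [(4, True, 1, 1), (3, True, 0, 1), (1, True, 0, 3)]) == "AACAT"

    def test_spell_rejects_disconnected_steps(self, toy_graph):
        with pytest.raises(ValueError, match="not connected"):
            spell_path(toy_graph, [(2, False, 0, 1), (3, False, 0, 1)])

    def test_spell_rejects_out_of_bounds(self, toy_graph):
        with pytest.raises(ValueError, match="out of bounds"):
            spell_path(toy_graph, [(2, False, 0, 2)])


class TestGfa:
    def test_toy_gfa_line_counts(self, toy_graph):
        lines = write_gfa(toy_graph).splitlines()
        tags = [line.split("\t")[0] for line in lines]
        assert tags.count("S") == 4
        assert tags.count("L") == 4
        assert tags.count("P") == 3  # chr1 + two alt paths
        assert any("0M" in line for line in lines if line.startswith("L"))

    def test_empty_graph_header_only(self):
        from snpgraph.graph_model import VariationGraph

        assert write_gfa(VariationGraph()).strip() == "H\tVN:Z:1.0"

    def test_round_trip_random_graphs(self):
        for seed in range(25):
            graph, _, _, _, _ = make_random_graph(seed)
            back = read_gfa(write_gfa(graph))
            assert back.nodes == graph.nodes
            assert back.edges == graph.edges
            assert {n: p.steps for n, p in back.paths.items()} == {
                n: p.steps for n, p in graph.paths.items()
            }
            assert back.snp_table == graph.snp_table

    def test_parse_error_names_line(self):
        with pytest.raises(GfaParseError, match="line 2"):
            read_gfa("H\tVN:Z:1.0\nS\tnotanint\tACGT\n")


def test_reverse_complement_involution():
    for seq in ["A", "ACGT", "GATTACA", "NNNAC"]:
        assert reverse_complement(reverse_complement(seq)) == seq
    assert reverse_complement("ATGTT") == "AACAT"
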