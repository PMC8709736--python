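"""Shared fixtures: the hand-built toy graph, random graphs, brute-force oracles."""

from __future__ import annotations

import pytest

from snpgraph.aligner import Read
from snpgraph.graph_model import VariationGraph, build_graph, reverse_complement
from snpgraph.seed_index import build_index
from snpgraph.simulator import (
    SimConfig,
    simulate_individual,
    simulate_reads,
    simulate_reference,
    simulate_snp_panel,
)

TOY_REFERENCE = {"chr1": "AAAATGCTT"}
TOY_SNPS = [("chr1", 7, "C", "T")]


@pytest.fixture(scope="session")
def toy_graph() -> VariationGraph:
    """Reference AAAATGCTT with one C>T SNP at position 7.

    Nodes: 1=AAAATG, 2=C (ref allele), 3=T (alt allele), 4=TT.
    """
    return build_graph(TOY_REFERENCE, TOY_SNPS)


@pytest.fixture(scope="session")
def toy_index(toy_graph):
    return build_index(toy_graph)


def make_random_graph(seed: int, genome_length: int = 150, snp_rate: float = 0.04):
    """A small random graph plus its generating reference and panel."""
    config = SimConfig(
        genome_length=genome_length,
        snp_rate=snp_rate,
        read_length=20,
        coverage=1.0,
        seed=seed,
    )
    reference = simulate_reference(config)
    panel, freqs = simulate_snp_panel(reference, config)
    graph = build_graph(reference, panel)
    return graph, reference, panel, freqs, config


@pytest.fixture
def random_graph_factory():
    return make_random_graph


def brute_force_locate(graph: VariationGraph, pattern: str):
    """Independent oracle: scan every node sequence and its reverse complement.

    Returns the set of (node_id, offset, is_reverse) occurrence triples with
    offsets counted in the hit's orientation.
    """
    out = set()
    for nid in graph.nodes:
        fwd = graph.nodes[nid].sequence
        for is_reverse, seq in ((False, fwd), (True, reverse_complement(fwd))):
            start = seq.find(pattern)
            while start != -1:
                out.add((nid, start, is_reverse))
                start = seq.find(pattern, start + 1)
    return out


def enumerate_read_walks(graph: VariationGraph, read_seq: str):
    """Independent oracle: every walk through the graph spelling the read.

    Unbounded depth-first enumeration from every possible start position on
    both strands; returns a set of step tuples
    ``((node_id, is_reverse, offset, length), ...)`` in read-spelling order.
    Exponential in the worst case; only for small graphs/reads.
    """
    succ: dict[int, list[int]] = {nid: [] for nid in graph.nodes}
    pred: dict[int, list[int]] = {nid: [] for nid in graph.nodes}
    for u, v in graph.edges:
        succ[u].append(v)
        pred[v].append(u)

    walks = set()

    def oriented(nid: int, rev: bool) -> str:
        seq = graph.nodes[nid].sequence
        return reverse_complement(seq) if rev else seq

    def extend(steps, pos, nid, rev):
        nxts = pred[nid] if rev else succ[nid]
        for nxt in nxts:
            seq = oriented(nxt, rev)
            remaining = len(read_seq) - pos
            take = min(len(seq), remaining)
            if read_seq[pos : pos + take] != seq[:take]:
                continue
            if take < len(seq) and take < remaining:
                continue
            new_steps = steps + [(nxt, rev, 0, take)]
            if pos + take == len(read_seq):
                walks.add(tuple(new_steps))
            else:
                extend(new_steps, pos + take, nxt, rev)

    for nid in graph.nodes:
        for rev in (False, True):
            seq = oriented(nid, rev)
            for off in range(len(seq)):
                take = min(len(seq) - off, len(read_seq))
                if read_seq[:take] != seq[off : off + take]:
                    continue
                if take < len(read_seq) and off + take < len(seq):
                    continue
                steps = [(nid, rev, off, take)]
                if take == len(read_seq):
                    walks.add(tuple(steps))
                else:
                    extend(steps, take, nid, rev)
    return walks


@pytest.fixture
def locate_oracle():
    return brute_force_locate


@pytest.fixture
def walk_oracle():
    return enumerate_read_walks


def simulate_pipeline_inputs(config: SimConfig):
    """Reference, panel, individual, truth and reads for one configuration."""
    reference = simulate_reference(config)
    panel, freqs = simulate_snp_panel(reference, config)
    individual, truth = simulate_individual(panel, config, reference, freqs)
    reads = list(simulate_reads(individual, config))
    return reference, panel, freqs, individual, truth, reads
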