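"""Depth-limited exact alignment of reads to the SNP variation graph.

The aligner is seed-and-extend with two hard resource caps taken from the
depth-limited search: a global budget of ``2 x N`` probed nodes per seed
(``N`` the read length) and at most 4 neighbor probes per node.  Matching
is exact: no mismatches, no gaps; a read either spells a complete walk
through the graph or is rejected.  Because forward edges strictly increase
node ids, a hit's strand flag fixes the traversal direction: forward-strand
hits extend toward greater ids, reverse-strand hits toward lower ids.

Seeding convention.  A seed anchors a terminal substring of the read (or of
its reverse complement) inside a single node such that the unmatched
remainder lies entirely in the traversal direction; anchors are taken at
both ends of the read on both strands, so the search is strand-symmetric.
Two anchor shapes exist:

* *suffix anchors*: the first ``L >= 2`` query characters match an oriented
  node suffix (or the whole query fits inside one node);
* *junction anchors*: the first aligned node contributes exactly one
  character (its oriented last base) and the following node matches in
  full.  These are required whenever a query starts on a one-base allele
  node, where no single node can share two characters with the read.

Seeds are ordered longest-anchor-first (the most promising starting nodes);
extension stops early as soon as a complete alignment traverses an SNP
allele node, which is reported as the read's best alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from snpgraph.graph_model import VariationGraph, reverse_complement
from snpgraph.seed_index import SeedHit, SeedIndex

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Read:
    """A sequencing read; qualities are carried through but never scored."""

    name: str
    sequence: str
    qualities: str | None = None


@dataclass
class GraphAlignment:
    """A complete, exact alignment of one read.

    ``steps`` are ``(node_id, is_reverse, start_offset, length)`` in read
    order; spelling them through the graph reproduces the read sequence
    exactly (reverse-strand alignments use reverse-oriented steps with
    decreasing node ids).  ``visited_nodes`` counts the nodes probed by the
    successful seed's search, bounded by ``2 x N``.
    """

    read_name: str
    read_sequence: str
    steps: list[tuple[int, bool, int, int]]
    is_reverse: bool
    covers_snp: bool
    visited_nodes: int

    @property
    def node_ids(self) -> list[int]:
        return [s[0] for s in self.steps]


@dataclass(frozen=True)
class AlignerParams:
    """Search caps; the defaults are the depth-limited search's constants."""

    node_budget_factor: int = 2
    neighbor_cap: int = 4
    min_seed_length: int = 2
    max_seed_length: int = 32
    backtrack: bool = True  # False: strict no-backtrack, abandon seed on dead end

    def __post_init__(self) -> None:
        if self.node_budget_factor < 1 or self.neighbor_cap < 1:
            raise ValueError("budget factor and neighbor cap must be positive")
        if not 1 <= self.min_seed_length <= self.max_seed_length:
            raise ValueError("need 1 <= min_seed_length <= max_seed_length")


DEFAULT_PARAMS = AlignerParams()


@dataclass
class MappingStats:
    """Per-run counters logged by :func:`map_reads`."""

    total: int = 0
    mapped: int = 0
    rejected: int = 0
    filtered: int = 0  # mapped but dropped by the SNP-only output filter
    skipped: int = 0  # malformed records


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def find_direction(hit: SeedHit) -> str:
    """Traversal direction implied by the hit's strand flag.

    Forward-strand hits (``rc() == False``) extend toward increasing node
    ids, reverse-strand hits toward decreasing ids.
    """
    return "decreasing" if hit.is_reverse else "increasing"


def _collect_seeds(
    seq: str, rc_seq: str, index: SeedIndex, params: AlignerParams
) -> list[tuple[int, int, bool, bool, int]]:
    """Sorted anchor tuples ``(-length, node_id, is_reverse, query_is_rc, offset)``.

    The tuple layout makes plain tuple comparison realize the seed order:
    longest anchor first, then ascending node id, then forward strand
    before reverse, then the read's own orientation before its reverse
    complement.
    """
    seeds: list[tuple[int, int, bool, bool, int]] = []
    suffix_map = index.suffix_map
    full_map = index.full_map
    last_char = index.last_char
    oriented = index.oriented
    succ, pred = index.graph._adjacency()
    max_len = params.max_seed_length
    min_len = params.min_seed_length

    for query, query_is_rc in ((seq, False), (rc_seq, True)):
        n = len(query)
        # whole query inside one node
        if n <= max_len:
            for nid, (fwd, rev) in oriented.items():
                for is_reverse, oseq in ((False, fwd), (True, rev)):
                    start = oseq.find(query)
                    while start != -1:
                        seeds.append((-n, nid, is_reverse, query_is_rc, start))
                        start = oseq.find(query, start + 1)
        # suffix anchors: query prefix ends at an oriented node boundary
        for length in range(min(max_len, n - 1), min_len - 1, -1):
            entries = suffix_map.get(query[:length])
            if entries:
                neg = -length
                for nid, is_reverse, off in entries:
                    seeds.append((neg, nid, is_reverse, query_is_rc, off))
        # junction anchors: one character in the first node, the next node
        # matched in full (or containing the rest of a short query)
        rest = query[1:]
        first = query[0]
        n_rest = len(rest)
        for node_len in index.node_lengths:
            if node_len > n_rest:
                continue
            entries = full_map.get(rest[:node_len])
            if not entries:
                continue
            neg = -(1 + node_len)
            for vid, is_reverse in entries:
                for uid in succ[vid] if is_reverse else pred[vid]:
                    if last_char[(uid, is_reverse)] == first:
                        u_len = len(oriented[uid][0])
                        seeds.append((neg, uid, is_reverse, query_is_rc, u_len - 1))
        if n_rest < max_len:
            # short query ending inside the junction's second node
            for vid, (fwd, rev) in oriented.items():
                for is_reverse, oseq in ((False, fwd), (True, rev)):
                    if len(oseq) > n_rest and oseq.startswith(rest):
                        for uid in succ[vid] if is_reverse else pred[vid]:
                            if last_char[(uid, is_reverse)] == first:
                                u_len = len(oriented[uid][0])
                                seeds.append((-n, uid, is_reverse, query_is_rc, u_len - 1))

    seeds.sort()
    return seeds


def find_initial_nodes(
    read: Read, index: SeedIndex, params: AlignerParams = DEFAULT_PARAMS
) -> list[SeedHit]:
    """Seed anchors for a read, ordered most promising first.

    Returns suffix and junction anchors for the read and its reverse
    complement (see module docstring), sorted by descending anchor length,
    then ascending node id, then forward strand before reverse.  An empty
    list is the rejection signal: reads shorter than the minimum seed
    length, reads containing ``N`` or other non-ACGT characters, and reads
    sharing no anchor with the graph are all rejected.
    """
    seq = read.sequence.upper()
    if len(seq) < params.min_seed_length or not set(seq) <= _ACGT:
        return []
    return [
        SeedHit(nid, off, is_reverse, -neg_len, qrc)
        for neg_len, nid, is_reverse, qrc, off in _collect_seeds(
            seq, reverse_complement(seq), index, params
        )
    ]


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _extend_core(
    query: str,
    node_id: int,
    start: int,
    orient: bool,
    otab: dict[int, tuple[str, str]],
    neigh: dict[int, list[int]],
    budget: int,
    cap: int,
    backtrack: bool,
) -> tuple[list[tuple[int, bool, int, int]], int] | None:
    """DFS completion of ``query`` from one anchor position.

    Returns (steps spelling the query in walk order, nodes probed) or
    ``None``.  Every probed neighbor decrements the global budget whether
    it matches or not, and budget is never refunded on backtrack; at most
    ``cap`` neighbors are probed per node.
    """
    n = len(query)
    seq0 = otab[node_id][1 if orient else 0]
    m0 = min(len(seq0) - start, n)
    if m0 <= 0 or query[:m0] != seq0[start : start + m0]:
        return None
    if m0 < n and start + m0 < len(seq0):
        return None  # anchor stops short of the node boundary: cannot continue
    steps: list[tuple[int, bool, int, int]] = [(node_id, orient, start, m0)]
    pos = m0
    visited = 0
    if pos == n:
        return steps, visited

    strand = 1 if orient else 0
    # frames: [neighbor list, next index, probes used]
    stack: list[list] = [[neigh[node_id], 0, 0]]
    while stack:
        frame = stack[-1]
        nlist, idx, probes = frame
        if idx >= len(nlist) or probes >= cap:
            if not backtrack:
                return None
            stack.pop()
            pos -= steps.pop()[3]
            continue
        frame[1] = idx + 1
        frame[2] = probes + 1
        if visited >= budget:
            return None
        visited += 1
        nxt = nlist[idx]
        nseq = otab[nxt][strand]
        nlen = len(nseq)
        remaining = n - pos
        if nlen <= remaining:
            if query.startswith(nseq, pos):
                steps.append((nxt, orient, 0, nlen))
                pos += nlen
                if pos == n:
                    return steps, visited
                stack.append([neigh[nxt], 0, 0])
        elif nseq.startswith(query[pos:]):
            steps.append((nxt, orient, 0, remaining))
            return steps, visited
    return None


def _finish_alignment(
    read: Read,
    steps: list[tuple[int, bool, int, int]],
    visited: int,
    orient: bool,
    query_is_rc: bool,
    graph: VariationGraph,
    otab: dict[int, tuple[str, str]],
) -> GraphAlignment:
    # normalize so the steps spell the read itself, in read order
    if query_is_rc:
        steps = [
            (nid, not rev, len(otab[nid][0]) - (off + ln), ln)
            for nid, rev, off, ln in reversed(steps)
        ]
    allele_nodes = graph.allele_nodes
    return GraphAlignment(
        read_name=read.name,
        read_sequence=read.sequence,
        steps=steps,
        is_reverse=orient != query_is_rc,
        covers_snp=any(nid in allele_nodes for nid, _, _, _ in steps),
        visited_nodes=visited,
    )


def extend_alignment(
    read: Read,
    hit: SeedHit,
    graph: VariationGraph,
    params: AlignerParams = DEFAULT_PARAMS,
) -> GraphAlignment | None:
    """Gap-free, mismatch-free completion of a read from one seed.

    Depth-first search in the hit's traversal direction with the two stop
    conditions: a global budget of ``node_budget_factor x N`` probed nodes
    (every probed neighbor counts, matching or not, and budget is never
    refunded on backtrack) and at most ``neighbor_cap`` neighbor probes per
    node.  Returns ``None`` when no completion is found within the budgets.
    """
    seq = read.sequence.upper()
    if len(seq) < params.min_seed_length or not set(seq) <= _ACGT:
        return None
    query = reverse_complement(seq) if hit.query_is_rc else seq
    otab = _oriented_table(graph)
    succ, pred = graph._adjacency()
    neigh = pred if hit.is_reverse else succ
    result = _extend_core(
        query,
        hit.node_id,
        hit.offset,
        hit.is_reverse,
        otab,
        neigh,
        params.node_budget_factor * len(seq),
        params.neighbor_cap,
        params.backtrack,
    )
    if result is None:
        return None
    steps, visited = result
    return _finish_alignment(
        read, steps, visited, hit.is_reverse, hit.query_is_rc, graph, otab
    )


def _oriented_table(graph: VariationGraph) -> dict[int, tuple[str, str]]:
    table = getattr(graph, "_oriented_table_cache", None)
    if table is None:
        table = {
            nid: (node.sequence, reverse_complement(node.sequence))
            for nid, node in graph.nodes.items()
        }
        graph._oriented_table_cache = table
    return table


# ---------------------------------------------------------------------------
# read-level driver
# ---------------------------------------------------------------------------

def map_read(
    read: Read,
    graph: VariationGraph,
    index: SeedIndex,
    params: AlignerParams = DEFAULT_PARAMS,
) -> GraphAlignment | None:
    """Best exact alignment of one read, or ``None`` if rejected.

    Seeds are tried in :func:`find_initial_nodes` order.  The first complete
    alignment that traverses an SNP allele node is returned immediately (it
    is the best choice for SNP detection); otherwise the first complete
    alignment found is returned after all seeds are exhausted.
    """
    seq = read.sequence.upper()
    if len(seq) < params.min_seed_length or not set(seq) <= _ACGT:
        return None
    rc_seq = reverse_complement(seq)
    otab = _oriented_table(graph)
    succ, pred = graph._adjacency()
    allele_nodes = graph.allele_nodes
    budget = params.node_budget_factor * len(seq)
    cap = params.neighbor_cap
    backtrack = params.backtrack

    best: tuple | None = None
    for _neg_len, node_id, is_reverse, query_is_rc, offset in _collect_seeds(
        seq, rc_seq, index, params
    ):
        result = _extend_core(
            rc_seq if query_is_rc else seq,
            node_id,
            offset,
            is_reverse,
            otab,
            pred if is_reverse else succ,
            budget,
            cap,
            backtrack,
        )
        if result is None:
            continue
        steps, visited = result
        if any(s[0] in allele_nodes for s in steps):
            return _finish_alignment(
                read, steps, visited, is_reverse, query_is_rc, graph, otab
            )
        if best is None:
            best = (steps, visited, is_reverse, query_is_rc)
    if best is None:
        return None
    steps, visited, is_reverse, query_is_rc = best
    return _finish_alignment(read, steps, visited, is_reverse, query_is_rc, graph, otab)


def map_reads(
    reads: Iterable[Read],
    graph: VariationGraph,
    index: SeedIndex,
    params: AlignerParams = DEFAULT_PARAMS,
    printsnp: bool = False,
    stats: MappingStats | None = None,
) -> Iterator[GraphAlignment]:
    """Map a stream of reads, preserving input order.

    With ``printsnp`` only alignments that traverse an SNP allele node are
    emitted (the genotyper uses nothing else).  Mapped/rejected/filtered
    counts are accumulated in ``stats`` if given and logged at the end.
    """
    if stats is None:
        stats = MappingStats()
    for read in reads:
        stats.total += 1
        if not read.sequence:
            stats.skipped += 1
            logger.warning("skipping malformed read record %r (empty sequence)", read.name)
            continue
        aln = map_read(read, graph, index, params)
        if aln is None:
            stats.rejected += 1
            continue
        stats.mapped += 1
        if printsnp and not aln.covers_snp:
            stats.filtered += 1
            continue
        yield aln
    logger.info(
        "mapped %d/%d reads (%d rejected, %d filtered by printsnp, %d skipped)",
        stats.mapped,
        stats.total,
        stats.rejected,
        stats.filtered,
        stats.skipped,
    )
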