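"""Exact-occurrence lookup of short patterns with GCSA2-style queries.

The full generalized compressed suffix array machinery (de Bruijn
approximation, FM-index encoding) is deliberately replaced by in-memory
dictionaries over the individual node sequences on both strands: node
lengths are bounded by 32, the aligner only needs seed anchors that start
within a single node, and cross-node matching is the aligner's job.  The
query contract is preserved: :func:`locate` reports, per hit, the node
``id()``, the orientation-relative ``offset()`` and the strand flag
``rc()``.

Besides the generic substring lookup the index maintains two
aligner-facing tables:

* a *suffix map* from every oriented node suffix (length >= 2) to its
  start position, used to anchor a terminal piece of a read that runs to a
  node boundary, and
* a *junction map* keyed on full oriented node strings plus the oriented
  last character of each node, used to anchor reads whose first aligned
  node contributes a single character (always the case when a read starts
  on a one-base allele node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snpgraph.graph_model import VariationGraph, reverse_complement

MIN_PATTERN = 2
MAX_PATTERN = 32

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SeedHit:
    """One exact occurrence of a pattern starting within a node.

    ``offset`` is 0-based and counted from the start of the node in the
    hit's orientation.  ``match_length`` characters read from
    ``(node_id, offset)`` in that orientation reproduce the pattern,
    possibly crossing into successor nodes (junction anchors).
    """

    node_id: int
    offset: int
    is_reverse: bool
    match_length: int
    # Aligner metadata: True when the anchored pattern is the reverse
    # complement of the query read rather than the read itself.  Together
    # with is_reverse this fixes the traversal frame (see aligner module).
    query_is_rc: bool = field(default=False, compare=False)


def resolve_hit(hit: SeedHit) -> tuple[int, int, bool]:
    """The (id, offset, rc) query triple of a hit.

    Pure accessor, kept as a named operation to mirror the index's query
    interface.
    """
    return hit.node_id, hit.offset, hit.is_reverse


class SeedIndex:
    """Lookup structure over a graph's node sequences, both strands."""

    def __init__(self, graph: VariationGraph):
        self.graph = graph
        # oriented sequences: [node][0]=forward, [node][1]=reverse complement
        self.oriented: dict[int, tuple[str, str]] = {}
        # suffix_map[s] -> list of (node_id, is_reverse, offset) where the
        # oriented node sequence ends with s starting at offset
        self.suffix_map: dict[str, list[tuple[int, bool, int]]] = {}
        # full_map[w] -> list of (node_id, is_reverse) with oriented sequence w
        self.full_map: dict[str, list[tuple[int, bool]]] = {}
        # last_char[(node_id, is_reverse)] -> final oriented character
        self.last_char: dict[tuple[int, bool], str] = {}
        self.node_lengths: list[int] = []
        self._substring_map: dict[str, list[tuple[int, bool, int]]] | None = None

        lengths: set[int] = set()
        for nid in sorted(graph.nodes):
            fwd = graph.nodes[nid].sequence
            rev = reverse_complement(fwd)
            self.oriented[nid] = (fwd, rev)
            lengths.add(len(fwd))
            for is_reverse, seq in ((False, fwd), (True, rev)):
                self.last_char[(nid, is_reverse)] = seq[-1]
                self.full_map.setdefault(seq, []).append((nid, is_reverse))
                for off in range(max(0, len(seq) - MAX_PATTERN) , len(seq) - 1):
                    self.suffix_map.setdefault(seq[off:], []).append(
                        (nid, is_reverse, off)
                    )
        self.node_lengths = sorted(lengths, reverse=True)

    # ------------------------------------------------------------------
    def _substrings(self) -> dict[str, list[tuple[int, bool, int]]]:
        # Built lazily: the generic locate() query is used on small graphs
        # (tests, oracle comparisons); the aligner uses the suffix/junction
        # tables instead.
        if self._substring_map is None:
            table: dict[str, list[tuple[int, bool, int]]] = {}
            for nid in sorted(self.oriented):
                fwd, rev = self.oriented[nid]
                for is_reverse, seq in ((False, fwd), (True, rev)):
                    n = len(seq)
                    for i in range(n - 1):
                        top = min(n, i + MAX_PATTERN)
                        for j in range(i + MIN_PATTERN, top + 1):
                            table.setdefault(seq[i:j], []).append(
                                (nid, is_reverse, i)
                            )
            self._substring_map = table
        return self._substring_map

    def locate(self, pattern: str) -> list[SeedHit]:
        """All occurrences of ``pattern`` starting within a node, both strands.

        Patterns must have length 2..32; patterns containing ``N`` (or any
        character outside ACGT) never match.  Hits are ordered by
        (node id, strand, offset).
        """
        if not MIN_PATTERN <= len(pattern) <= MAX_PATTERN:
            raise ValueError(
                f"pattern length {len(pattern)} outside {MIN_PATTERN}..{MAX_PATTERN}"
            )
        pattern = pattern.upper()
        if not set(pattern) <= _ACGT:
            return []
        entries = self._substrings().get(pattern, [])
        return [
            SeedHit(nid, off, is_reverse, len(pattern))
            for nid, is_reverse, off in sorted(
                entries, key=lambda e: (e[0], e[1], e[2])
            )
        ]


def build_index(graph: VariationGraph) -> SeedIndex:
    """Build the seed index for a graph (deterministic for a given graph)."""
    return SeedIndex(graph)


def locate(index: SeedIndex, pattern: str) -> list[SeedHit]:
    """See :meth:`SeedIndex.locate`."""
    return index.locate(pattern)
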