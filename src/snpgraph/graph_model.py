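"""SNP variation graph: construction, validation, traversal, GFA serialization.

The graph is a directed acyclic sequence graph.  Nodes carry DNA strings of
1..32 characters over {A,C,G,T,N}; node identifiers increase strictly along
every forward edge, so forward traversal walks left to right along the
reference and reverse traversal walks right to left on the complementary
strand.  Each biallelic SNP contributes two parallel one-character allele
nodes (a "diamond"): the reference-allele node lies on the chromosome path,
and each allele node additionally lies on its own ``alt_``-prefixed path so
that allele membership is recoverable from the path set alone.

Coordinates: VCF positions are 1-based; node offsets are 0-based and are
counted from the start of the node *in the stated orientation* (an offset on
a reverse-oriented node counts from the node's last forward character).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

MAX_NODE_LEN = 32
ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GraphConstructionError(ValueError):
    """Raised when a reference/SNP combination cannot form a valid graph."""


@dataclass(frozen=True)
class Node:
    """A graph node: unique positive id and a 1..32-character sequence."""

    id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"node id must be positive, got {self.id}")
        if not 1 <= len(self.sequence) <= MAX_NODE_LEN:
            raise ValueError(
                f"node {self.id}: sequence length {len(self.sequence)} "
                f"outside 1..{MAX_NODE_LEN}"
            )
        if not set(self.sequence) <= ALPHABET:
            bad = set(self.sequence) - ALPHABET
            raise ValueError(f"node {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class GraphPosition:
    """A single-base position: node, orientation, 0-based orientation-relative offset."""

    node_id: int
    is_reverse: bool
    offset: int


@dataclass
class Path:
    """A named walk through the graph.

    ``steps`` is an ordered list of ``(node_id, is_reverse)`` pairs;
    consecutive steps must be joined by an edge in the stated orientations.
    Alternative-allele paths have names starting with ``alt_``.
    """

    name: str
    steps: list[tuple[int, bool]] = field(default_factory=list)


@dataclass(frozen=True)
class SnpRecord:
    """Links one biallelic SNP's VCF coordinates to its two allele nodes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    ref_node_id: int
    alt_node_id: int


@dataclass
class VariationGraph:
    """Nodes, forward edges, named paths and the SNP table.

    Edges are stored once in forward orientation ``(u, v)`` with ``u < v``;
    reverse traversal is implicit.
    """

    nodes: dict[int, Node] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    paths: dict[str, Path] = field(default_factory=dict)
    snp_table: list[SnpRecord] = field(default_factory=list)

    # ------------------------------------------------------------------ caches
    def __post_init__(self) -> None:
        self._succ: dict[int, list[int]] | None = None
        self._pred: dict[int, list[int]] | None = None
        self._allele_nodes: frozenset[int] | None = None

    def _invalidate(self) -> None:
        self._succ = None
        self._pred = None
        self._allele_nodes = None

    def _adjacency(self) -> tuple[dict[int, list[int]], dict[int, list[int]]]:
        if self._succ is None or self._pred is None:
            succ: dict[int, list[int]] = {nid: [] for nid in self.nodes}
            pred: dict[int, list[int]] = {nid: [] for nid in self.nodes}
            for u, v in self.edges:
                if u in succ:
                    succ[u].append(v)
                if v in pred:
                    pred[v].append(u)
            for lst in succ.values():
                lst.sort()
            for lst in pred.values():
                lst.sort(reverse=True)
            self._succ, self._pred = succ, pred
        return self._succ, self._pred

    @property
    def allele_nodes(self) -> frozenset[int]:
        """Node ids that realize a SNP allele (ref or alt)."""
        if self._allele_nodes is None:
            ids: set[int] = set()
            for rec in self.snp_table:
                ids.add(rec.ref_node_id)
                ids.add(rec.alt_node_id)
            self._allele_nodes = frozenset(ids)
        return self._allele_nodes

    # -------------------------------------------------------------- traversal
    def node_seq(self, node_id: int) -> str:
        try:
            return self.nodes[node_id].sequence
        except KeyError:
            raise KeyError(f"unknown node id {node_id}") from None

    def oriented_seq(self, node_id: int, is_reverse: bool) -> str:
        seq = self.node_seq(node_id)
        return reverse_complement(seq) if is_reverse else seq

    def successors(self, node_id: int, is_reverse: bool) -> list[tuple[int, bool]]:
        """One-step neighbors in the given traversal direction.

        Forward traversal (``is_reverse=False``) follows forward edges to
        nodes with greater ids, sorted ascending; reverse traversal follows
        edges backwards to nodes with lower ids, sorted descending.  The
        fixed order makes the depth-limited search reproducible.
        """
        if node_id not in self.nodes:
            raise KeyError(f"unknown node id {node_id}")
        succ, pred = self._adjacency()
        if is_reverse:
            return [(u, True) for u in pred[node_id]]
        return [(v, False) for v in succ[node_id]]

    def has_edge_oriented(self, a: tuple[int, bool], b: tuple[int, bool]) -> bool:
        """True if step ``a`` can be followed by step ``b``."""
        (u, u_rev), (v, v_rev) = a, b
        if u_rev != v_rev:
            return False  # SNP-only graphs never switch strand mid-walk
        if u_rev:
            return (v, u) in self.edges
        return (u, v) in self.edges

    def spell_path(self, steps: Sequence[tuple[int, bool, int, int]]) -> str:
        """Concatenate node subsequences along connected steps.

        Each step is ``(node_id, is_reverse, start_offset, length)`` with the
        offset counted in the stated orientation.  Reverse-oriented steps
        contribute reverse-complemented sequence.
        """
        out: list[str] = []
        prev: tuple[int, bool] | None = None
        for node_id, is_reverse, start, length in steps:
            seq = self.oriented_seq(node_id, is_reverse)
            if start < 0 or length < 0 or start + length > len(seq):
                raise ValueError(
                    f"step ({node_id},{'-' if is_reverse else '+'},{start},{length}) "
                    f"out of bounds for node of length {len(seq)}"
                )
            cur = (node_id, is_reverse)
            if prev is not None and not self.has_edge_oriented(prev, cur):
                raise ValueError(f"steps {prev} -> {cur} are not connected by an edge")
            out.append(seq[start : start + length])
            prev = cur
        return "".join(out)

    def chromosome_paths(self) -> dict[str, Path]:
        return {n: p for n, p in self.paths.items() if not n.startswith("alt_")}


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def alt_path_name(chrom: str, pos: int, allele_index: int) -> str:
    """Naming scheme for per-allele paths: ``alt_<chrom>_<pos>_<0|1>``."""
    return f"alt_{chrom}_{pos}_{allele_index}"


def build_graph(
    reference: Mapping[str, str],
    snps: Iterable[tuple[str, int, str, str]],
) -> VariationGraph:
    """Build the SNP variation graph from a reference and biallelic SNPs.

    Node ids are assigned sequentially in left-to-right reference order per
    chromosome (chromosomes in input order), so every forward edge increases
    the node id.  Reference runs between SNPs are greedily chunked into
    nodes of at most 32 characters.  Each SNP becomes two parallel
    one-character allele nodes; the chromosome path takes the
    reference-allele node and each allele node gets its own ``alt_`` path.

    Raises :class:`GraphConstructionError` on a reference-base mismatch,
    duplicate SNP position, out-of-range position, an SNP at an ``N`` base,
    or non-single-character alleles, and ``ValueError`` on characters
    outside {A,C,G,T,N}.
    """
    by_chrom: dict[str, list[tuple[int, str, str]]] = {chrom: [] for chrom in reference}
    seen: set[tuple[str, int]] = set()
    for chrom, pos, ref_allele, alt_allele in snps:
        if chrom not in reference:
            raise GraphConstructionError(f"SNP on unknown chromosome {chrom!r}")
        if (chrom, pos) in seen:
            raise GraphConstructionError(f"duplicate SNP position {chrom}:{pos}")
        seen.add((chrom, pos))
        if len(ref_allele) != 1 or len(alt_allele) != 1:
            raise GraphConstructionError(
                f"{chrom}:{pos}: alleles must be single characters "
                f"({ref_allele!r}>{alt_allele!r})"
            )
        if ref_allele == alt_allele:
            raise GraphConstructionError(f"{chrom}:{pos}: ref and alt alleles are equal")
        by_chrom[chrom].append((pos, ref_allele.upper(), alt_allele.upper()))

    graph = VariationGraph()
    next_id = 1

    def add_node(seq: str) -> int:
        nonlocal next_id
        node = Node(next_id, seq)
        graph.nodes[node.id] = node
        next_id += 1
        return node.id

    for chrom, seq in reference.items():
        seq = seq.upper()
        if not set(seq) <= ALPHABET:
            bad = sorted(set(seq) - ALPHABET)
            raise ValueError(f"chromosome {chrom}: invalid characters {bad}")
        sites = sorted(by_chrom[chrom])
        for pos, ref_allele, _alt in sites:
            if not 1 <= pos <= len(seq):
                raise GraphConstructionError(
                    f"{chrom}:{pos}: position outside chromosome of length {len(seq)}"
                )
            base = seq[pos - 1]
            if base == "N":
                raise GraphConstructionError(f"{chrom}:{pos}: SNP at an N reference base")
            if base != ref_allele:
                raise GraphConstructionError(
                    f"{chrom}:{pos}: reference base {base!r} does not match "
                    f"REF allele {ref_allele!r}"
                )

        chrom_steps: list[tuple[int, bool]] = []
        # frontier: node ids whose forward edges reach the next emitted node(s)
        frontier: list[int] = []

        def link_to(new_ids: list[int]) -> None:
            for u in frontier:
                for v in new_ids:
                    graph.edges.add((u, v))

        cursor = 0  # 0-based position of the next unemitted reference base
        for pos, ref_allele, alt_allele in sites:
            run = seq[cursor : pos - 1]
            for i in range(0, len(run), MAX_NODE_LEN):
                nid = add_node(run[i : i + MAX_NODE_LEN])
                link_to([nid])
                frontier = [nid]
                chrom_steps.append((nid, False))
            ref_id = add_node(ref_allele)
            alt_id = add_node(alt_allele)
            link_to([ref_id, alt_id])
            frontier = [ref_id, alt_id]
            chrom_steps.append((ref_id, False))
            graph.snp_table.append(
                SnpRecord(chrom, pos, ref_allele, alt_allele, ref_id, alt_id)
            )
            graph.paths[alt_path_name(chrom, pos, 0)] = Path(
                alt_path_name(chrom, pos, 0), [(ref_id, False)]
            )
            graph.paths[alt_path_name(chrom, pos, 1)] = Path(
                alt_path_name(chrom, pos, 1), [(alt_id, False)]
            )
            cursor = pos
        tail = seq[cursor:]
        for i in range(0, len(tail), MAX_NODE_LEN):
            nid = add_node(tail[i : i + MAX_NODE_LEN])
            link_to([nid])
            frontier = [nid]
            chrom_steps.append((nid, False))
        graph.paths[chrom] = Path(chrom, chrom_steps)

    graph._invalidate()
    return graph


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_graph(graph: VariationGraph) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the graph is valid.  Violations are data, not
    exceptions, so callers can report all problems at once.
    """
    violations: list[str] = []

    for nid, node in graph.nodes.items():
        if nid != node.id:
            violations.append(f"node-key mismatch: key {nid} vs node.id {node.id}")
        if not 1 <= len(node.sequence) <= MAX_NODE_LEN:
            violations.append(
                f"node-length bound: node {nid} has length {len(node.sequence)}"
            )
        if not set(node.sequence) <= ALPHABET:
            violations.append(f"alphabet: node {nid} contains invalid characters")

    for u, v in sorted(graph.edges):
        if u not in graph.nodes or v not in graph.nodes:
            violations.append(f"edge endpoint missing: ({u},{v})")
            continue
        if not u < v:
            violations.append(
                f"ID monotonicity: forward edge ({u},{v}) does not increase node id"
            )

    on_path: set[int] = set()
    for name, path in graph.paths.items():
        if name != path.name:
            violations.append(f"path-key mismatch: key {name!r} vs path.name {path.name!r}")
        prev: tuple[int, bool] | None = None
        for step in path.steps:
            nid, _rev = step
            if nid not in graph.nodes:
                violations.append(f"path {name!r}: unknown node {nid}")
                prev = None
                continue
            on_path.add(nid)
            if prev is not None and not graph.has_edge_oriented(prev, step):
                violations.append(
                    f"path connectivity: {name!r} steps {prev} -> {step} not joined by an edge"
                )
            prev = step

    for nid in graph.nodes:
        if nid not in on_path:
            violations.append(f"path coverage: node {nid} lies on no path")

    succ, pred = graph._adjacency()
    for rec in graph.snp_table:
        for role, node_id, allele in (
            ("ref", rec.ref_node_id, rec.ref_allele),
            ("alt", rec.alt_node_id, rec.alt_allele),
        ):
            if node_id not in graph.nodes:
                violations.append(
                    f"SnpRecord consistency: {rec.chrom}:{rec.pos} {role} node "
                    f"{node_id} missing"
                )
                continue
            if graph.nodes[node_id].sequence != allele:
                violations.append(
                    f"SnpRecord consistency: {rec.chrom}:{rec.pos} {role} node "
                    f"{node_id} spells {graph.nodes[node_id].sequence!r}, "
                    f"expected {allele!r}"
                )
        r, a = rec.ref_node_id, rec.alt_node_id
        if r in graph.nodes and a in graph.nodes:
            if set(pred.get(r, ())) != set(pred.get(a, ())):
                violations.append(
                    f"diamond motif: {rec.chrom}:{rec.pos} allele nodes {r},{a} "
                    f"have different predecessor sets"
                )
            if set(succ.get(r, ())) != set(succ.get(a, ())):
                violations.append(
                    f"diamond motif: {rec.chrom}:{rec.pos} allele nodes {r},{a} "
                    f"have different successor sets"
                )
        alt0 = alt_path_name(rec.chrom, rec.pos, 0)
        alt1 = alt_path_name(rec.chrom, rec.pos, 1)
        if alt0 not in graph.paths or alt1 not in graph.paths:
            violations.append(
                f"alt paths: {rec.chrom}:{rec.pos} missing {alt0!r} or {alt1!r}"
            )

    return violations


# ---------------------------------------------------------------------------
# module-level wrappers (operation surface)
# ---------------------------------------------------------------------------

def successors(
    graph: VariationGraph, node_id: int, is_reverse: bool
) -> list[tuple[int, bool]]:
    """See :meth:`VariationGraph.successors`."""
    return graph.successors(node_id, is_reverse)


def spell_path(
    graph: VariationGraph, steps: Sequence[tuple[int, bool, int, int]]
) -> str:
    """See :meth:`VariationGraph.spell_path`."""
    return graph.spell_path(steps)


def haplotype_walk(
    graph: VariationGraph, chrom: str, alt_positions: Iterable[int]
) -> list[tuple[int, bool]]:
    """Chromosome walk taking the alternative allele at the given positions.

    Returns forward steps; spelling them yields the haplotype sequence in
    which each SNP in ``alt_positions`` carries its alternative base and
    every other site carries the reference base.
    """
    alt_at = set(alt_positions)
    swap: dict[int, int] = {}
    for rec in graph.snp_table:
        if rec.chrom == chrom and rec.pos in alt_at:
            swap[rec.ref_node_id] = rec.alt_node_id
    path = graph.paths[chrom]
    return [(swap.get(nid, nid), rev) for nid, rev in path.steps]


# ---------------------------------------------------------------------------
# GFA 1.0 serialization
# ---------------------------------------------------------------------------

class GfaParseError(ValueError):
    """Raised on a malformed GFA line; message includes the line number."""


def write_gfa(graph: VariationGraph) -> str:
    """Serialize to GFA 1.0 (S/L/P lines, ``0M`` overlaps).

    The SNP table is not written separately: it is fully recoverable from
    the ``alt_<chrom>_<pos>_<i>`` path names and the allele node sequences,
    which keeps the GFA self-contained.
    """
    lines = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        lines.append(f"S\t{nid}\t{graph.nodes[nid].sequence}")
    for u, v in sorted(graph.edges):
        lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
    for name in sorted(graph.paths):
        path = graph.paths[name]
        steps = ",".join(f"{nid}{'-' if rev else '+'}" for nid, rev in path.steps)
        overlaps = ",".join(["0M"] * max(len(path.steps) - 1, 0)) or "*"
        lines.append(f"P\t{name}\t{steps}\t{overlaps}")
    return "\n".join(lines) + "\n"


def _rebuild_snp_table(graph: VariationGraph) -> None:
    records: dict[tuple[str, int], dict[int, int]] = {}
    for name, path in graph.paths.items():
        if not name.startswith("alt_"):
            continue
        parts = name.split("_")
        # alt_<chrom>_<pos>_<i>; chrom may itself contain underscores
        if len(parts) < 4:
            continue
        try:
            pos = int(parts[-2])
            idx = int(parts[-1])
        except ValueError:
            continue
        chrom = "_".join(parts[1:-2])
        if len(path.steps) != 1 or idx not in (0, 1):
            continue
        records.setdefault((chrom, pos), {})[idx] = path.steps[0][0]
    for (chrom, pos), alleles in sorted(records.items()):
        if set(alleles) != {0, 1}:
            continue
        ref_id, alt_id = alleles[0], alleles[1]
        graph.snp_table.append(
            SnpRecord(
                chrom,
                pos,
                graph.nodes[ref_id].sequence,
                graph.nodes[alt_id].sequence,
                ref_id,
                alt_id,
            )
        )


def read_gfa(text: str | Iterator[str]) -> VariationGraph:
    """Parse GFA 1.0 text produced by :func:`write_gfa` (S, L, P lines).

    The round trip ``read_gfa(write_gfa(g))`` reproduces ids, sequences,
    edges, path names/steps, and the SNP table.
    """
    graph = VariationGraph()
    lines = text.splitlines() if isinstance(text, str) else text
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("H", "#")):
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag == "S":
                nid = int(fields[1])
                if nid in graph.nodes:
                    raise ValueError(f"duplicate segment id {nid}")
                graph.nodes[nid] = Node(nid, fields[2])
            elif tag == "L":
                u, u_or, v, v_or = fields[1], fields[2], fields[3], fields[4]
                if u_or != "+" or v_or != "+":
                    raise ValueError("only forward-orientation links are supported")
                graph.edges.add((int(u), int(v)))
            elif tag == "P":
                name = fields[1]
                steps: list[tuple[int, bool]] = []
                if fields[2] != "*" and fields[2]:
                    for token in fields[2].split(","):
                        orient = token[-1]
                        if orient not in "+-":
                            raise ValueError(f"bad path step {token!r}")
                        steps.append((int(token[:-1]), orient == "-"))
                graph.paths[name] = Path(name, steps)
            # other record types are ignored
        except (IndexError, ValueError) as exc:
            raise GfaParseError(f"GFA line {lineno}: {exc}") from None
    graph._invalidate()
    _rebuild_snp_table(graph)
    return graph
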