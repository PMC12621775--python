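"""Bidirected variation-graph model with GFA v1 I/O.

A variation graph is a bidirected graph whose nodes carry nucleotide
sequences and whose edges join node *sides* (left or right end of a node).
A walk traverses nodes in an orientation: a forward visit enters the left
side and exits the right side and spells the node sequence; a reverse visit
enters the right side, exits the left, and spells the reverse complement.
Named walks embed the reference and the haplotype panel in the graph.

Offsets are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import BoundsError, BrokenWalkError, GFAParseError, UnsupportedDialectError

LEFT = 0
RIGHT = 1

FORWARD = 0
REVERSE = 1

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N is its own complement."""
    return seq.translate(_COMP)[::-1]


class NodeSide(NamedTuple):
    """One end of a node; edges join pairs of these."""

    node_id: int
    side: int  # LEFT or RIGHT

    def opposite(self) -> "NodeSide":
        return NodeSide(self.node_id, 1 - self.side)

    def __repr__(self):
        return f"{self.node_id}{'LR'[self.side]}"


class OrientedNode(NamedTuple):
    """A node visit with direction: forward enters left/exits right."""

    node_id: int
    orientation: int  # FORWARD or REVERSE

    def flip(self) -> "OrientedNode":
        return OrientedNode(self.node_id, 1 - self.orientation)

    @property
    def entry_side(self) -> NodeSide:
        return NodeSide(self.node_id, LEFT if self.orientation == FORWARD else RIGHT)

    @property
    def exit_side(self) -> NodeSide:
        return NodeSide(self.node_id, RIGHT if self.orientation == FORWARD else LEFT)

    def __repr__(self):
        return f"{self.node_id}{'+-'[self.orientation]}"


class Position(NamedTuple):
    """A single base in the graph: node, reading orientation and 0-based
    offset into the oriented node sequence."""

    node_id: int
    orientation: int
    offset: int

    def __repr__(self):
        return f"({self.node_id}{'+-'[self.orientation]},{self.offset})"


REFERENCE = "reference"
HAPLOTYPE = "haplotype"


@dataclass
class Walk:
    """A named walk through the graph (a reference path or a haplotype)."""

    name: str
    steps: list[OrientedNode]
    role: str = HAPLOTYPE

    def reversed(self) -> "Walk":
        """The same walk read in the opposite direction."""
        return Walk(self.name + "~rev", [s.flip() for s in self.steps[::-1]], self.role)


def _edge_key(a: NodeSide, b: NodeSide) -> tuple[NodeSide, NodeSide]:
    return (a, b) if a <= b else (b, a)


@dataclass
class VariationGraph:
    """Sequence-labeled bidirected graph with embedded walks."""

    sequences: dict[int, str] = field(default_factory=dict)
    edges: set[tuple[NodeSide, NodeSide]] = field(default_factory=set)
    walks: list[Walk] = field(default_factory=list)
    _adjacency: dict[NodeSide, list[NodeSide]] | None = field(
        default=None, repr=False, compare=False
    )

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: int, seq: str) -> None:
        if node_id <= 0:
            raise ValueError(f"node ids must be positive, got {node_id}")
        if not seq:
            raise ValueError(f"node {node_id} has an empty sequence")
        self.sequences[node_id] = seq.upper()
        self._adjacency = None

    def add_edge(self, a: NodeSide, b: NodeSide) -> None:
        for s in (a, b):
            if s.node_id not in self.sequences:
                raise ValueError(f"edge endpoint references unknown node {s.node_id}")
        self.edges.add(_edge_key(a, b))
        self._adjacency = None

    def add_walk(self, name: str, steps: Iterable[OrientedNode], role: str = HAPLOTYPE) -> Walk:
        walk = Walk(name, list(steps), role)
        self.validate_walk(walk)
        self.walks.append(walk)
        return walk

    # -- basic queries -----------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.sequences)

    def node_len(self, node_id: int) -> int:
        return len(self.sequences[node_id])

    def has_edge(self, a: NodeSide, b: NodeSide) -> bool:
        return _edge_key(a, b) in self.edges

    def adjacency(self) -> dict[NodeSide, list[NodeSide]]:
        """side -> sorted list of sides joined to it by an edge (self-loops
        appear once)."""
        if self._adjacency is None:
            adj: dict[NodeSide, list[NodeSide]] = {}
            for nid in self.sequences:
                adj[NodeSide(nid, LEFT)] = []
                adj[NodeSide(nid, RIGHT)] = []
            for a, b in self.edges:
                adj[a].append(b)
                if b != a:
                    adj[b].append(a)
            for lst in adj.values():
                lst.sort()
            self._adjacency = adj
        return self._adjacency

    def haplotype_walks(self) -> list[Walk]:
        return [w for w in self.walks if w.role == HAPLOTYPE]

    def reference_walks(self) -> list[Walk]:
        return [w for w in self.walks if w.role == REFERENCE]

    def total_sequence_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    # -- validation --------------------------------------------------------

    def validate_walk(self, walk: Walk) -> None:
        for step in walk.steps:
            if step.node_id not in self.sequences:
                raise BrokenWalkError(
                    f"walk {walk.name!r} visits unknown node {step.node_id}"
                )
        for i in range(len(walk.steps) - 1):
            a, b = walk.steps[i], walk.steps[i + 1]
            if not self.has_edge(a.exit_side, b.entry_side):
                raise BrokenWalkError(
                    f"walk {walk.name!r}: no edge joins step {i} ({a}) to step "
                    f"{i + 1} ({b})",
                    step_index=i,
                )

    def validate(self) -> None:
        for nid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"node {nid} has an empty sequence")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"node {nid} has non-ACGTN characters {bad}")
        for a, b in self.edges:
            for s in (a, b):
                if s.node_id not in self.sequences:
                    raise ValueError(f"edge endpoint references unknown node {s.node_id}")
        for walk in self.walks:
            self.validate_walk(walk)

    def prune_unsupported_edges(self) -> int:
        """Drop edges used by no stored walk; returns the number removed.

        Mirrors the convention of haplotype-panel graph formats in which the
        stored walks implicitly define the edge set.
        """
        used: set[tuple[NodeSide, NodeSide]] = set()
        for walk in self.walks:
            for i in range(len(walk.steps) - 1):
                used.add(
                    _edge_key(walk.steps[i].exit_side, walk.steps[i + 1].entry_side)
                )
        dropped = self.edges - used
        self.edges -= dropped
        self._adjacency = None
        return len(dropped)


# -- sequence extraction ---------------------------------------------------


def oriented_sequence(graph: VariationGraph, node: OrientedNode) -> str:
    seq = graph.sequences[node.node_id]
    return seq if node.orientation == FORWARD else revcomp(seq)


def walk_sequence(graph: VariationGraph, walk: Walk) -> str:
    """Concatenated oriented node sequences along a walk."""
    graph.validate_walk(walk)
    return "".join(oriented_sequence(graph, step) for step in walk.steps)


def extract_base(graph: VariationGraph, pos: Position) -> str:
    """The single base at a graph position (oriented)."""
    if pos.node_id not in graph.sequences:
        raise BoundsError(f"unknown node {pos.node_id}")
    n = graph.node_len(pos.node_id)
    if not 0 <= pos.offset < n:
        raise BoundsError(
            f"offset {pos.offset} out of range for node {pos.node_id} (length {n})"
        )
    seq = graph.sequences[pos.node_id]
    if pos.orientation == FORWARD:
        return seq[pos.offset]
    return revcomp(seq)[pos.offset]


def reverse_position(graph: VariationGraph, pos: Position) -> Position:
    """The same base read on the opposite strand (mirrored offset)."""
    n = graph.node_len(pos.node_id)
    return Position(pos.node_id, 1 - pos.orientation, n - 1 - pos.offset)


# -- GFA v1 I/O ------------------------------------------------------------

_ORIENT = {"+": FORWARD, "-": REVERSE}

# L-line orientations to the sides an edge joins: the from-node is exited
# (via right if +, left if -) and the to-node is entered (left if +, right
# if -).


def _l_line_sides(from_id, from_o, to_id, to_o):
    a = NodeSide(from_id, RIGHT if from_o == FORWARD else LEFT)
    b = NodeSide(to_id, LEFT if to_o == FORWARD else RIGHT)
    return a, b


def parse_gfa(stream, reference_prefixes: tuple[str, ...] = ("ref",)) -> VariationGraph:
    """Parse GFA v1 (S, L with 0M/* overlap, P and W lines) into a graph.

    Walk names matching any of ``reference_prefixes`` are stored with the
    reference role; all others are haplotypes.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = VariationGraph()
    deferred: list[tuple[int, list[str]]] = []  # L/P/W processed after all S lines
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GFAParseError("S line needs id and sequence", lineno)
            try:
                nid = int(fields[1])
            except ValueError:
                raise GFAParseError(
                    f"node ids must be integers, got {fields[1]!r}", lineno
                ) from None
            if fields[2] in ("", "*"):
                raise GFAParseError(f"node {nid} has no sequence", lineno)
            graph.add_node(nid, fields[2])
        elif tag in ("L", "P", "W"):
            deferred.append((lineno, fields))
        elif tag == "H":
            continue
        # other record types are ignored

    for lineno, fields in deferred:
        tag = fields[0]
        if tag == "L":
            if len(fields) < 6:
                raise GFAParseError("L line needs 5 fields", lineno)
            try:
                fid, tid = int(fields[1]), int(fields[3])
            except ValueError:
                raise GFAParseError("L line node ids must be integers", lineno) from None
            for nid in (fid, tid):
                if nid not in graph.sequences:
                    raise GFAParseError(f"L line references unknown node {nid}", lineno)
            if fields[2] not in _ORIENT or fields[4] not in _ORIENT:
                raise GFAParseError("L line orientations must be + or -", lineno)
            if fields[5] not in ("0M", "*"):
                raise UnsupportedDialectError(
                    f"only 0M/* overlaps are supported, got {fields[5]!r}", lineno
                )
            a, b = _l_line_sides(fid, _ORIENT[fields[2]], tid, _ORIENT[fields[4]])
            graph.add_edge(a, b)
        elif tag == "P":
            if len(fields) < 3:
                raise GFAParseError("P line needs a name and step list", lineno)
            name = fields[1]
            steps = []
            for tok in fields[2].split(","):
                if len(tok) < 2 or tok[-1] not in "+-":
                    raise GFAParseError(f"bad path step {tok!r}", lineno)
                try:
                    nid = int(tok[:-1])
                except ValueError:
                    raise GFAParseError(f"bad path step {tok!r}", lineno) from None
                if nid not in graph.sequences:
                    raise GFAParseError(
                        f"P line references unknown node {nid}", lineno
                    )
                steps.append(OrientedNode(nid, _ORIENT[tok[-1]]))
            role = (
                REFERENCE
                if any(name.startswith(p) for p in reference_prefixes)
                else HAPLOTYPE
            )
            try:
                graph.add_walk(name, steps, role)
            except BrokenWalkError as exc:
                raise GFAParseError(str(exc), lineno) from exc
        elif tag == "W":
            if len(fields) < 7:
                raise GFAParseError("W line needs 6 fields", lineno)
            sample, hap = fields[1], fields[2]
            name = f"{sample}#{hap}#{fields[3]}"
            steps = []
            walk_str = fields[6]
            i = 0
            while i < len(walk_str):
                glyph = walk_str[i]
                if glyph not in "><":
                    raise GFAParseError(f"bad W walk string at {walk_str[i:]!r}", lineno)
                j = i + 1
                while j < len(walk_str) and walk_str[j] not in "><":
                    j += 1
                try:
                    nid = int(walk_str[i + 1 : j])
                except ValueError:
                    raise GFAParseError(f"bad W walk node {walk_str[i+1:j]!r}", lineno) from None
                if nid not in graph.sequences:
                    raise GFAParseError(
                        f"W line references unknown node {nid}", lineno
                    )
                steps.append(
                    OrientedNode(nid, FORWARD if glyph == ">" else REVERSE)
                )
                i = j
            role = (
                REFERENCE
                if any(sample.startswith(p) for p in reference_prefixes)
                else HAPLOTYPE
            )
            try:
                graph.add_walk(name, steps, role)
            except BrokenWalkError as exc:
                raise GFAParseError(str(exc), lineno) from exc
    return graph


def write_gfa(graph: VariationGraph, stream=None) -> str | None:
    """Serialize to GFA v1 (S, L, P). Returns the text when stream is None."""
    out = io.StringIO() if stream is None else stream
    out.write("H\tVN:Z:1.0\n")
    for nid in sorted(graph.sequences):
        out.write(f"S\t{nid}\t{graph.sequences[nid]}\n")
    for a, b in sorted(graph.edges):
        # emit as from-node exited via a, to-node entered via b
        from_o = "+" if a.side == RIGHT else "-"
        to_o = "+" if b.side == LEFT else "-"
        out.write(f"L\t{a.node_id}\t{from_o}\t{b.node_id}\t{to_o}\t0M\n")
    for walk in graph.walks:
        steps = ",".join(f"{s.node_id}{'+-'[s.orientation]}" for s in walk.steps)
        out.write(f"P\t{walk.name}\t{steps}\t*\n")
    if stream is None:
        return out.getvalue()
    return None


def read_sequences(path):
    """Yield (name, sequence) from FASTA/FASTQ, plain or gzipped."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        first = handle.read(1)
        handle.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq).upper()
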