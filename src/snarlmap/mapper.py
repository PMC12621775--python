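"""End-to-end single-read mapping: seed, chain, extend, score, GAF out.

``Mapper`` bundles the indexes built from a graph (snarl tree, distance
index, minimizer index, haplotype walk index) and maps reads one at a
time. The primary alignment gets a mapping quality in [0, 60] from the
score margin between the best and the best *distinctly placed* secondary
alignment; reads with no extendable chain are reported unmapped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .align import (
    AlignmentPath,
    ChainExtensionError,
    ExtensionParams,
    HaplotypeWalkIndex,
    Scoring,
    extend_chain,
)
from .chain import ChainingParams, chain_anchors
from .distance import build_distance_index
from .errors import SnarlmapError
from .graph import FORWARD, OrientedNode, VariationGraph, oriented_sequence
from .seeds import MinimizerIndex, SeedingParams, build_minimizer_index, select_seeds
from .snarls import decompose
from .zipcodes import build_zip_forest

__all__ = [
    "GraphAlignment",
    "MapperParams",
    "Mapper",
    "compute_mapq",
    "write_gaf",
    "parse_gaf",
    "GafRecord",
]


@dataclass
class MapperParams:
    seeding: SeedingParams = field(default_factory=SeedingParams)
    chaining: ChainingParams = field(default_factory=ChainingParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    max_alignments: int = 1
    mapq_cap: int = 60
    # two placements overlapping this much (of the smaller) are one site
    same_site_overlap: float = 0.5
    # below this fraction of the perfect score the read is unmapped
    min_score_fraction: float = 0.1
    # chains scoring below this fraction of the best chain are not
    # extended (they cannot produce a competitive alignment)
    chain_score_fraction: float = 0.5


@dataclass
class GraphAlignment:
    """A scored read-to-graph alignment ready for GAF serialization."""

    name: str
    read_len: int
    path: AlignmentPath
    score: int
    mapq: int = 60
    secondary: bool = False

    @property
    def read_start(self):
        return self.path.left_clip

    @property
    def read_end(self):
        return self.read_len - self.path.right_clip


def compute_mapq(primary_score, secondary_score, min_possible, max_possible) -> int:
    """Phred-like confidence from the score margin, capped at 60.

    ``60 * (primary - secondary) / (primary - min_possible)``, rounded and
    clamped to [0, 60]; a read with no secondary placement gets 60.
    """
    if secondary_score is None:
        return 60
    if primary_score < secondary_score:
        raise SnarlmapError("primary score below secondary score")
    denom = primary_score - min_possible
    if denom <= 0:
        return 0
    q = 60.0 * (primary_score - secondary_score) / denom
    return max(0, min(60, round(q)))


# ---------------------------------------------------------------------------
# Mapper
# ---------------------------------------------------------------------------


class Mapper:
    """Builds all indexes for a graph and maps reads."""

    def __init__(self, graph: VariationGraph, params: MapperParams | None = None):
        self.graph = graph
        self.params = params or MapperParams()
        self.snarl_tree = decompose(graph)
        self.distance_index = build_distance_index(graph, self.snarl_tree)
        self.minimizer_index = build_minimizer_index(graph, self.params.seeding)
        self.walk_index = HaplotypeWalkIndex(graph)
        self.stats = {"mapped": 0, "unmapped": 0, "chains_failed": 0}

    # -- core -------------------------------------------------------------

    def map_read(self, name: str, read: str) -> list[GraphAlignment]:
        """Map one read; empty list means unmapped."""
        read = read.upper()
        p = self.params
        seeds = select_seeds(read, self.minimizer_index, p.seeding)
        if not seeds:
            self.stats["unmapped"] += 1
            return []
        forest = build_zip_forest(seeds, self.distance_index)
        chains = []
        for tree in forest:
            chains.extend(chain_anchors(tree, p.chaining))
        chains.sort(key=lambda c: (-c.score, c.read_start, str(c.anchors[0].pos)))
        chains = _dedupe_chains(chains)[: p.chaining.max_chains]
        if chains:
            floor = chains[0].score * p.chain_score_fraction
            chains = [c for c in chains if c.score >= floor]

        aligns: list[tuple[int, AlignmentPath]] = []
        for c in chains:
            try:
                path = extend_chain(
                    read, c, self.graph, self.distance_index, p.extension, self.walk_index
                )
            except (ChainExtensionError, AssertionError):
                self.stats["chains_failed"] += 1
                continue
            aligns.append((path.score, path))
        if not aligns:
            self.stats["unmapped"] += 1
            return []
        aligns.sort(key=lambda t: (-t[0], t[1].left_clip))
        primary_score, primary = aligns[0]
        max_possible = len(read) * p.extension.scoring.match
        if primary_score < p.min_score_fraction * max_possible:
            self.stats["unmapped"] += 1
            return []
        secondary_score = None
        for s, a in aligns[1:]:
            if not self._same_site(primary, a):
                secondary_score = s
                break
        mapq = compute_mapq(primary_score, secondary_score, 0, max_possible)
        mapq = min(mapq, p.mapq_cap)
        out = [GraphAlignment(name, len(read), primary, primary_score, mapq)]
        for s, a in aligns[1 : p.max_alignments]:
            out.append(GraphAlignment(name, len(read), a, s, 0, secondary=True))
        self.stats["mapped"] += 1
        return out

    def map_reads(self, reads):
        """Map (name, seq) pairs; yields GraphAlignment lists per read."""
        for name, seq in reads:
            yield self.map_read(name, seq)

    def _same_site(self, a: AlignmentPath, b: AlignmentPath) -> bool:
        ia = _span_interval_set(self.graph, a.spans)
        ib = _span_interval_set(self.graph, b.spans)
        shared = 0
        for key, ivs in ib.items():
            for lo, hi in ivs:
                for lo2, hi2 in ia.get(key, ()):
                    shared += max(0, min(hi, hi2) - max(lo, lo2))
        smaller = min(
            sum(hi - lo for ivs in ia.values() for lo, hi in ivs),
            sum(hi - lo for ivs in ib.values() for lo, hi in ivs),
        )
        return smaller > 0 and shared / smaller >= self.params.same_site_overlap


def _span_interval_set(graph, spans):
    out: dict = {}
    for node, lo, hi in spans:
        n = graph.node_len(node.node_id)
        if node.orientation == FORWARD:
            iv = (lo, hi)
        else:
            iv = (n - hi, n - lo)
        out.setdefault(node.node_id, []).append(iv)
    return out


def _dedupe_chains(chains):
    seen = set()
    out = []
    for c in chains:
        key = (c.read_start, c.read_end, c.anchors[0].pos, c.anchors[-1].pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# GAF
# ---------------------------------------------------------------------------


def _path_string(steps: list[OrientedNode]) -> str:
    return "".join(("<" if s.orientation else ">") + str(s.node_id) for s in steps)


def _cs_tag(graph, read: str, aln: GraphAlignment) -> str:
    """Difference string (cs:Z) over the aligned region."""
    target = "".join(
        oriented_sequence(graph, node)[lo:hi] for node, lo, hi in aln.path.spans
    )
    qi = aln.read_start
    ti = 0
    parts = []
    for op, ln in aln.path.ops:
        if op == "=":
            parts.append(f":{ln}")
            qi += ln
            ti += ln
        elif op == "X":
            for t in range(ln):
                parts.append(f"*{target[ti + t].lower()}{read[qi + t].lower()}")
            qi += ln
            ti += ln
        elif op == "I":
            parts.append(f"+{read[qi : qi + ln].lower()}")
            qi += ln
        else:
            parts.append(f"-{target[ti : ti + ln].lower()}")
            ti += ln
    return "".join(parts)


def write_gaf(alignments, stream=None, graph: VariationGraph | None = None, reads=None):
    """Serialize alignments as GAF records (0-based, half-open).

    ``graph`` enables the path-length column and, with ``reads`` (a dict
    name -> sequence), the cs:Z difference tag. Unmapped reads produce no
    record. Returns the text when ``stream`` is None.
    """
    out = io.StringIO() if stream is None else stream
    for aln in alignments:
        steps = aln.path.steps
        path_str = _path_string(steps) if steps else "*"
        if graph is not None and steps:
            path_len = sum(graph.node_len(s.node_id) for s in steps)
        else:
            path_len = aln.path.walk_span
        pstart = aln.path.start_offset
        pend = pstart + aln.path.walk_span
        fields = [
            aln.name,
            aln.read_len,
            aln.read_start,
            aln.read_end,
            "+",
            path_str,
            path_len,
            pstart,
            pend,
            aln.path.matches(),
            sum(ln for _, ln in aln.path.ops),
            aln.mapq,
            f"AS:i:{aln.score}",
            f"tp:A:{'S' if aln.secondary else 'P'}",
        ]
        if graph is not None and reads is not None and aln.name in reads:
            fields.append("cs:Z:" + _cs_tag(graph, reads[aln.name].upper(), aln))
        out.write("\t".join(str(f) for f in fields) + "\n")
    if stream is None:
        return out.getvalue()
    return None


@dataclass
class GafRecord:
    name: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    steps: list[OrientedNode]
    path_len: int
    pstart: int
    pend: int
    matches: int
    block: int
    mapq: int
    tags: dict

    @property
    def secondary(self) -> bool:
        return self.tags.get("tp") == "S"

    @property
    def score(self):
        return int(self.tags["AS"]) if "AS" in self.tags else None

    def graph_intervals(self, graph: VariationGraph):
        """Aligned (node, lo, hi) intervals in node-forward coordinates."""
        out = []
        consumed = 0
        for s in self.steps:
            n = graph.node_len(s.node_id)
            a = max(self.pstart, consumed)
            b = min(self.pend, consumed + n)
            if a < b:
                lo, hi = a - consumed, b - consumed
                if s.orientation == FORWARD:
                    out.append((s.node_id, lo, hi))
                else:
                    out.append((s.node_id, n - hi, n - lo))
            consumed += n
        return out


def parse_gaf(stream) -> list[GafRecord]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        steps = []
        if f[5] != "*":
            i = 0
            while i < len(f[5]):
                orient = 0 if f[5][i] == ">" else 1
                j = i + 1
                while j < len(f[5]) and f[5][j] not in "<>":
                    j += 1
                steps.append(OrientedNode(int(f[5][i + 1 : j]), orient))
                i = j
        tags = {}
        for tag in f[12:]:
            k, _typ, v = tag.split(":", 2)
            tags[k] = v
        out.append(
            GafRecord(
                f[0],
                int(f[1]),
                int(f[2]),
                int(f[3]),
                f[4],
                steps,
                int(f[6]),
                int(f[7]),
                int(f[8]),
                int(f[9]),
                int(f[10]),
                int(f[11]),
                tags,
            )
        )
    return out
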