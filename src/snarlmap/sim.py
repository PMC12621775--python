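"""Synthetic pangenomes, reads and mapping evaluation.

``simulate_graph`` builds a variation graph by applying variant events
(SNPs, indels, inversions, tandem duplications) to a random linear
backbone and threading haplotype walks through the chosen alleles.
``simulate_reads`` samples error-injected reads from those haplotypes with
truth records; ``evaluate_mappings`` scores a GAF against the truth,
stratified by mapping quality.

Everything is deterministic given the RNG seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError, GenerationError
from .graph import (
    FORWARD,
    HAPLOTYPE,
    REFERENCE,
    REVERSE,
    NodeSide,
    OrientedNode,
    VariationGraph,
    revcomp,
    walk_sequence,
)

_BASES = np.array(list("ACGT"))


@dataclass
class GraphSimParams:
    """Event rates and sizes for synthetic pangenome construction."""

    backbone_len: int = 10_000
    snp_rate: float = 0.001
    indel_rate: float = 0.0002
    indel_len_mean: float = 3.0
    indel_len_max: int = 20
    inversion_count: int = 0
    inversion_len: int = 100
    duplication_count: int = 0
    duplication_len: int = 100
    haplotype_count: int = 4
    alt_freq: float = 0.5
    seed: int = 0

    def validate(self):
        for r in (self.snp_rate, self.indel_rate, self.alt_freq):
            if not 0 <= r <= 1:
                raise GenerationError(f"rates must be in [0,1], got {r}")
        for L in (
            self.backbone_len,
            self.indel_len_max,
            self.inversion_len,
            self.duplication_len,
            self.haplotype_count,
        ):
            if L <= 0:
                raise GenerationError("lengths and counts must be positive")


@dataclass
class ReadSimParams:
    """Read sampling and parametric error model.

    Two conventional presets: hifi-like (0.5% total error) and ont-like
    (5% total error); see :func:`error_preset`.
    """

    read_len_min: int = 1000
    read_len_max: int = 10_000
    sub_rate: float = 0.003
    ins_rate: float = 0.001
    del_rate: float = 0.001
    count: int = 100
    seed: int = 0

    def validate(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise GenerationError(f"error rates must be in [0,1), got {r}")


def error_preset(name: str) -> dict:
    """Named per-base error-rate presets (substitution, insertion, deletion)."""
    if name == "hifi":
        return dict(sub_rate=0.002, ins_rate=0.0015, del_rate=0.0015)
    if name == "ont":
        return dict(sub_rate=0.02, ins_rate=0.015, del_rate=0.015)
    raise GenerationError(f"unknown error preset {name!r}")


@dataclass
class TruthRecord:
    """Where a simulated read really came from."""

    name: str
    haplotype: str
    hap_start: int
    hap_end: int
    strand: str  # '+' or '-'
    # projection onto graph coordinates: (node_id, lo, hi) half-open,
    # in node-forward coordinates
    graph_intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def to_tsv(self) -> str:
        ivs = ",".join(f"{n}:{lo}-{hi}" for n, lo, hi in self.graph_intervals)
        return (
            f"{self.name}\t{self.haplotype}\t{self.hap_start}\t{self.hap_end}"
            f"\t{self.strand}\t{ivs}"
        )

    @classmethod
    def from_tsv(cls, line: str) -> "TruthRecord":
        name, hap, s, e, strand, ivs = line.rstrip("\n").split("\t")
        out = cls(name, hap, int(s), int(e), strand)
        if ivs:
            for tok in ivs.split(","):
                n, rng = tok.split(":")
                lo, hi = rng.split("-")
                out.graph_intervals.append((int(n), int(lo), int(hi)))
        return out


# ---------------------------------------------------------------------------
# Graph simulation
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def simulate_graph(params: GraphSimParams) -> VariationGraph:
    """Build a synthetic pangenome; walks are ``ref`` plus ``hap{i}``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    B = params.backbone_len
    backbone = _random_seq(rng, B)

    # --- place events without overlap (1 bp of backbone between events) --
    events = []  # (start, end, kind, payload)

    def _try_place(length, kind, payload=None, tries=200):
        for _ in range(tries):
            s = int(rng.integers(1, max(2, B - length - 1)))
            e = s + length
            if all(e + 1 < s2 or s > e2 + 1 for s2, e2, _, _ in events):
                events.append((s, e, kind, payload))
                return True
        return False

    n_snp = rng.binomial(B, params.snp_rate)
    n_indel = rng.binomial(B, params.indel_rate)
    for _ in range(params.inversion_count):
        if not _try_place(params.inversion_len, "inv"):
            raise GenerationError("could not place inversion without overlap")
    for _ in range(params.duplication_count):
        if not _try_place(params.duplication_len, "dup"):
            raise GenerationError("could not place duplication without overlap")
    for _ in range(int(n_indel)):
        ln = min(1 + rng.geometric(1.0 / params.indel_len_mean), params.indel_len_max)
        if rng.random() < 0.5:
            _try_place(int(ln), "del")
        else:
            # insertion occupies no backbone; anchor at a point
            _try_place(0, "ins", _random_seq(rng, int(ln)))
    for _ in range(int(n_snp)):
        _try_place(1, "snp")
    events.sort()

    # --- build slots ------------------------------------------------------
    graph = VariationGraph()
    next_id = [1]

    def new_node(seq):
        nid = next_id[0]
        graph.add_node(nid, seq)
        next_id[0] += 1
        return nid

    # slot: dict(kind, in_sides, out_sides, passthrough, alleles)
    # alleles: hap chooses steps via a callable(allele_code) -> [OrientedNode]
    slots = []
    cursor = 0
    for s, e, kind, payload in events:
        if s > cursor:
            nid = new_node(backbone[cursor:s])
            slots.append(
                dict(kind="plain", nid=nid, passthrough=False)
            )
        cursor = e
        if kind == "snp":
            ref = backbone[s]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            r, a = new_node(ref), new_node(alt)
            slots.append(dict(kind="snp", ref=r, alt=a, passthrough=False))
        elif kind == "del":
            nid = new_node(backbone[s:e])
            slots.append(dict(kind="del", nid=nid, passthrough=True))
        elif kind == "ins":
            nid = new_node(payload)
            slots.append(dict(kind="ins", nid=nid, passthrough=True))
        elif kind == "inv":
            nid = new_node(backbone[s:e])
            slots.append(dict(kind="inv", nid=nid, passthrough=False))
        elif kind == "dup":
            nid = new_node(backbone[s:e])
            slots.append(dict(kind="dup", nid=nid, passthrough=False))
    if cursor < B:
        nid = new_node(backbone[cursor:B])
        slots.append(dict(kind="plain", nid=nid, passthrough=False))

    # --- wire edges -------------------------------------------------------
    from .graph import LEFT, RIGHT

    def in_sides(slot):
        k = slot["kind"]
        if k in ("plain", "del", "ins", "dup"):
            return [NodeSide(slot["nid"], LEFT)]
        if k == "snp":
            return [NodeSide(slot["ref"], LEFT), NodeSide(slot["alt"], LEFT)]
        if k == "inv":
            return [NodeSide(slot["nid"], LEFT), NodeSide(slot["nid"], RIGHT)]
        raise AssertionError(k)

    def out_sides(slot):
        k = slot["kind"]
        if k in ("plain", "del", "ins", "dup"):
            return [NodeSide(slot["nid"], RIGHT)]
        if k == "snp":
            return [NodeSide(slot["ref"], RIGHT), NodeSide(slot["alt"], RIGHT)]
        if k == "inv":
            return [NodeSide(slot["nid"], RIGHT), NodeSide(slot["nid"], LEFT)]
        raise AssertionError(k)

    frontier: list[NodeSide] = []
    for slot in slots:
        for a in frontier:
            for b in in_sides(slot):
                graph.add_edge(a, b)
        if slot["passthrough"]:
            frontier = frontier + out_sides(slot)
        else:
            frontier = out_sides(slot)
        if slot["kind"] == "dup":
            graph.add_edge(
                NodeSide(slot["nid"], RIGHT), NodeSide(slot["nid"], LEFT)
            )

    # --- walks ------------------------------------------------------------
    def make_walk(name, role, choose):
        steps = []
        for slot in slots:
            k = slot["kind"]
            if k == "plain":
                steps.append(OrientedNode(slot["nid"], FORWARD))
            elif k == "snp":
                steps.append(
                    OrientedNode(slot["alt" if choose(slot) else "ref"], FORWARD)
                )
            elif k == "del":
                if not choose(slot):
                    steps.append(OrientedNode(slot["nid"], FORWARD))
            elif k == "ins":
                if choose(slot):
                    steps.append(OrientedNode(slot["nid"], FORWARD))
            elif k == "inv":
                steps.append(
                    OrientedNode(slot["nid"], REVERSE if choose(slot) else FORWARD)
                )
            elif k == "dup":
                steps.append(OrientedNode(slot["nid"], FORWARD))
                if choose(slot):
                    steps.append(OrientedNode(slot["nid"], FORWARD))
        return graph.add_walk(name, steps, role)

    make_walk("ref", REFERENCE, lambda slot: False)
    # fixed allele table per event slot x haplotype
    event_slots = [s for s in slots if s["kind"] != "plain"]
    table = rng.random((params.haplotype_count, max(1, len(event_slots))))
    slot_index = {id(s): i for i, s in enumerate(event_slots)}
    for h in range(params.haplotype_count):
        make_walk(
            f"hap{h}",
            HAPLOTYPE,
            lambda slot, h=h: table[h, slot_index[id(slot)]] < params.alt_freq,
        )
    graph.validate()
    return graph


def random_variation_graph(seed: int, max_nodes: int = 50) -> VariationGraph:
    """A small random variation graph with dense variation, inversions and
    loops — the workhorse fixture for randomized property tests."""
    rng = np.random.default_rng(seed)
    backbone = int(rng.integers(30, max(40, max_nodes * 4)))
    p = GraphSimParams(
        backbone_len=backbone,
        snp_rate=0.08,
        indel_rate=0.03,
        indel_len_mean=2.0,
        indel_len_max=6,
        inversion_count=int(rng.integers(0, 3)),
        inversion_len=max(3, backbone // 12),
        duplication_count=int(rng.integers(0, 3)),
        duplication_len=max(3, backbone // 12),
        haplotype_count=int(rng.integers(2, 6)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    for _ in range(10):
        try:
            g = simulate_graph(p)
        except GenerationError:
            p.inversion_count = max(0, p.inversion_count - 1)
            p.duplication_count = max(0, p.duplication_count - 1)
            continue
        if len(g.sequences) <= max_nodes:
            return g
        p.backbone_len = max(30, p.backbone_len * 2 // 3)
        p.snp_rate *= 0.7
        p.indel_rate *= 0.7
    return g


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _walk_offset_index(graph, walk):
    """Cumulative start offset of each step along the walk's sequence."""
    offs = [0]
    for st in walk.steps:
        offs.append(offs[-1] + graph.node_len(st.node_id))
    return offs


def _project_interval(graph, walk, lo, hi):
    """Project a half-open walk interval to node-forward graph intervals."""
    offs = _walk_offset_index(graph, walk)
    out = []
    for i, st in enumerate(walk.steps):
        s, e = offs[i], offs[i + 1]
        a, b = max(lo, s), min(hi, e)
        if a >= b:
            continue
        n = graph.node_len(st.node_id)
        if st.orientation == FORWARD:
            out.append((st.node_id, a - s, b - s))
        else:
            out.append((st.node_id, n - (b - s), n - (a - s)))
    return out


def simulate_reads(
    graph: VariationGraph,
    haplotypes: list,
    params: ReadSimParams,
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Sample reads uniformly over haplotype positions and strands.

    Returns (reads, truth) where reads are (name, sequence, quality)
    triples ready for FASTQ output.
    """
    params.validate()
    if not haplotypes:
        raise GenerationError("no haplotypes to sample reads from")
    rng = np.random.default_rng(params.seed)
    seqs = {w.name: walk_sequence(graph, w) for w in haplotypes}
    names = sorted(seqs)
    reads, truth = [], []
    skipped = 0
    for i in range(params.count):
        hap = names[int(rng.integers(0, len(names)))]
        hseq = seqs[hap]
        ln = int(rng.integers(params.read_len_min, params.read_len_max + 1))
        if ln > len(hseq):
            skipped += 1
            continue
        start = int(rng.integers(0, len(hseq) - ln + 1))
        frag = hseq[start : start + ln]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        seq = _inject_errors(rng, frag, params)
        name = f"read{i}"
        reads.append((name, seq, "I" * len(seq)))
        walk = next(w for w in haplotypes if w.name == hap)
        rec = TruthRecord(
            name,
            hap,
            start,
            start + ln,
            strand,
            _project_interval(graph, walk, start, start + ln),
        )
        truth.append(rec)
    if skipped:
        import sys

        print(
            f"warning: skipped {skipped} reads longer than their haplotype",
            file=sys.stderr,
        )
    return reads, truth


def _inject_errors(rng, seq: str, params: ReadSimParams) -> str:
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r < params.del_rate:
            continue
        if r < params.del_rate + params.ins_rate:
            out.append(bases[int(rng.integers(0, 4))])
        if rng.random() < params.sub_rate:
            alts = [b for b in bases if b != ch]
            out.append(alts[int(rng.integers(0, 3))])
        else:
            out.append(ch)
    return "".join(out)


def write_fastq(reads, stream=None) -> str | None:
    out = io.StringIO() if stream is None else stream
    for name, seq, qual in reads:
        out.write(f"@{name}\n{seq}\n+\n{qual}\n")
    if stream is None:
        return out.getvalue()
    return None


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _interval_overlap(a, b):
    """Shared bases between two (node, lo, hi) interval lists."""
    from collections import defaultdict

    bya = defaultdict(list)
    for n, lo, hi in a:
        bya[n].append((lo, hi))
    shared = 0
    for n, lo, hi in b:
        for lo2, hi2 in bya.get(n, ()):
            shared += max(0, min(hi, hi2) - max(lo, lo2))
    return shared


@dataclass
class EvalSummary:
    per_mapq: dict  # mapq -> [correct, incorrect]
    unmapped: int
    min_overlap: float

    def counts(self):
        c = sum(v[0] for v in self.per_mapq.values())
        i = sum(v[1] for v in self.per_mapq.values())
        return c, i, self.unmapped

    def correct_at(self, mapq_min: int):
        """(correct, total) among reads reported at mapq >= threshold."""
        c = sum(v[0] for q, v in self.per_mapq.items() if q >= mapq_min)
        t = sum(sum(v) for q, v in self.per_mapq.items() if q >= mapq_min)
        return c, t

    def roc_tsv(self) -> str:
        """Cumulative correct/incorrect counts by descending MAPQ cutoff."""
        lines = ["mapq\treads\tcum_correct\tcum_incorrect\tcum_error_rate"]
        cc = ci = 0
        for q in sorted(self.per_mapq, reverse=True):
            c, i = self.per_mapq[q]
            cc += c
            ci += i
            tot = cc + ci
            lines.append(f"{q}\t{c + i}\t{cc}\t{ci}\t{ci / tot if tot else 0:.6g}")
        lines.append(f"unmapped\t{self.unmapped}\t-\t-\t-")
        return "\n".join(lines) + "\n"


def evaluate_mappings(
    gaf, truth: list[TruthRecord], graph: VariationGraph, min_overlap: float = 0.5
) -> EvalSummary:
    """Score primary GAF records against truth.

    A read is correct when its reported graph interval shares at least
    ``min_overlap`` of the truth interval's bases. Reads in the truth set
    with no GAF record count as unmapped.
    """
    from .mapper import parse_gaf

    if isinstance(gaf, str):
        records = parse_gaf(io.StringIO(gaf))
    else:
        records = parse_gaf(gaf)
    by_name = {t.name: t for t in truth}
    per_mapq: dict[int, list[int]] = {}
    seen = set()
    for rec in records:
        if rec.secondary:
            continue
        t = by_name.get(rec.name)
        if t is None:
            raise EvaluationError(f"GAF read {rec.name!r} absent from truth set")
        seen.add(rec.name)
        ivs = rec.graph_intervals(graph)
        tlen = sum(hi - lo for _, lo, hi in t.graph_intervals)
        frac = _interval_overlap(ivs, t.graph_intervals) / tlen if tlen else 0.0
        slot = per_mapq.setdefault(rec.mapq, [0, 0])
        if frac >= min_overlap:
            slot[0] += 1
        else:
            slot[1] += 1
    unmapped = len(truth) - len(seen)
    return EvalSummary(per_mapq, unmapped, min_overlap)
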