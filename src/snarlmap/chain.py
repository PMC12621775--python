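"""Two-pass co-linear chaining of seed anchors.

Anchors are exact k-mer matches; a chain is an ordered subset whose read
starts strictly increase and whose consecutive anchors are reachable in
the graph. The score maximizes newly covered read bases and penalizes the
*gap* — the difference between read distance and graph distance of
consecutive anchors — with a Minimap2-style cost that is linear in the
gap plus a logarithmic term.

Chaining runs in two passes over the zip code tree order: a fragment pass
with tight gap limits links nearby anchors, then a chain pass links whole
fragments under looser limits. Both passes share the same scoring model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .distance import INF
from .zipcodes import ZipCodeTree, tree_distance_iter

__all__ = ["Anchor", "AnchorChain", "ChainingParams", "gap_cost", "chain_anchors"]


@dataclass
class ChainingParams:
    match_bonus: float = 1.0
    c_lin: float = 0.01
    c_log: float = 0.5
    frag_max_read_gap: int = 60
    frag_max_graph_gap: int = 60
    chain_max_read_gap: int = 10_000
    chain_max_graph_gap: int = 10_000
    max_chains: int = 4
    lookback: int = 64  # predecessors examined per anchor (bounds DP cost)

    def validate(self):
        vals = [
            self.match_bonus,
            self.c_lin,
            self.c_log,
            self.frag_max_read_gap,
            self.frag_max_graph_gap,
            self.chain_max_read_gap,
            self.chain_max_graph_gap,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("chaining parameters must be non-negative")


@dataclass(eq=False)
class Anchor:
    """A seed lifted to chaining: read interval [start, start+k) matching
    the graph exactly, starting at ``pos``."""

    read_start: int
    length: int
    pos: object  # Position
    seed: object  # Seed (carries the oriented node path)

    @property
    def read_end(self):
        return self.read_start + self.length


@dataclass(eq=False)
class AnchorChain:
    anchors: list[Anchor]
    score: float
    link_dists: list[float] = field(default_factory=list)  # start-to-start

    @property
    def read_start(self):
        return self.anchors[0].read_start

    @property
    def read_end(self):
        return self.anchors[-1].read_end

    def __repr__(self):
        return (
            f"AnchorChain({len(self.anchors)} anchors, read "
            f"[{self.read_start},{self.read_end}), score {self.score:.2f})"
        )


def gap_cost(read_gap, graph_gap, k, c_lin: float = 0.01, c_log: float = 0.5):
    """Cost of the difference between read and graph distances.

    ``g = |read_gap - graph_gap|``: zero gap costs nothing, otherwise
    ``c_lin * k * g + c_log * log2(g)``. An infinite graph gap forbids the
    link (infinite cost).
    """
    if graph_gap == INF or graph_gap is None:
        return INF
    g = abs(read_gap - graph_gap)
    if g == 0:
        return 0.0
    return c_lin * k * g + c_log * math.log2(g)


def link_terms(prev: Anchor, nxt: Anchor, graph_between, params: ChainingParams):
    """(new_coverage, cost) for linking two anchors, or None if invalid.

    ``graph_between`` is the exact count of bases strictly between the two
    anchor start positions (infinite if unreachable). This is the single
    scoring model shared by both passes.
    """
    read_dist = nxt.read_start - prev.read_start
    if read_dist <= 0:
        return None
    if graph_between == INF:
        return None
    k = prev.length
    # start-to-start graph distance; identical positions count as zero
    graph_dist = 0 if prev.pos == nxt.pos else graph_between + 1
    cost = gap_cost(read_dist, graph_dist, k, params.c_lin, params.c_log)
    new_cov = min(k, read_dist)
    return new_cov, cost


def _within(prev, nxt, graph_between, max_read_gap, max_graph_gap):
    k = prev.length
    read_dist = nxt.read_start - prev.read_start
    graph_dist = 0 if prev.pos == nxt.pos else graph_between + 1
    return read_dist - k <= max_read_gap and graph_dist - k <= max_graph_gap


def _fragment_pass(tree: ZipCodeTree, anchors, params: ChainingParams):
    """Optimal DP over tree order under the tight (fragment) limits;
    returns (score, prev) arrays."""
    n = len(anchors)
    score = [a.length * params.match_bonus for a in anchors]
    prev = [None] * n
    gap_bound = params.frag_max_graph_gap + max((a.length for a in anchors), default=0)
    klen = anchors[0].length
    for i in range(n):
        ai = anchors[i]
        window = (ai.read_start - params.frag_max_read_gap - klen, ai.read_start)
        for j, d in tree_distance_iter(tree, i, params.lookback, gap_bound, window):
            aj = anchors[j]
            if not _within(aj, ai, d, params.frag_max_read_gap, params.frag_max_graph_gap):
                continue
            terms = link_terms(aj, ai, d, params)
            if terms is None:
                continue
            new_cov, cost = terms
            cand = score[j] + new_cov * params.match_bonus - cost
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    return score, prev


def _extract_fragments(anchors, score, prev):
    """Disjoint best-first tracebacks of the fragment DP."""
    n = len(anchors)
    order = sorted(
        range(n), key=lambda i: (-score[i], anchors[i].read_start, i)
    )
    used = [False] * n
    fragments = []
    for end in order:
        if used[end]:
            continue
        idxs = []
        i = end
        while i is not None and not used[i]:
            idxs.append(i)
            used[i] = True
            i = prev[i]
        idxs.reverse()
        # recompute the fragment's own score (the traceback may have been
        # truncated at an anchor already used by a better fragment)
        fragments.append((idxs, score[end] if i is None else None))
    return fragments


@dataclass(eq=False)
class _Fragment:
    idxs: list[int]
    anchors: list[Anchor]
    score: float
    dists: list[float]


def _fragment_score(anchors, dists, params):
    s = anchors[0].length * params.match_bonus
    for i in range(1, len(anchors)):
        terms = link_terms(anchors[i - 1], anchors[i], dists[i - 1], params)
        new_cov, cost = terms
        s += new_cov * params.match_bonus - cost
    return s


def chain_anchors(tree: ZipCodeTree, params: ChainingParams) -> list[AnchorChain]:
    """Chain the occurrences of a zip code tree into scored anchor chains.

    Pass 1 builds fragments under the tight gap limits; pass 2 links
    fragments under the loose limits. Returns up to ``max_chains``
    non-duplicative chains, best first, with deterministic tie-breaks.
    """
    params.validate()
    anchors = [
        Anchor(seed.read_offset, seed.length, seed.pos, seed)
        for seed, _copy in tree.occs
    ]
    if not anchors:
        return []
    score, prev = _fragment_pass(tree, anchors, params)

    frags: list[_Fragment] = []
    for idxs, _ in _extract_fragments(anchors, score, prev):
        fa = [anchors[i] for i in idxs]
        dists = [
            tree.index.min_distance(fa[t].pos, fa[t + 1].pos)
            if fa[t].pos != fa[t + 1].pos
            else _same_pos_dist(tree, idxs[t], idxs[t + 1])
            for t in range(len(fa) - 1)
        ]
        frags.append(_Fragment(idxs, fa, _fragment_score(fa, dists, params), dists))
    # deterministic fragment order along the tree
    frags.sort(key=lambda f: (f.idxs[0],))

    # pass 2: DP over fragments under the loose limits
    m = len(frags)
    fscore = [f.score for f in frags]
    fprev = [None] * m
    for i in range(m):
        fi = frags[i]
        for j in range(i - 1, -1, -1):
            fj = frags[j]
            pa, na = fj.anchors[-1], fi.anchors[0]
            if na.read_start <= pa.read_start:
                continue
            if na.read_start - pa.read_end > params.chain_max_read_gap:
                continue
            d = (
                0
                if pa.pos == na.pos
                else tree.index.min_distance(pa.pos, na.pos)
            )
            if not _within(pa, na, d, params.chain_max_read_gap, params.chain_max_graph_gap):
                continue
            terms = link_terms(pa, na, d, params)
            if terms is None:
                continue
            new_cov, cost = terms
            # linking replaces the first anchor's full-coverage credit
            adj = fi.score - fi.anchors[0].length * params.match_bonus
            cand = fscore[j] + adj + new_cov * params.match_bonus - cost
            if cand > fscore[i]:
                fscore[i] = cand
                fprev[i] = j

    order = sorted(range(m), key=lambda i: (-fscore[i], frags[i].idxs[0]))
    used = [False] * m
    chains: list[AnchorChain] = []
    for end in order:
        if len(chains) >= params.max_chains:
            break
        if used[end]:
            continue
        path = []
        i = end
        ok = True
        while i is not None:
            if used[i]:
                ok = False
                break
            path.append(i)
            i = fprev[i]
        if not ok:
            continue
        path.reverse()
        for i in path:
            used[i] = True
        all_anchors: list[Anchor] = []
        all_dists: list[float] = []
        for t, i in enumerate(path):
            f = frags[i]
            if t > 0:
                pa, na = all_anchors[-1], f.anchors[0]
                d = (
                    0
                    if pa.pos == na.pos
                    else tree.index.min_distance(pa.pos, na.pos)
                )
                all_dists.append(d)
            all_anchors.extend(f.anchors)
            all_dists.extend(f.dists)
        chains.append(AnchorChain(all_anchors, fscore[end], all_dists))
    return chains


def _same_pos_dist(tree, i, j):
    occ_i, occ_j = tree.occs[i], tree.occs[j]
    if occ_i[1] != occ_j[1]:
        return tree.index.loop_distance(occ_i[0].pos)
    return 0
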