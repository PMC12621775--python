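"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force and kept separate from the
library code paths it validates.
"""

from heapq import heappop, heappush

import numpy as np

from snarlmap.graph import (
    FORWARD,
    LEFT,
    REVERSE,
    RIGHT,
    NodeSide,
    Position,
    oriented_sequence,
)

INF = float("inf")


# -- distances --------------------------------------------------------------


def oracle_reach(graph, src_node, src_orient):
    """dd[(w, o)] = minimum total length of intermediate nodes on any walk
    from the exit of (src_node, src_orient) to the entry of (w, o)."""
    adj = graph.adjacency()
    exit_side = NodeSide(src_node, RIGHT if src_orient == FORWARD else LEFT)
    dd = {}
    heap = []
    ctr = 0
    for t in adj[exit_side]:
        st = (t.node_id, FORWARD if t.side == LEFT else REVERSE)
        heappush(heap, (0, ctr, st))
        ctr += 1
    while heap:
        c, _, st = heappop(heap)
        if st in dd:
            continue
        dd[st] = c
        w, o = st
        ln = graph.node_len(w)
        ex = NodeSide(w, RIGHT if o == FORWARD else LEFT)
        for t in adj[ex]:
            nst = (t.node_id, FORWARD if t.side == LEFT else REVERSE)
            if nst not in dd:
                heappush(heap, (c + ln, ctr, nst))
                ctr += 1
    return dd


def oracle_min_distance(graph, a: Position, b: Position, same_pos_zero=True):
    """Bases strictly between two positions by Dijkstra over oriented
    nodes."""
    if (
        a.node_id == b.node_id
        and a.orientation == b.orientation
        and a.offset == b.offset
        and same_pos_zero
    ):
        return 0
    best = INF
    if (
        a.node_id == b.node_id
        and a.orientation == b.orientation
        and b.offset > a.offset
    ):
        best = b.offset - a.offset - 1
    dd = oracle_reach(graph, a.node_id, a.orientation)
    la = graph.node_len(a.node_id)
    key = (b.node_id, b.orientation)
    if key in dd:
        best = min(best, (la - 1 - a.offset) + dd[key] + b.offset)
    return best


def all_positions(graph):
    out = []
    for nid in sorted(graph.sequences):
        for o in (FORWARD, REVERSE):
            for off in range(graph.node_len(nid)):
                out.append(Position(nid, o, off))
    return out


# -- snarls -----------------------------------------------------------------


def definitional_snarl_check(graph, snarl):
    """True iff a snarl's boundaries are separable and minimal and its
    content matches the cut component, straight from the definitions."""
    from snarlmap.snarls import is_minimal, is_separable, separable_content

    if not is_separable(graph, snarl.start, snarl.end):
        return False
    if separable_content(graph, snarl.start, snarl.end) != snarl.content:
        return False
    return is_minimal(graph, snarl.start, snarl.end)


def bruteforce_separable_minimal_pairs(graph):
    """All separable+minimal side pairs by exhaustive definitional scan."""
    from snarlmap.snarls import is_minimal, is_separable

    pairs = set()
    nodes = sorted(graph.sequences)
    sides = [NodeSide(n, s) for n in nodes for s in (LEFT, RIGHT)]
    sep = set()
    for i, a in enumerate(sides):
        for b in sides[i + 1 :]:
            if a.node_id == b.node_id:
                continue
            if is_separable(graph, a, b):
                sep.add((a, b))
    for a, b in sep:
        if is_minimal(graph, a, b):
            pairs.add((a, b))
    return pairs


# -- alignment --------------------------------------------------------------


def nw_affine(q: str, t: str, sc) -> int:
    """Full-matrix global affine-gap alignment score (row-vectorized)."""
    n, m = len(q), len(t)
    A, X, O, E = sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    NEGV = -(10**9)
    if n == 0 and m == 0:
        return 0
    if n == 0:
        return -(O + E * m)
    if m == 0:
        return -(O + E * n)
    ta = np.frombuffer(t.encode(), np.uint8)
    H = np.full(m + 1, NEGV, dtype=np.int64)
    I = np.full(m + 1, NEGV, dtype=np.int64)
    H[0] = 0
    H[1:] = -(O + E * np.arange(1, m + 1))
    for i in range(1, n + 1):
        Hp = H
        I = np.maximum(Hp - O, I) - E
        qc = ord(q[i - 1])
        sub = np.where((ta == qc) & (ta != ord("N")), A, -X)
        diag = Hp[:-1] + sub
        H = np.full(m + 1, NEGV, dtype=np.int64)
        H[0] = -(O + E * i)
        I[0] = -(O + E * i)
        H[1:] = np.maximum(diag, I[1:])
        pref = np.maximum.accumulate(H[:-1] - O + E * np.arange(m))
        H[1:] = np.maximum(H[1:], pref - E * np.arange(1, m + 1))
    return int(H[m])


def enumerate_walk_strings(graph, from_pos, to_pos, max_len=200, max_walks=256):
    """All walk strings strictly between two positions (graph truth, not
    restricted to stored haplotypes), capped for tractability."""
    from snarlmap.align import _successor_positions
    from snarlmap.graph import OrientedNode

    out = []
    stack = [(from_pos, "")]
    while stack and len(out) < max_walks:
        pos, acc = stack.pop()
        if len(acc) > max_len:
            continue
        for nxt in _successor_positions(graph, pos):
            if nxt.offset >= graph.node_len(nxt.node_id):
                continue
            if nxt == to_pos:
                out.append(acc)
            base = oriented_sequence(
                graph, OrientedNode(nxt.node_id, nxt.orientation)
            )[nxt.offset]
            stack.append((nxt, acc + base))
    return sorted(set(out))


# -- chaining ---------------------------------------------------------------


def bruteforce_best_chain(anchors, dist_fn, params):
    """Maximum chain score over all ordered anchor subsets.

    Anchors must have distinct read starts (the order of a subset is then
    forced). ``dist_fn(a, b)`` gives bases strictly between anchor start
    positions.
    """
    from snarlmap.chain import link_terms, _within

    order = sorted(anchors, key=lambda a: a.read_start)
    n = len(order)
    best = 0.0
    for mask in range(1, 1 << n):
        sel = [order[i] for i in range(n) if mask >> i & 1]
        score = sel[0].length * params.match_bonus
        ok = True
        for p, a in zip(sel, sel[1:]):
            d = dist_fn(p, a)
            if not _within(p, a, d, params.frag_max_read_gap, params.frag_max_graph_gap):
                ok = False
                break
            terms = link_terms(p, a, d, params)
            if terms is None:
                ok = False
                break
            cov, cost = terms
            score += cov * params.match_bonus - cost
        if ok:
            best = max(best, score)
    return best
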