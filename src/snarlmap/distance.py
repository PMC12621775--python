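"""Exact minimum-distance index over the snarl tree.

``min_distance(a, b)`` is the minimum number of bases strictly between two
graph positions over all walks that read ``a`` (in its orientation) and
later read ``b``: 0 when ``b`` is the next base, infinity when
unreachable, and 0 for the identical position.

The index summarizes every snarl and chain bottom-up:

* a snarl stores a small local graph over its boundary sides and the outer
  ends of its child chains, with child chains entering as 2x2 transit
  matrices (through-distance plus same-end return distances, which are
  finite only when the child contains an inversion or loop);
* a chain stores prefix sums of item lengths and snarl through-distances,
  plus the positions where direction can reverse (snarls with finite
  same-side return, cyclic closures), so straight runs cost O(1) and only
  reversal points need search.

Queries lift both positions toward the root, proposing a candidate at
every common ancestor; paths that leave a structure and come back are
accounted for at the parent level, so the result is exact, including
through cycles and inversions.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from heapq import heappop, heappush

from .errors import BoundsError, ConsistencyError
from .graph import FORWARD, LEFT, RIGHT, NodeSide, Position, VariationGraph
from .snarls import Snarl, SnarlChain, SnarlTree, edge_assignment

INF = math.inf


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class SnarlRecord:
    snarl: Snarl
    ports: dict  # NodeSide -> 'A' | 'B' | (child_idx, 'L'/'R')
    out_edges: dict  # ('o', port) -> list of (('i', port), cost)
    thr: float = INF  # out(A) -> in(B)
    ret_a: float = INF  # out(A) -> in(A)
    ret_b: float = INF  # out(B) -> in(B)
    parent_chain: "ChainRecord | None" = None
    pos_t: int = 0  # snarl index within parent chain

    def dijkstra(self, sources):
        """Multi-source Dijkstra over the local state graph.

        ``sources``: dict of ('o', port) -> initial cost. Returns dict of
        ('i', port) -> cost. Single-source results are cached, so the
        multi-source answer is an elementwise minimum over cached runs.
        """
        if self._cache is None:
            self._cache = {}
        out: dict = {}
        for st, c in sources.items():
            if c >= INF:
                continue
            single = self._cache.get(st)
            if single is None:
                single = self._dijkstra_single(st)
                self._cache[st] = single
            for tgt, w in single.items():
                t = c + w
                if tgt not in out or out[tgt] > t:
                    out[tgt] = t
        return out

    def _dijkstra_single(self, source):
        heap = []
        sources = {source: 0}
        ctr = 0
        for st, c in sources.items():
            if c < INF:
                heappush(heap, (c, ctr, st))
                ctr += 1
        best: dict = {}
        while heap:
            c, _, st = heappop(heap)
            if st in best and best[st] <= c:
                continue
            best[st] = c
            if st[0] == "o":
                for nxt, w in self.out_edges.get(st, ()):
                    if nxt not in best or best[nxt] > c + w:
                        heappush(heap, (c + w, ctr, nxt))
                        ctr += 1
            else:
                # in-port of a child chain: cross via its transit matrix
                port = st[1]
                if isinstance(port, tuple):
                    for nxt, w in self.transit_edges(port):
                        if w < INF and (nxt not in best or best[nxt] > c + w):
                            heappush(heap, (c + w, ctr, nxt))
                            ctr += 1
        return {st: c for st, c in best.items() if st[0] == "i"}

    def transit_edges(self, port):
        ci, end = port
        crec = self.child_recs[ci]
        if end == "L":
            return (
                (("o", (ci, "R")), crec.t_lr),
                (("o", (ci, "L")), crec.t_ll),
            )
        return (
            (("o", (ci, "L")), crec.t_lr),
            (("o", (ci, "R")), crec.t_rr),
        )

    child_recs: list = None  # set at build time
    _cache: dict = None  # per-source Dijkstra results


@dataclass(eq=False)
class ChainRecord:
    chain: SnarlChain
    lens: list[int]
    orients: list[int]  # orientation of each node item in chain direction
    thr: list[float]
    ret_l: list[float]  # bounce off snarl t back into item t
    ret_r: list[float]  # bounce off snarl t back into item t+1 (mod m)
    cyclic: bool
    end_bounce_l: float = INF
    end_bounce_r: float = INF
    parent_snarl: SnarlRecord | None = None
    child_index: int = 0  # index among the parent snarl's children
    root_id: int = -1  # connected-component identity for top-level chains
    # transit matrix (valid for non-cyclic chains)
    t_lr: float = INF
    t_ll: float = INF
    t_rr: float = INF
    # prefix sums
    TH: list[float] = field(default_factory=list)
    LL: list[int] = field(default_factory=list)
    inf_thr: list[int] = field(default_factory=list)
    bouncy: list[int] = field(default_factory=list)  # item indices
    plain: bool = True
    # all-pairs shortest paths among direction-change states (lazy)
    _snodes: list = None
    _SP: list = None

    @property
    def m(self):
        return len(self.lens)

    def finalize(self):
        m = self.m
        th = 0.0
        self.TH = [0.0]
        self.inf_thr = []
        for t in range(m - 1):
            if self.thr[t] == INF:
                self.inf_thr.append(t)
            else:
                th += self.thr[t]
            self.TH.append(th)
        ll = 0
        self.LL = [0]
        for k in range(m):
            ll += self.lens[k]
            self.LL.append(ll)
        b = set()
        rng = m if self.cyclic else m - 1
        for t in range(rng):
            if self.ret_l[t] < INF:
                b.add(t)
            if self.ret_r[t] < INF:
                b.add((t + 1) % m)
        if self.cyclic:
            b.add(0)
            b.add(m - 1)
        if self.end_bounce_l < INF:
            b.add(0)
        if self.end_bounce_r < INF:
            b.add(m - 1)
        self.bouncy = sorted(b)
        self.plain = not b and not self.cyclic

    # -- straight-run arithmetic ------------------------------------------

    def straight(self, i, j):
        """Bases strictly between exiting item i rightward and entering
        item j rightward (i < j, no direction change, no wrap)."""
        if i >= j:
            return INF
        lo = bisect_left(self.inf_thr, i)
        if lo < len(self.inf_thr) and self.inf_thr[lo] < j:
            return INF
        return (self.TH[j] - self.TH[i]) + (self.LL[j] - self.LL[i + 1])

    def _core_plain(self, i, di, j, dj):
        """out(i,di) -> in(j,dj) with no reversal available."""
        if di != dj:
            return INF
        if di == 1:
            return self.straight(i, j) if i < j else INF
        return self.straight(j, i) if j < i else INF

    # -- general routing ---------------------------------------------------

    def route(self, sources, targets):
        """Minimum costs from source states to target states.

        States: ('in', i, d) / ('out', i, d) with d in {+1, -1}, plus the
        pseudo-states 'ENL'/'ENR' (entering the chain) and 'EXL'/'EXR'
        (having exited it). Returns dict target -> cost.
        """
        m = self.m
        src = {}
        for st, c in sources.items():
            if c >= INF:
                continue
            st = self._normalize(st)
            if st is not None and (st not in src or src[st] > c):
                src[st] = c
        tgts = [(t, self._normalize_target(t)) for t in targets]
        if self.plain:
            out = {}
            for torig, t in tgts:
                best = INF
                if t is not None:
                    for st, c in src.items():
                        best = min(best, c + self._pair_plain(st, t))
                out[torig] = best
            return out
        return self._route_via_specials(src, tgts)

    def _special_graph(self):
        """Direction-change states and their all-pairs shortest paths.

        Any walk within the chain is a sequence of straight runs joined at
        bounce/wrap edges, so routing reduces to: straight to a special
        state, shortest path among specials, straight to the target.
        """
        if self._snodes is not None:
            return self._snodes, self._SP
        m = self.m
        edges = []
        rng = m if self.cyclic else m - 1
        for t in range(rng):
            if self.ret_l[t] < INF:
                edges.append((("out", t, 1), ("in", t, -1), self.ret_l[t]))
            nxt = (t + 1) % m
            if self.ret_r[t] < INF:
                edges.append((("out", nxt, -1), ("in", nxt, 1), self.ret_r[t]))
        if self.cyclic:
            w = self.thr[m - 1]
            if w < INF:
                edges.append((("out", m - 1, 1), ("in", 0, 1), w))
                edges.append((("out", 0, -1), ("in", m - 1, -1), w))
        if self.end_bounce_l < INF:
            edges.append((("out", 0, -1), ("in", 0, 1), self.end_bounce_l))
        if self.end_bounce_r < INF:
            edges.append((("out", m - 1, 1), ("in", m - 1, -1), self.end_bounce_r))
        nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
        k = len(nodes)
        idx = {s: i for i, s in enumerate(nodes)}
        SP = [[INF] * k for _ in range(k)]
        for i in range(k):
            SP[i][i] = 0.0
        for i, s1 in enumerate(nodes):
            for j, s2 in enumerate(nodes):
                if i != j:
                    c = self._pair_plain(s1, s2)
                    if c < SP[i][j]:
                        SP[i][j] = c
        for a, b, c in edges:
            i, j = idx[a], idx[b]
            if c < SP[i][j]:
                SP[i][j] = c
        for h in range(k):
            row_h = SP[h]
            for i in range(k):
                d = SP[i][h]
                if d == INF:
                    continue
                row_i = SP[i]
                for j in range(k):
                    v = d + row_h[j]
                    if v < row_i[j]:
                        row_i[j] = v
        self._snodes, self._SP = nodes, SP
        return nodes, SP

    def _route_via_specials(self, src, tgts):
        direct_src = list(src.items())
        out = {}
        need_specials = []
        for torig, t in tgts:
            best = INF
            if t is not None:
                for st, c in direct_src:
                    v = c + self._pair_plain(st, t)
                    if v < best:
                        best = v
            # a finite straight route is already optimal (bounces only add
            # distance); the special graph matters only when it is not
            if best < INF:
                out[torig] = best
            else:
                need_specials.append((torig, t))
        if not need_specials:
            return out
        nodes, SP = self._special_graph()
        k = len(nodes)
        u = [INF] * k
        for i, s1 in enumerate(nodes):
            for st, c in direct_src:
                v = c + self._pair_plain(st, s1)
                if v < u[i]:
                    u[i] = v
        via = [INF] * k  # best cost from any source to special j
        for j in range(k):
            best = u[j]
            for i in range(k):
                if u[i] < INF and SP[i][j] < INF:
                    v = u[i] + SP[i][j]
                    if v < best:
                        best = v
            via[j] = best
        for torig, t in need_specials:
            best = INF
            if t is not None:
                for j, s2 in enumerate(nodes):
                    if via[j] < INF:
                        v = via[j] + self._pair_plain(s2, t)
                        if v < best:
                            best = v
            out[torig] = best
        return out

    def _normalize(self, st):
        if st == "ENL":
            return ("in", 0, 1)
        if st == "ENR":
            return ("in", self.m - 1, -1)
        return st

    def _normalize_target(self, st):
        if st == "EXL":
            return ("out", 0, -1)
        if st == "EXR":
            return ("out", self.m - 1, 1)
        return st

    def _pair_plain(self, s, t):
        # s, t are ('in'|'out', i, d)
        if s == t:
            return 0
        k1, i, di = s
        k2, j, dj = t
        if k1 == "in" and k2 == "out" and i == j and di == dj:
            return self.lens[i]
        c = self.lens[i] if k1 == "in" else 0
        core = self._core_plain(i, di, j, dj)
        if core == INF:
            return INF
        c += core
        if k2 == "out":
            c += self.lens[j]
        return c

    def transit(self):
        """(t_lr, t_ll, t_rr) for a non-cyclic chain used as a snarl child."""
        if self.cyclic:
            return INF, INF, INF
        r = self.route({"ENL": 0}, ["EXR", "EXL"])
        r2 = self.route({"ENR": 0}, ["EXR"])
        return r["EXR"], r["EXL"], r2["EXR"]


@dataclass(eq=False)
class DistanceIndex:
    graph: VariationGraph
    tree: SnarlTree
    node_rec: dict  # node_id -> (ChainRecord, item_index)
    chain_recs: dict  # id(SnarlChain) -> ChainRecord
    snarl_recs: dict  # id(Snarl) -> SnarlRecord
    skipped_edges: list = field(default_factory=list)

    def min_distance(self, a: Position, b: Position, _same_pos_zero: bool = True):
        return _min_distance(self, a, b, _same_pos_zero)

    def loop_distance(self, a: Position):
        """Bases strictly between reading a and reading a *again* (finite
        only inside cycles)."""
        return _min_distance(self, a, a, False)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def build_distance_index(graph: VariationGraph, tree: SnarlTree) -> DistanceIndex:
    if tree.graph is not graph:
        raise ConsistencyError("snarl tree was built from a different graph")
    assignment = edge_assignment(tree)
    by_snarl: dict[int, list] = {}
    unassigned = []
    for edge, owner in assignment.items():
        if owner is None:
            unassigned.append(edge)
        else:
            by_snarl.setdefault(id(owner), []).append(edge)

    index = DistanceIndex(graph, tree, {}, {}, {}, [])

    def build_chain(chain: SnarlChain, root_id: int) -> ChainRecord:
        srecs = []
        for t, snarl in enumerate(chain.snarls):
            srecs.append(build_snarl(snarl, root_id))
        m = len(chain.nodes)
        rec = ChainRecord(
            chain=chain,
            lens=[graph.node_len(n.node_id) for n in chain.nodes],
            orients=[n.orientation for n in chain.nodes],
            thr=[s.thr for s in srecs],
            ret_l=[s.ret_a for s in srecs],
            ret_r=[s.ret_b for s in srecs],
            cyclic=chain.cyclic,
            root_id=root_id,
        )
        # pathological root-level decorations: self-loops on the outer end
        # sides, or a single-node circular component
        if chain.parent is None:
            outer_l = chain.nodes[0].entry_side
            outer_r = chain.nodes[-1].exit_side
            for a, b in unassigned:
                if a == b == outer_l:
                    rec.end_bounce_l = 0
                elif a == b == outer_r:
                    rec.end_bounce_r = 0
                elif m == 1 and {a, b} == {outer_l, outer_r}:
                    rec.cyclic = True
                    rec.thr = [0]
                    rec.ret_l = [INF]
                    rec.ret_r = [INF]
        rec.finalize()
        for t, srec in enumerate(srecs):
            srec.parent_chain = rec
            srec.pos_t = t
        index.chain_recs[id(chain)] = rec
        for i, n in enumerate(chain.nodes):
            index.node_rec[n.node_id] = (rec, i)
        return rec

    def build_snarl(snarl: Snarl, root_id: int) -> SnarlRecord:
        child_recs = []
        ports: dict[NodeSide, object] = {snarl.start: "A", snarl.end: "B"}
        for ci, child in enumerate(snarl.children):
            crec = build_chain(child, root_id)
            crec.parent_snarl = None  # set below
            crec.child_index = ci
            t = crec.transit()
            crec.t_lr, crec.t_ll, crec.t_rr = t
            child_recs.append(crec)
            if not child.cyclic:
                ports[child.nodes[0].entry_side] = (ci, "L")
                ports[child.nodes[-1].exit_side] = (ci, "R")
        rec = SnarlRecord(snarl=snarl, ports=ports, out_edges={})
        rec.child_recs = child_recs
        for crec in child_recs:
            crec.parent_snarl = rec
        for a, b in by_snarl.get(id(snarl), ()):  # local 0-cost hops
            pa, pb = ports.get(a), ports.get(b)
            if pa is None or pb is None:
                index.skipped_edges.append((a, b))
                continue
            rec.out_edges.setdefault(("o", pa), []).append((("i", pb), 0))
            if (a, pa) != (b, pb):
                rec.out_edges.setdefault(("o", pb), []).append((("i", pa), 0))
        # summary distances
        d = rec.dijkstra({("o", "A"): 0})
        rec.thr = d.get(("i", "B"), INF)
        rec.ret_a = d.get(("i", "A"), INF)
        d = rec.dijkstra({("o", "B"): 0})
        rec.ret_b = d.get(("i", "B"), INF)
        index.snarl_recs[id(snarl)] = rec
        return rec

    for root_id, root in enumerate(tree.roots):
        build_chain(root, root_id)

    missing = set(graph.sequences) - set(index.node_rec)
    if missing:
        raise ConsistencyError(f"nodes missing from the snarl tree: {sorted(missing)}")
    return index


# ---------------------------------------------------------------------------
# Query
# ---------------------------------------------------------------------------


def _check_pos(graph: VariationGraph, p: Position):
    if p.node_id not in graph.sequences:
        raise BoundsError(f"unknown node {p.node_id}")
    if not 0 <= p.offset < graph.node_len(p.node_id):
        raise BoundsError(f"offset {p.offset} out of range on node {p.node_id}")


def _ancestor_chain_ids(index: DistanceIndex, rec: ChainRecord):
    out = []
    r = rec
    while r is not None:
        out.append(r)
        r = r.parent_snarl.parent_chain if r.parent_snarl is not None else None
    return out


def _min_distance(index: DistanceIndex, a: Position, b: Position, same_pos_zero=True):
    graph = index.graph
    _check_pos(graph, a)
    _check_pos(graph, b)
    best = INF

    if a.node_id == b.node_id and a.orientation == b.orientation:
        if b.offset == a.offset:
            if same_pos_zero:
                return 0
        elif b.offset > a.offset:
            best = b.offset - a.offset - 1

    rec_a, i_a = index.node_rec[a.node_id]
    rec_b, j_b = index.node_rec[b.node_id]
    if rec_a.root_id != rec_b.root_id:
        return best

    anc_a = _ancestor_chain_ids(index, rec_a)
    anc_b = _ancestor_chain_ids(index, rec_b)
    ids_b = {id(r): k for k, r in enumerate(anc_b)}
    ka = 0
    while id(anc_a[ka]) not in ids_b:
        ka += 1
    D = anc_a[ka]
    kb = ids_b[id(D)]

    # initial y targets on its own chain; lift y up to D first, remembering
    # the last snarl it crossed so that paths meeting x inside a shared
    # snarl are not lost
    d_b = 1 if b.orientation == rec_b.orients[j_b] else -1
    y_states = {("in", j_b, d_b): b.offset}
    y_last = None  # (snarl record, child index, cl, cr)

    recy = rec_b
    while recy is not D:
        en_l = recy.route({"ENL": 0}, list(y_states))
        en_r = recy.route({"ENR": 0}, list(y_states))
        cl = min((en_l[t] + c for t, c in y_states.items()), default=INF)
        cr = min((en_r[t] + c for t, c in y_states.items()), default=INF)
        s = recy.parent_snarl
        ci = recy.child_index
        y_last = (s, ci, cl, cr)
        # cost from each snarl boundary to y
        da = s.dijkstra({("o", "A"): 0})
        db = s.dijkstra({("o", "B"): 0})

        def through(dd):
            v = INF
            x = dd.get(("i", (ci, "L")), INF)
            if x < INF and cl < INF:
                v = min(v, x + cl)
            x = dd.get(("i", (ci, "R")), INF)
            if x < INF and cr < INF:
                v = min(v, x + cr)
            return v

        ya, yb = through(da), through(db)
        pc = s.parent_chain
        t = s.pos_t
        y_states = {}
        if ya < INF:
            y_states[("out", t, 1)] = ya
        if yb < INF:
            y_states[("out", (t + 1) % pc.m, -1)] = yb
        recy = pc

    # initial x frontier: states on its own chain
    la = graph.node_len(a.node_id)
    d_a = 1 if a.orientation == rec_a.orients[i_a] else -1
    x_states = {("out", i_a, d_a): la - 1 - a.offset}

    # lift x until its frontier lives on chain D
    rec = rec_a
    while rec is not D:
        ex = rec.route(x_states, ["EXL", "EXR"])
        s = rec.parent_snarl
        ci = rec.child_index
        din = s.dijkstra(
            {("o", (ci, "L")): ex["EXL"], ("o", (ci, "R")): ex["EXR"]}
        )
        if y_last is not None and y_last[0] is s:
            # x and y meet inside this snarl without leaving it
            _, cj, cl, cr = y_last
            w = din.get(("i", (cj, "L")), INF)
            if w < INF and cl < INF:
                best = min(best, w + cl)
            w = din.get(("i", (cj, "R")), INF)
            if w < INF and cr < INF:
                best = min(best, w + cr)
        # exit the snarl into its parent chain
        pa = din.get(("i", "A"), INF)
        pb = din.get(("i", "B"), INF)
        pc = s.parent_chain
        t = s.pos_t
        x_states = {}
        if pa < INF:
            x_states[("in", t, -1)] = pa
        if pb < INF:
            x_states[("in", (t + 1) % pc.m, 1)] = pb
        rec = pc

    # walk up from the deepest common chain to the root, proposing a
    # candidate at every level
    rec = D
    while True:
        if x_states and y_states:
            r = rec.route(x_states, list(y_states))
            for t, c in y_states.items():
                if r[t] < INF and c < INF:
                    best = min(best, r[t] + c)
        s = rec.parent_snarl
        if s is None:
            break
        ex = rec.route(x_states, ["EXL", "EXR"])
        en_l = rec.route({"ENL": 0}, list(y_states))
        en_r = rec.route({"ENR": 0}, list(y_states))
        cl = min((en_l[t] + c for t, c in y_states.items()), default=INF)
        cr = min((en_r[t] + c for t, c in y_states.items()), default=INF)
        ci = rec.child_index
        # candidate: leave this chain, wander in the parent snarl, re-enter
        din = s.dijkstra({("o", (ci, "L")): ex["EXL"], ("o", (ci, "R")): ex["EXR"]})
        x_in_l = din.get(("i", (ci, "L")), INF)
        x_in_r = din.get(("i", (ci, "R")), INF)
        if x_in_l < INF and cl < INF:
            best = min(best, x_in_l + cl)
        if x_in_r < INF and cr < INF:
            best = min(best, x_in_r + cr)
        # lift x through the snarl
        pa = din.get(("i", "A"), INF)
        pb = din.get(("i", "B"), INF)
        pc = s.parent_chain
        t = s.pos_t
        x_states = {}
        if pa < INF:
            x_states[("in", t, -1)] = pa
        if pb < INF:
            x_states[("in", (t + 1) % pc.m, 1)] = pb
        # lift y through the snarl
        da = s.dijkstra({("o", "A"): 0})
        db = s.dijkstra({("o", "B"): 0})

        def through2(dd):
            v = INF
            x = dd.get(("i", (ci, "L")), INF)
            if x < INF and cl < INF:
                v = min(v, x + cl)
            x = dd.get(("i", (ci, "R")), INF)
            if x < INF and cr < INF:
                v = min(v, x + cr)
            return v

        ya, yb = through2(da), through2(db)
        y_states = {}
        if ya < INF:
            y_states[("out", t, 1)] = ya
        if yb < INF:
            y_states[("out", (t + 1) % pc.m, -1)] = yb
        rec = pc

    if best < INF:
        return int(best)
    return INF


def min_distance(index: DistanceIndex, a: Position, b: Position):
    """Minimum bases strictly between two positions (module-level API)."""
    return index.min_distance(a, b)
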