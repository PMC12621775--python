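"""Base-level extension: turn an anchor chain into a full alignment.

Per-link alignment runs a gap-affine wavefront algorithm (WFA) against
the haplotype strings spelled between consecutive anchors; when no
haplotype walk exists, when WFA fails its score budget, or when the
problem exceeds the configured length ceiling, a banded global aligner
over the graph takes over. Read tails are aligned with an X-drop
extension aligner over the graph, soft-clipping whatever cannot be
extended. Anchors themselves are exact matches by construction.

Scores are integer gap-affine: ``match`` reward, ``mismatch`` penalty and
``gap_open + gap_extend * length`` per gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import INF
from .graph import (
    FORWARD,
    LEFT,
    RIGHT,
    NodeSide,
    OrientedNode,
    Position,
    VariationGraph,
    oriented_sequence,
)

NEG = -(10**9)


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def validate(self):
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("match must be positive and penalties non-negative")

    def score_ops(self, ops) -> int:
        s = 0
        for op, ln in ops:
            if op == "=":
                s += self.match * ln
            elif op == "X":
                s -= self.mismatch * ln
            elif op in "ID":
                s -= self.gap_open + self.gap_extend * ln
        return s


def merge_ops(ops):
    """Coalesce adjacent runs of the same op and drop empties."""
    out = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


@dataclass
class AlignmentPath:
    """A read-to-walk alignment.

    ``spans`` lists the consumed stretches of the walk as
    (OrientedNode, lo, hi) half-open oriented-offset intervals (a node
    revisited through a loop appears as separate spans); ``ops`` is the
    CIGAR-style operation list over (read, walk); soft-clipped read
    prefixes/suffixes are recorded separately from the ops."""

    spans: list[tuple[OrientedNode, int, int]]
    ops: list[tuple[str, int]]
    score: int
    left_clip: int = 0
    right_clip: int = 0

    @property
    def steps(self) -> list[OrientedNode]:
        return [s[0] for s in self.spans]

    @property
    def start_offset(self) -> int:
        return self.spans[0][1] if self.spans else 0

    @property
    def read_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in "=XI")

    @property
    def walk_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in "=XD")

    def matches(self) -> int:
        return sum(ln for op, ln in self.ops if op == "=")


# ---------------------------------------------------------------------------
# Wavefront alignment (gap-affine, exact)
# ---------------------------------------------------------------------------


def _match_runs(q: str, t: str):
    """R[i, j] = length of the common prefix of q[i:] and t[j:]."""
    n, m = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    # N never matches anything, including itself
    is_n = ord("N")
    R = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        eq = (ta == qa[i]) & (ta != is_n) & (qa[i] != is_n)
        R[i, :m] = np.where(eq, R[i + 1, 1:] + 1, 0)
    return R


class _Wave:
    __slots__ = ("lo", "hi", "arr")

    def __init__(self, lo, hi, arr):
        self.lo, self.hi, self.arr = lo, hi, arr

    def get(self, d):
        if self.lo <= d <= self.hi:
            return int(self.arr[d - self.lo])
        return NEG

    def vec(self, lo, hi):
        """Offsets over [lo, hi] padded with NEG."""
        out = np.full(hi - lo + 1, NEG, dtype=np.int64)
        a = max(lo, self.lo)
        b = min(hi, self.hi)
        if a <= b:
            out[a - lo : b - lo + 1] = self.arr[a - self.lo : b - self.lo + 1]
        return out


_EMPTY = _Wave(0, -1, np.empty(0, dtype=np.int64))


def wfa_align(query: str, target: str, scoring: Scoring = Scoring(), max_score_gap=INF):
    """Optimal gap-affine global alignment via wavefronts.

    Returns (score, ops) identical in score to full dynamic programming,
    or None when the score falls more than ``max_score_gap`` below the
    all-match baseline (the failure value that triggers graph fallback).
    """
    scoring.validate()
    n, m = len(query), len(target)
    A, X, O, E = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    if n == 0 and m == 0:
        return 0, []
    if n == 0:
        return -(O + E * m), [("D", m)]
    if m == 0:
        return -(O + E * n), [("I", n)]
    # doubled-cost transform: minimizing this cost maximizes the score
    x2, o2, e2 = 2 * (A + X), 2 * O, A + 2 * E
    budget = 2 * max_score_gap

    R = _match_runs(query, target)

    def extend(wave):
        if wave.hi < wave.lo:
            return wave
        ds = np.arange(wave.lo, wave.hi + 1)
        i = wave.arr
        ok = i > NEG // 2
        ii = np.clip(i, 0, n)
        jj = np.clip(ii - ds, 0, m)
        run = R[ii, jj]
        wave.arr = np.where(ok, i + run, i)
        return wave

    hist = {}
    M0 = _Wave(0, 0, np.array([0], dtype=np.int64))
    extend(M0)
    hist[0] = (M0, _EMPTY, _EMPTY)
    d_final = n - m
    if M0.get(d_final) >= n:
        return A * n, [("=", n)]

    s = 0
    while True:
        s += 1
        if s > budget or s > x2 * (n + m):
            return None
        Mx = hist.get(s - x2, (_EMPTY,) * 3)[0]
        Moe = hist.get(s - o2 - e2, (_EMPTY,) * 3)[0]
        Ie = hist.get(s - e2, (_EMPTY,) * 3)[1]
        De = hist.get(s - e2, (_EMPTY,) * 3)[2]
        los = [w.lo for w in (Mx, Moe, Ie, De) if w.hi >= w.lo]
        his = [w.hi for w in (Mx, Moe, Ie, De) if w.hi >= w.lo]
        if not los:
            hist[s] = (_EMPTY, _EMPTY, _EMPTY)
            continue
        lo, hi = min(los) - 1, max(his) + 1
        dr = np.arange(lo, hi + 1)
        iv = _Wave(lo, hi, None)

        I_arr = np.maximum(Moe.vec(lo - 1, hi - 1), Ie.vec(lo - 1, hi - 1)) + 1
        D_arr = np.maximum(Moe.vec(lo + 1, hi + 1), De.vec(lo + 1, hi + 1))
        M_arr = np.maximum(Mx.vec(lo, hi) + 1, np.maximum(I_arr, D_arr))

        def _clamp(arr):
            i = arr
            j = i - dr
            bad = (i < 0) | (i > n) | (j < 0) | (j > m) | (i < NEG // 2 + 10**6)
            return np.where(bad, NEG, i)

        I_arr = _clamp(I_arr)
        D_arr = _clamp(D_arr)
        M_arr = _clamp(M_arr)
        Mw = _Wave(lo, hi, M_arr)
        extend(Mw)
        hist[s] = (Mw, _Wave(lo, hi, I_arr), _Wave(lo, hi, D_arr))
        if Mw.get(d_final) >= n:
            break

    score = (A * (n + m) - s) // 2
    ops = _wfa_traceback(hist, s, d_final, n, x2, o2, e2, R)
    return score, merge_ops(ops)


def _wfa_traceback(hist, s, d, n, x2, o2, e2, R):
    ops = []
    state = "M"
    i = n
    while True:
        M, I, D = hist.get(s, (_EMPTY,) * 3)
        if state == "M":
            if s == 0:
                ops.append(("=", i))
                break
            mism = hist.get(s - x2, (_EMPTY,) * 3)[0].get(d) + 1
            ins = I.get(d)
            dele = D.get(d)
            i0 = max(mism, ins, dele)
            if i > i0:
                ops.append(("=", i - i0))
                i = i0
            if i == mism and mism > NEG // 2:
                ops.append(("X", 1))
                s, i = s - x2, i - 1
            elif i == dele and dele > NEG // 2:
                state = "D"
            else:
                state = "I"
        elif state == "I":
            prev_ext = hist.get(s - e2, (_EMPTY,) * 3)[1].get(d - 1)
            ops.append(("I", 1))
            if prev_ext > NEG // 2 and prev_ext + 1 == i:
                s, d, i = s - e2, d - 1, i - 1
            else:
                s, d, i = s - o2 - e2, d - 1, i - 1
                state = "M"
        else:  # D
            prev_ext = hist.get(s - e2, (_EMPTY,) * 3)[2].get(d + 1)
            ops.append(("D", 1))
            if prev_ext > NEG // 2 and prev_ext == i:
                s, d = s - e2, d + 1
            else:
                s, d = s - o2 - e2, d + 1
                state = "M"
    return ops[::-1]


# ---------------------------------------------------------------------------
# Haplotype walk enumeration between positions
# ---------------------------------------------------------------------------


class HaplotypeWalkIndex:
    """Occurrence lists of oriented nodes in the haplotype walks (both
    directions), for fast local walk enumeration."""

    def __init__(self, graph: VariationGraph):
        self.graph = graph
        self.walks = []
        self.occ: dict = {}  # (node, orientation) -> [(walk_idx, step_idx)]
        for w in graph.haplotype_walks():
            for view in (w, w.reversed()):
                wi = len(self.walks)
                self.walks.append(view)
                for si, st in enumerate(view.steps):
                    self.occ.setdefault((st.node_id, st.orientation), []).append(
                        (wi, si)
                    )


def enumerate_local_haplotypes(
    graph: VariationGraph,
    from_pos: Position,
    to_pos: Position,
    limit: int = 16,
    max_len: int | None = None,
    walk_index: HaplotypeWalkIndex | None = None,
):
    """Distinct haplotype-consistent walks from just after ``from_pos`` to
    just before ``to_pos``, with their spelled strings.

    Each result is (steps, string): steps cover the nodes from
    ``from_pos``'s node through ``to_pos``'s node inclusive; the string
    holds the bases strictly between the two positions. Capped at
    ``limit`` results; walks longer than ``max_len`` bases between are
    abandoned.
    """
    if walk_index is None:
        walk_index = HaplotypeWalkIndex(graph)
    if max_len is None:
        max_len = 10_000
    out = []
    seen = set()
    same_node = (
        from_pos.node_id == to_pos.node_id
        and from_pos.orientation == to_pos.orientation
        and to_pos.offset > from_pos.offset
    )
    for wi, si in walk_index.occ.get((from_pos.node_id, from_pos.orientation), ()):
        steps = walk_index.walks[wi].steps
        tail0 = oriented_sequence(graph, steps[si])[from_pos.offset + 1 :]
        if same_node:
            string = oriented_sequence(graph, steps[si])[
                from_pos.offset + 1 : to_pos.offset
            ]
            key = ((steps[si],), string)
            if key not in seen:
                seen.add(key)
                out.append(([steps[si]], string))
        parts = [tail0]
        consumed = len(tail0)
        j = si
        while consumed <= max_len and len(out) < limit * 4:
            j += 1
            if j >= len(steps):
                break
            st = steps[j]
            if st.node_id == to_pos.node_id and st.orientation == to_pos.orientation:
                string = "".join(parts) + oriented_sequence(graph, st)[: to_pos.offset]
                sub = tuple(steps[si : j + 1])
                key = (sub, string)
                if key not in seen:
                    seen.add(key)
                    out.append((list(sub), string))
                # fall through: the walk may reach to_pos again (loops)
            seq = oriented_sequence(graph, st)
            parts.append(seq)
            consumed += len(seq)
    out.sort(key=lambda r: (len(r[1]), r[1], tuple(r[0])))
    return out[:limit]


# ---------------------------------------------------------------------------
# Graph dynamic programming engine (banded global and X-drop extension)
# ---------------------------------------------------------------------------


def _successor_positions(graph: VariationGraph, pos: Position):
    n = graph.node_len(pos.node_id)
    if pos.offset >= n:
        return []  # virtual end-of-graph state
    if pos.offset + 1 < n:
        return [Position(pos.node_id, pos.orientation, pos.offset + 1)]
    exit_side = NodeSide(pos.node_id, RIGHT if pos.orientation == FORWARD else LEFT)
    out = []
    for t in graph.adjacency()[exit_side]:
        out.append(Position(t.node_id, FORWARD if t.side == LEFT else 1, 0))
    if not out:
        # dead end: a virtual position one past the node so the last base
        # can still be consumed
        out.append(Position(pos.node_id, pos.orientation, n))
    return out


class _Col:
    __slots__ = ("t", "pos", "lo", "hi", "M", "I", "D", "btM", "btD", "preds")

    def __init__(self, t, pos, lo, hi):
        self.t, self.pos, self.lo, self.hi = t, pos, lo, hi
        size = hi - lo + 1
        self.M = np.full(size, NEG, dtype=np.int64)
        self.I = np.full(size, NEG, dtype=np.int64)
        self.D = np.full(size, NEG, dtype=np.int64)
        self.btM = np.full(size, -1, dtype=np.int32)
        self.btD = np.full(size, -1, dtype=np.int32)
        self.preds: list = []

    def H(self):
        return np.maximum(self.M, np.maximum(self.I, self.D))

    def ensure(self, lo, hi):
        if lo >= self.lo and hi <= self.hi:
            return
        nlo, nhi = min(lo, self.lo), max(hi, self.hi)
        size = nhi - nlo + 1
        for name, fill in (
            ("M", NEG), ("I", NEG), ("D", NEG), ("btM", -1), ("btD", -1),
        ):
            old = getattr(self, name)
            arr = np.full(size, fill, dtype=old.dtype)
            arr[self.lo - nlo : self.hi - nlo + 1] = old
            setattr(self, name, arr)
        self.lo, self.hi = nlo, nhi


class _GraphDP:
    """Column-wise gap-affine DP over the position graph.

    Columns are (t, position) states: t graph bases consumed, about to
    read ``position``; cells are query offsets. Band mode keeps
    |i - t| <= band; xdrop mode prunes cells scoring more than x below
    the running best. Cycles unroll naturally because t grows.
    """

    def __init__(self, graph, query, scoring, band=None, x_drop=None, max_cols=200_000):
        self.graph = graph
        self.q = query
        self.qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        self.n = len(query)
        self.sc = scoring
        self.band = band
        self.x_drop = x_drop
        self.max_cols = max_cols
        self.cols: dict = {}
        self.best = None  # (score, -t, -i, colkey)
        self._succ_cache: dict = {}
        self.overflowed = False

    def _succ(self, pos):
        s = self._succ_cache.get(pos)
        if s is None:
            s = _successor_positions(self.graph, pos)
            self._succ_cache[pos] = s
        return s

    def _base_at(self, pos):
        return oriented_sequence(
            self.graph, OrientedNode(pos.node_id, pos.orientation)
        )[pos.offset]

    def run(self, start_positions):
        n = self.n
        if self.band is not None:
            lo0, hi0 = 0, min(n, self.band)
        else:
            lo0, hi0 = 0, 0
        frontier: dict = {}
        for p in start_positions:
            col = frontier.setdefault((0, p), _Col(0, p, lo0, hi0))
            col.M[0] = 0
        ncols = 0
        t = 0
        while frontier:
            live = []
            for key in sorted(frontier, key=lambda kv: kv[1]):
                col = frontier[key]
                self._insert_pass(col)
                if self.x_drop is not None and not self._xdrop_trim(col):
                    continue
                self.cols[key] = col
                live.append(col)
                ncols += 1
            if ncols > self.max_cols:
                self.overflowed = True
                break
            if self.band is not None and t + 1 > n + self.band:
                break
            if self.band is not None:
                tlo, thi = max(0, t + 1 - self.band), min(n, t + 1 + self.band)
                if tlo > thi:
                    break
            frontier = {}
            for col in live:
                if col.pos.offset >= self.graph.node_len(col.pos.node_id):
                    continue  # virtual end state: nothing left to read
                base = self._base_at(col.pos)
                H = col.H()
                for p2 in self._succ(col.pos):
                    if self.band is not None:
                        wlo, whi = tlo, thi
                    else:
                        wlo, whi = col.lo, min(n, col.hi + 1)
                    key2 = (t + 1, p2)
                    col2 = frontier.get(key2)
                    if col2 is None:
                        col2 = _Col(t + 1, p2, wlo, whi)
                        frontier[key2] = col2
                    else:
                        col2.ensure(wlo, whi)
                    kidx = len(col2.preds)
                    col2.preds.append((t, col.pos))
                    self._expand(col, col2, H, base, kidx)
            t += 1
        return self.cols

    def _expand(self, col, col2, H, base, kidx):
        o, e = self.sc.gap_open, self.sc.gap_extend
        A, X = self.sc.match, self.sc.mismatch
        lo, hi = col.lo, col.hi
        lo2, hi2 = col2.lo, col2.hi
        # diagonal move: col2.M[i] <- col.H[i-1] + sub(q[i-1], base)
        i_lo = max(lo2, lo + 1, 1)
        i_hi = min(hi2, hi + 1, self.n)
        if i_lo <= i_hi:
            src = slice(i_lo - 1 - lo, i_hi - lo)
            if base == "N":
                sub = np.full(i_hi - i_lo + 1, -X, dtype=np.int64)
            else:
                sub = np.where(self.qarr[i_lo - 1 : i_hi] == ord(base), A, -X)
            cand = H[src] + sub
            st = np.full(i_hi - i_lo + 1, 0, dtype=np.int32)
            st[col.D[src] == H[src]] = 2
            st[col.I[src] == H[src]] = 1
            st[col.M[src] == H[src]] = 0
            cand[H[src] <= NEG // 2] = NEG
            dst = slice(i_lo - lo2, i_hi - lo2 + 1)
            better = cand > col2.M[dst]
            col2.M[dst] = np.where(better, cand, col2.M[dst])
            col2.btM[dst] = np.where(better, 3 * kidx + st, col2.btM[dst])
        # deletion move (graph base consumed, query static)
        j_lo = max(lo2, lo)
        j_hi = min(hi2, hi)
        if j_lo <= j_hi:
            src = slice(j_lo - lo, j_hi - lo + 1)
            dst = slice(j_lo - lo2, j_hi - lo2 + 1)
            open_ = H[src] - o - e
            open_[H[src] <= NEG // 2] = NEG
            ext = col.D[src] - e
            ext[col.D[src] <= NEG // 2] = NEG
            cand = np.maximum(open_, ext)
            frm = (ext >= open_).astype(np.int32)
            better = cand > col2.D[dst]
            col2.D[dst] = np.where(better, cand, col2.D[dst])
            col2.btD[dst] = np.where(better, 2 * kidx + frm, col2.btD[dst])

    def _insert_pass(self, col):
        o, e = self.sc.gap_open, self.sc.gap_extend
        size = col.hi - col.lo + 1
        if size <= 1:
            return
        base = np.maximum(col.M, col.D)
        idx = np.arange(size, dtype=np.int64)
        shifted = np.where(base > NEG // 2, base - o + e * idx, NEG)
        pref = np.maximum.accumulate(shifted)
        cand = np.full(size, NEG, dtype=np.int64)
        ok = pref[:-1] > NEG // 2
        cand[1:] = np.where(ok, pref[:-1] - e * idx[1:], NEG)
        col.I = np.maximum(col.I, cand)

    def _xdrop_trim(self, col):
        H = col.H()
        mx = int(H.max(initial=NEG))
        if mx <= NEG // 2:
            return False
        i_best = col.lo + int(H.argmax())
        cand = (mx, -col.t, -i_best, (col.t, col.pos))
        if self.best is None or cand > self.best:
            self.best = cand
        cut = self.best[0] - self.x_drop
        keep = np.nonzero(H >= cut)[0]
        if keep.size == 0:
            return False
        a, b = int(keep[0]), int(keep[-1])
        if a > 0 or b < col.hi - col.lo:
            new_lo, new_hi = col.lo + a, col.lo + b
            for name in ("M", "I", "D", "btM", "btD"):
                setattr(col, name, getattr(col, name)[a : b + 1])
            col.lo, col.hi = new_lo, new_hi
        return True

    # -- traceback ---------------------------------------------------------

    def traceback(self, key, i):
        """(ops, consumed positions) for the best-scoring state at query
        offset ``i`` in column ``key``."""
        col = self.cols[key]
        li = i - col.lo
        vals = (col.M[li], col.I[li], col.D[li])
        state = "MID"[int(np.argmax(vals))]
        ops = []
        positions = []
        o, e = self.sc.gap_open, self.sc.gap_extend
        while not (col.t == 0 and i == 0 and state == "M"):
            li = i - col.lo
            if state == "M":
                bt = int(col.btM[li])
                k, pstate = bt // 3, bt % 3
                pt, ppos = col.preds[k]
                positions.append(ppos)
                base = self._base_at(ppos)
                ops.append(("=", 1) if i > 0 and self.q[i - 1] == base != "N" else ("X", 1))
                col = self.cols[(pt, ppos)]
                i -= 1
                state = "MID"[pstate]
            elif state == "D":
                bt = int(col.btD[li])
                k, frm = bt // 2, bt % 2
                pt, ppos = col.preds[k]
                positions.append(ppos)
                ops.append(("D", 1))
                col = self.cols[(pt, ppos)]
                if frm == 1:
                    state = "D"
                else:
                    pli = i - col.lo
                    vals = (col.M[pli], col.I[pli], col.D[pli])
                    state = "MID"[int(np.argmax(vals))]
            else:  # I: query gap, within column
                ops.append(("I", 1))
                i -= 1
                li = i - col.lo
                if li < 0:
                    raise AssertionError("insertion traceback fell out of band")
                prev_ext = col.I[li] if col.I[li] > NEG // 2 else NEG
                base_prev = max(col.M[li], col.D[li])
                if prev_ext - e >= base_prev - o - e and prev_ext > NEG // 2:
                    state = "I"
                else:
                    state = "M" if col.M[li] >= col.D[li] else "D"
        return merge_ops(ops[::-1]), positions[::-1]


def positions_to_spans(positions):
    """Collapse a consumed-position sequence into (OrientedNode, lo, hi)
    spans with contiguous oriented offsets."""
    spans = []
    for p in positions:
        node = OrientedNode(p.node_id, p.orientation)
        if spans and spans[-1][0] == node and spans[-1][2] == p.offset:
            spans[-1] = (node, spans[-1][1], p.offset + 1)
        else:
            spans.append((node, p.offset, p.offset + 1))
    return spans


def banded_graph_align(
    query: str,
    graph: VariationGraph,
    from_pos: Position,
    to_pos: Position,
    band_width: int,
    scoring: Scoring = Scoring(),
    max_cols: int = 200_000,
):
    """Best global alignment of ``query`` to any walk strictly between two
    positions, within a band of the diagonal. Returns an AlignmentPath or
    None when no walk fits in the band (caller may widen the band once).
    """
    scoring.validate()
    dp = _GraphDP(graph, query, scoring, band=band_width, max_cols=max_cols)
    starts = _successor_positions(graph, from_pos)
    if not starts:
        return None
    dp.run(starts)
    n = len(query)
    best = None
    for (t, p), col in dp.cols.items():
        if p != to_pos or not col.lo <= n <= col.hi:
            continue
        v = int(col.H()[n - col.lo])
        if v <= NEG // 2:
            continue
        if best is None or (v, -t) > best[0]:
            best = ((v, -t), (t, p))
    if best is None:
        return None
    ops, positions = dp.traceback(best[1], n)
    return AlignmentPath(positions_to_spans(positions), ops, best[0][0])


def xdrop_tail_align(
    query_tail: str,
    graph: VariationGraph,
    anchor: Position,
    direction: int,
    x_drop: int = 100,
    scoring: Scoring = Scoring(),
    max_cols: int = 200_000,
):
    """Extend outward from an anchored base, X-drop pruned.

    ``direction`` +1 extends rightward (tail follows the anchor base); -1
    extends leftward (tail, given in read order, precedes it). The
    unaligned remainder of the tail is soft-clipped; the worst case is an
    empty alignment with the whole tail clipped.
    """
    scoring.validate()
    n = len(query_tail)
    if n == 0:
        return AlignmentPath([], [], 0)
    if direction < 0:
        from .graph import reverse_position, revcomp

        # leftward extension == rightward extension of the reverse
        # complement on the opposite strand
        res = xdrop_tail_align(
            revcomp(query_tail),
            graph,
            reverse_position(graph, anchor),
            1,
            x_drop,
            scoring,
            max_cols,
        )
        positions = []
        for node, lo, hi in res.spans:
            for k in range(lo, hi):
                positions.append(Position(node.node_id, node.orientation, k))
        mirrored = [
            Position(p.node_id, 1 - p.orientation, graph.node_len(p.node_id) - 1 - p.offset)
            for p in positions[::-1]
        ]
        return AlignmentPath(
            positions_to_spans(mirrored),
            merge_ops(res.ops[::-1]),
            res.score,
            left_clip=res.right_clip,
        )
    dp = _GraphDP(graph, query_tail, scoring, x_drop=x_drop, max_cols=max_cols)
    starts = _successor_positions(graph, anchor)
    if not starts:
        return AlignmentPath([], [], 0, right_clip=n)
    dp.run(starts)
    if dp.best is None or dp.best[0] <= 0:
        return AlignmentPath([], [], 0, right_clip=n)
    score, _nt, ni, key = dp.best
    i_best = -ni
    ops, positions = dp.traceback(key, i_best)
    return AlignmentPath(
        positions_to_spans(positions), ops, score, right_clip=n - i_best
    )


# ---------------------------------------------------------------------------
# Chain extension
# ---------------------------------------------------------------------------


@dataclass
class ExtensionParams:
    scoring: Scoring = field(default_factory=Scoring)
    band_width: int = 64
    x_drop: int = 100
    hap_limit: int = 16
    # WFA problem-size ceiling: larger link problems go straight to the
    # banded graph aligner
    wfa_max_len: int = 2**16
    max_tail: int = 20_000


class ChainExtensionError(Exception):
    """A chain link could not be stitched; the chain is discarded."""


def _anchor_base_pos(graph, anchor, b):
    """Graph position of base ``b`` (0-based) within an anchor's k-mer,
    following its stored oriented path."""
    off = anchor.pos.offset + b
    for st in anchor.seed.path:
        n = graph.node_len(st.node_id)
        if off < n:
            return Position(st.node_id, st.orientation, off)
        off -= n
    raise AssertionError("anchor path shorter than its k-mer")


def _anchor_spans(graph, anchor):
    """Consumed spans of an anchor's k bases along its path."""
    spans = []
    off = anchor.pos.offset
    remaining = anchor.length
    for st in anchor.seed.path:
        if remaining <= 0:
            break
        n = graph.node_len(st.node_id)
        take = min(n - off, remaining)
        if take > 0:
            spans.append((st, off, off + take))
            remaining -= take
        off = 0
    if remaining > 0:
        raise AssertionError("anchor path shorter than its k-mer")
    return spans


def _trim_anchor(graph, anchor, v):
    """A copy of ``anchor`` with its first ``v`` bases removed."""
    import copy

    new = copy.copy(anchor)
    new_seed = copy.copy(anchor.seed)
    pos = _anchor_base_pos(graph, anchor, v)
    # drop fully-consumed leading path steps
    path = list(anchor.seed.path)
    off = anchor.pos.offset + v
    while path and off >= graph.node_len(path[0].node_id):
        off -= graph.node_len(path[0].node_id)
        path.pop(0)
    new_seed.path = tuple(path)
    new_seed.pos = pos
    new.seed = new_seed
    new.pos = pos
    new.read_start = anchor.read_start + v
    new.length = anchor.length - v
    return new


def _hap_spans(graph, steps, from_pos, to_pos, string_len):
    """Consumed spans of a haplotype link string (strictly between the
    anchor positions)."""
    spans = []
    if not steps:
        return spans
    if len(steps) == 1:
        node = steps[0]
        lo, hi = from_pos.offset + 1, to_pos.offset
        if hi > lo:
            spans.append((node, lo, hi))
        return spans
    n0 = graph.node_len(steps[0].node_id)
    if from_pos.offset + 1 < n0:
        spans.append((steps[0], from_pos.offset + 1, n0))
    for st in steps[1:-1]:
        spans.append((st, 0, graph.node_len(st.node_id)))
    if to_pos.offset > 0:
        spans.append((steps[-1], 0, to_pos.offset))
    total = sum(hi - lo for _, lo, hi in spans)
    if total != string_len:
        raise AssertionError("haplotype span arithmetic mismatch")
    return spans


def _merge_spans(parts):
    out = []
    for sp in parts:
        for node, lo, hi in sp:
            if hi <= lo:
                continue
            if out and out[-1][0] == node and out[-1][2] == lo:
                out[-1] = (node, out[-1][1], hi)
            else:
                out.append((node, lo, hi))
    return out


def extend_chain(
    read: str,
    chain,
    graph: VariationGraph,
    index,
    params: ExtensionParams | None = None,
    walk_index: HaplotypeWalkIndex | None = None,
):
    """Extend an anchor chain into a base-level alignment of the read.

    Links between consecutive anchors are aligned by WFA against the
    haplotype strings spelled between them (best string wins), falling
    back to the banded graph aligner when no haplotype walk exists, when
    WFA fails, or when the link exceeds the WFA length ceiling. Tails are
    aligned with the X-drop extender. Raises ChainExtensionError when a
    link cannot be stitched.
    """
    if params is None:
        params = ExtensionParams()
    sc = params.scoring
    if walk_index is None:
        walk_index = HaplotypeWalkIndex(graph)

    # resolve read overlaps between consecutive anchors by trimming the
    # later anchor; anchors that add nothing are dropped
    kept = []
    for a in chain.anchors:
        if not kept:
            kept.append(a)
            continue
        prev = kept[-1]
        if a.read_start >= prev.read_end:
            kept.append(a)
            continue
        v = prev.read_end - a.read_start
        if v >= a.length:
            continue
        kept.append(_trim_anchor(graph, a, v))

    # stitch left to right; an anchor whose link cannot be aligned (e.g.
    # an allele conflict created by overlap trimming) is dropped
    span_parts = [_anchor_spans(graph, kept[0])]
    ops: list = [("=", kept[0].length)]
    stitched = [kept[0]]
    dropped = 0
    for a in kept[1:]:
        prev = stitched[-1]
        p_end = _anchor_base_pos(graph, prev, prev.length - 1)
        q_mid = read[prev.read_end : a.read_start]
        link = _align_link(q_mid, graph, p_end, a.pos, index, params, walk_index)
        if link is None:
            dropped += 1
            continue
        link_spans, link_ops = link
        span_parts.append(link_spans)
        ops.extend(link_ops)
        span_parts.append(_anchor_spans(graph, a))
        ops.append(("=", a.length))
        stitched.append(a)
    if dropped > max(2, len(kept) // 4):
        raise ChainExtensionError(
            f"{dropped} of {len(kept)} chain links could not be aligned"
        )
    kept = stitched

    # tails
    first, last = kept[0], kept[-1]
    left_tail = read[: first.read_start]
    right_tail = read[last.read_end :]
    left_clip = right_clip = 0
    if left_tail:
        lt = xdrop_tail_align(
            left_tail[-params.max_tail :], graph, first.pos, -1, params.x_drop, sc
        )
        left_clip = lt.left_clip + max(0, len(left_tail) - params.max_tail)
        span_parts.insert(0, lt.spans)
        ops = lt.ops + ops
    if right_tail:
        p_end = _anchor_base_pos(graph, last, last.length - 1)
        rt = xdrop_tail_align(
            right_tail[: params.max_tail], graph, p_end, 1, params.x_drop, sc
        )
        right_clip = rt.right_clip + max(0, len(right_tail) - params.max_tail)
        span_parts.append(rt.spans)
        ops = ops + rt.ops

    ops = merge_ops(ops)
    spans = _merge_spans(span_parts)
    path = AlignmentPath(spans, ops, sc.score_ops(ops), left_clip, right_clip)
    if path.read_span + left_clip + right_clip != len(read):
        raise ChainExtensionError("stitched alignment does not cover the read")
    if path.walk_span != sum(hi - lo for _, lo, hi in spans):
        raise ChainExtensionError("stitched alignment walk-span mismatch")
    return path


def _align_link(q_mid, graph, from_pos, to_pos, index, params, walk_index):
    """Align the read segment between two anchors; returns (spans, ops)
    or None."""
    sc = params.scoring
    d = index.min_distance(from_pos, to_pos)
    if d == INF:
        return None
    if d == 0 and not q_mid:
        return [], []
    max_len = min(max(2 * len(q_mid) + 32, d + 32), params.wfa_max_len)
    best = None
    if d <= params.wfa_max_len and len(q_mid) <= params.wfa_max_len:
        cands = enumerate_local_haplotypes(
            graph, from_pos, to_pos, params.hap_limit, max_len, walk_index
        )
        for steps, s in cands:
            gap = abs(len(s) - len(q_mid))
            budget = (
                sc.mismatch * (min(len(s), len(q_mid)) // 3 + 2)
                + 2 * (sc.gap_open + sc.gap_extend * (gap + 8))
                + 16
            )
            res = wfa_align(q_mid, s, sc, max_score_gap=budget)
            if res is None:
                continue
            score, w_ops = res
            if best is None or score > best[0]:
                best = (score, steps, s, w_ops)
    if best is not None:
        _, steps, s, w_ops = best
        spans = _hap_spans(graph, steps, from_pos, to_pos, len(s))
        return spans, w_ops
    # graph fallback: banded global alignment between the anchors
    band = max(params.band_width, abs(d - len(q_mid)) + 8)
    for b in (band, band * 2):
        res = banded_graph_align(q_mid, graph, from_pos, to_pos, b, sc)
        if res is not None:
            return res.spans, res.ops
    return None
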