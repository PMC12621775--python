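"""Minimizer seeding over haplotype walk sequences.

The index stores (w,k)-minimizers of every haplotype walk, keyed by an
invertible 64-bit hash of the 2-bit-packed canonical k-mer, mapped to the
graph positions (and oriented node paths) where the k-mer is spelled.
Because k-mers are taken from walk sequences, seeds may start mid-node and
span edges.

Seed selection uses *weighted minimizers*: each read minimizer gets weight
(1 + n_occurrences)^-q, rare minimizers are emitted first, minimizers over
the hard hit cap contribute no seeds, and emission stops once the emitted
weight covers ``score_fraction`` of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .graph import FORWARD, REVERSE, OrientedNode, Position, VariationGraph

# splitmix64 finalizer; fixed constants so index files and tests are
# reproducible across runs and platforms
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class SeedingParams:
    k: int = 29
    w: int = 11
    hard_hit_cap: int = 500
    weight_downweight: float = 0.8
    score_fraction: float = 0.9

    def validate(self):
        if not 1 <= self.k <= 31:
            raise ParameterError(f"k must be in [1, 31], got {self.k}")
        if self.w < 1:
            raise ParameterError(f"window must be >= 1, got {self.w}")
        if self.hard_hit_cap <= 0:
            raise ParameterError("hard_hit_cap must be positive")


@dataclass(eq=False)
class Seed:
    """An exact k-mer match between read and graph.

    ``pos`` is the graph position of the first base of the k-mer *as read*
    (so the read k-mer is spelled forward from ``pos``); ``path`` is the
    oriented node walk it spells along.
    """

    read_offset: int
    pos: Position
    mhash: int
    path: tuple[OrientedNode, ...]
    length: int = 0  # k-mer length
    zipcode: object = None

    def __repr__(self):
        return f"Seed(r{self.read_offset}@{self.pos})"


@dataclass
class MinimizerIndex:
    k: int
    w: int
    # hash -> list of (pos_forward, pos_rc, path_forward)
    hits: dict = field(default_factory=dict)

    def count(self, h: int) -> int:
        lst = self.hits.get(h)
        return len(lst) if lst else 0


def _pack_kmers(seq: str, k: int):
    """(fwd, rc, valid) packed 2-bit k-mer arrays for every offset."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return None
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    valid = (win < 4).all(axis=1)
    pw_f = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    pw_r = (np.uint64(1) << (np.uint64(2) * np.arange(k, dtype=np.uint64)))
    with np.errstate(over="ignore"):
        fwd = (win * pw_f).sum(axis=1)
        rc = ((np.uint64(3) - win) * pw_r).sum(axis=1)
    return fwd, rc, valid


def _hash64(x):
    with np.errstate(over="ignore"):
        x = np.uint64(x).copy() if isinstance(x, np.ndarray) else np.uint64(x)
        x = x ^ (x >> np.uint64(30))
        x = x * _MIX1
        x = x ^ (x >> np.uint64(27))
        x = x * _MIX2
        x = x ^ (x >> np.uint64(31))
    return x


def minimizers(seq: str, k: int, w: int):
    """(offset, canonical_hash, read_is_canonical) for each (w,k)-minimizer.

    The minimizer of a window is the valid k-mer with the smallest hash of
    its canonical (strand-independent) packed form; ties break leftmost.
    """
    packed = _pack_kmers(seq, k)
    if packed is None:
        return []
    fwd, rc, valid = packed
    canon = np.minimum(fwd, rc)
    h = _hash64(canon)
    h[~valid] = np.iinfo(np.uint64).max
    n = len(h)
    if n < 1:
        return []
    ww = min(w, n)
    windows = np.lib.stride_tricks.sliding_window_view(h, ww)
    arg = windows.argmin(axis=1) + np.arange(windows.shape[0])
    sel = np.unique(arg)
    sel = sel[valid[sel]]
    is_canon = fwd[sel] <= rc[sel]
    hs = h[sel]
    return [
        (int(o), int(hh), bool(c)) for o, hh, c in zip(sel, hs, is_canon)
    ]


def _walk_offsets(graph, walk):
    offs = [0]
    for st in walk.steps:
        offs.append(offs[-1] + graph.node_len(st.node_id))
    return offs


def _pos_at(graph, walk, offs, walk_off, flip=False):
    """Graph position of the base at a walk offset (optionally on the
    opposite strand)."""
    import bisect

    i = bisect.bisect_right(offs, walk_off) - 1
    st = walk.steps[i]
    within = walk_off - offs[i]
    n = graph.node_len(st.node_id)
    if not flip:
        return Position(st.node_id, st.orientation, within), i
    return Position(st.node_id, 1 - st.orientation, n - 1 - within), i


def build_minimizer_index(graph: VariationGraph, params: SeedingParams) -> MinimizerIndex:
    """Index the (w,k)-minimizers of every haplotype walk sequence."""
    params.validate()
    walks = graph.haplotype_walks()
    if not walks:
        raise ParameterError("graph has no haplotype walks to index")
    from .graph import walk_sequence

    k = params.k
    index = MinimizerIndex(k=k, w=params.w)
    seen: dict[int, set] = {}
    for walk in walks:
        seq = walk_sequence(graph, walk)
        offs = _walk_offsets(graph, walk)
        for off, h, is_canon in minimizers(seq, k, params.w):
            p_f, i0 = _pos_at(graph, walk, offs, off)
            p_r, i1 = _pos_at(graph, walk, offs, off + k - 1, flip=True)
            if not is_canon:
                # store canonically: pos_forward spells the canonical k-mer
                p_f, p_r = p_r, p_f
                path = tuple(s.flip() for s in walk.steps[i0 : i1 + 1][::-1])
            else:
                path = tuple(walk.steps[i0 : i1 + 1])
            key = seen.setdefault(h, set())
            if p_f in key:
                continue
            key.add(p_f)
            index.hits.setdefault(h, []).append((p_f, p_r, path))
    return index


def select_seeds(read: str, index: MinimizerIndex, params: SeedingParams) -> list[Seed]:
    """Weighted-minimizer seed selection for one read.

    Minimizers are processed in decreasing weight 1/(1+count)^q; each one's
    graph hits are emitted as seeds until the processed weight reaches
    ``score_fraction`` of the total. Minimizers with more than
    ``hard_hit_cap`` occurrences are skipped (their weight still counts as
    processed).
    """
    params.validate()
    if len(read) < index.k:
        return []
    mins = minimizers(read, index.k, index.w)
    if not mins:
        return []
    q = params.weight_downweight
    weighted = []
    total = 0.0
    for off, h, is_canon in mins:
        cnt = index.count(h)
        if cnt == 0:
            continue  # not in the graph (sequencing error or novel sequence)
        wgt = (1.0 + cnt) ** (-q)
        total += wgt
        weighted.append((wgt, off, h, is_canon))
    # ties break on the hash so that any dropped fraction scatters evenly
    # across the read instead of truncating one end
    weighted.sort(key=lambda t: (-t[0], t[2], t[1]))
    goal = params.score_fraction * total
    got = 0.0
    seeds: list[Seed] = []
    for wgt, off, h, is_canon in weighted:
        if got >= goal:
            break
        got += wgt
        occs = index.hits.get(h)
        if len(occs) > params.hard_hit_cap:
            continue
        for p_f, p_r, path in occs:
            if is_canon:
                seeds.append(Seed(off, p_f, h, path, index.k))
            else:
                seeds.append(
                    Seed(off, p_r, h, tuple(s.flip() for s in path[::-1]), index.k)
                )
    seeds.sort(key=lambda s: (s.read_offset, s.pos))
    return seeds
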