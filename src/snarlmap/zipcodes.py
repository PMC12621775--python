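"""Zip codes and the zip code tree: seed ordering and distances for chaining.

A *zip code* records a position's placement on the snarl tree — the chain
items and snarl children on the path from the root down to the node,
with chain-direction coordinates — so seeds can be sorted into a traversal
order of the snarl tree and grouped by shared ancestry without touching
the graph.

A *zip code tree* lays the seeds of one read out in that order (one tree
per connected component and traversal direction, so a forest per read).
Seeds that can reach themselves through a cycle are duplicated once,
approximating an unrolled, acyclic view in which a read may cross a loop
twice. Iterating predecessors of a seed yields exact graph distances from
the distance index; pairs that cannot reach each other (parallel alleles)
are never yielded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distance import INF, DistanceIndex
from .errors import ConsistencyError
from .graph import FORWARD, Position
from .seeds import Seed

__all__ = [
    "ZipCode",
    "ZipCodeTree",
    "compute_zipcode",
    "zip_sort_key",
    "build_zip_forest",
    "tree_distance_iter",
]


@dataclass(frozen=True)
class ZipCode:
    """Snarl-tree ancestry of a position, root first.

    records: tuples, one per level —
      ('chain', chain_id, item_index)   chain level, item holding the next level
      ('snarl', snarl_id, child_rank)   snarl level, rank of the child chain
      ('node', node_id, coord, orientation_in_chain_direction)
    ``coord`` is the base offset in chain-forward coordinates.
    """

    records: tuple

    @property
    def root_id(self) -> int:
        return self.records[0][1]


def compute_zipcode(index: DistanceIndex, pos: Position) -> ZipCode:
    if pos.node_id not in index.node_rec:
        raise ConsistencyError(f"position {pos} is not in the indexed graph")
    rec, item = index.node_rec[pos.node_id]
    n = index.graph.node_len(pos.node_id)
    item_orient = rec.orients[item]
    # base offset in node-forward coordinates, then chain-forward
    off_f = pos.offset if pos.orientation == FORWARD else n - 1 - pos.offset
    coord = off_f if item_orient == FORWARD else n - 1 - off_f
    arrives_fwd = pos.orientation == item_orient
    down = [("node", pos.node_id, coord, 0 if arrives_fwd else 1)]
    # chain-level positions interleave node items (2i) and snarl slots
    # (2t+1) so that node t < snarl t < node t+1 in sort order
    r, item_key = rec, 2 * item
    while True:
        down.append(("chain", id(r.chain), item_key))
        s = r.parent_snarl
        if s is None:
            root = ("root", r.root_id)
            break
        down.append(("snarl", id(s.snarl), r.child_index))
        r = s.parent_chain
        item_key = 2 * s.pos_t + 1
    return ZipCode((root,) + tuple(down[::-1]))


def zip_sort_key(zipcode: ZipCode):
    """A totally ordered key grouping seeds by ancestry and ordering them
    along chains (graph access free)."""
    key = []
    for rec in zipcode.records:
        if rec[0] == "root":
            key.append(rec[1])
        elif rec[0] == "chain":
            key.append(rec[2])
        elif rec[0] == "snarl":
            key.append(rec[2])
        else:  # node
            key.append(rec[2])
            key.append(rec[3])
    return tuple(key)


def zip_seeds(seeds: list[Seed], index: DistanceIndex) -> None:
    for s in seeds:
        if s.zipcode is None:
            s.zipcode = compute_zipcode(index, s.pos)


@dataclass(eq=False)
class ZipCodeTree:
    """Ordered seed occurrences for one component and traversal direction."""

    direction: int  # +1: chain-forward traversal; -1: reverse
    occs: list  # list of (seed, copy_index)
    index: DistanceIndex
    _dists: list | None = None

    def __len__(self):
        return len(self.occs)

    @property
    def dists(self):
        """Edge labels: distance from each occurrence to the next (lazy)."""
        if self._dists is None:
            self._dists = _adjacent_dists(self.occs, self.index)
        return self._dists

    def dump(self) -> str:
        """Indented text rendering: seeds nested in their snarl-tree
        structures, with adjacent-seed distance labels."""
        lines = [f"tree dir={'+' if self.direction > 0 else '-'}"]
        prev_records = ()
        for i, (seed, copy) in enumerate(self.occs):
            recs = seed.zipcode.records
            depth = sum(1 for r in recs if r[0] in ("chain", "snarl"))
            shared = 0
            for r1, r2 in zip(prev_records, recs):
                if r1 != r2 or r1[0] == "node":
                    break
                shared += 1
            for lvl in range(shared, len(recs)):
                r = recs[lvl]
                if r[0] == "chain":
                    lines.append("  " * lvl + f"chain[{r[2]}]")
                elif r[0] == "snarl":
                    lines.append("  " * lvl + f"snarl(child {r[2]})")
            label = "" if i + 1 >= len(self.occs) else f"  ->next {self.dists[i]}"
            lines.append(
                "  " * depth
                + f"seed r{seed.read_offset}@{seed.pos} copy{copy}{label}"
            )
            prev_records = recs
        return "\n".join(lines)


def _occurrence_order(seeds: list[Seed], index: DistanceIndex):
    """Sorted occurrences with loop duplication.

    Seeds that can reach themselves (finite loop distance) form runs in
    sort order; each maximal run is emitted twice, giving each loop seed a
    second, later copy to support one extra cycle traversal.
    """
    loopable = {}

    def is_loopable(seed):
        key = (seed.pos.node_id, seed.pos.orientation)
        if key not in loopable:
            loopable[key] = index.loop_distance(seed.pos) < INF
        return loopable[key]

    ordered = sorted(seeds, key=lambda s: (zip_sort_key(s.zipcode), s.read_offset))
    occs = []
    run: list[Seed] = []
    for s in ordered:
        if is_loopable(s):
            run.append(s)
            occs.append((s, 0))
        else:
            if run:
                occs.extend((r, 1) for r in run)
                run = []
            occs.append((s, 0))
    if run:
        occs.extend((r, 1) for r in run)
    return occs


def build_zip_forest(seeds: list[Seed], index: DistanceIndex) -> list[ZipCodeTree]:
    """Group zip-coded seeds into trees: one per connected component and
    traversal direction. Trees are deterministic for a given seed set."""
    zip_seeds(seeds, index)
    by_root: dict[int, list[Seed]] = {}
    for s in seeds:
        by_root.setdefault(s.zipcode.root_id, []).append(s)
    forest = []
    for root_id in sorted(by_root):
        group = by_root[root_id]
        occs = _occurrence_order(group, index)
        forest.append(ZipCodeTree(1, occs, index))
        forest.append(ZipCodeTree(-1, occs[::-1], index))
    return forest


def _pair_distance(index, p_occ, s_occ):
    p, pc = p_occ
    s, sc = s_occ
    if p.pos == s.pos:
        if pc == sc and p is not s:
            return 0  # same base, same copy: co-located seeds
        if pc != sc:
            return index.loop_distance(p.pos)
        return INF
    return index.min_distance(p.pos, s.pos)


def _adjacent_dists(occs, index):
    return [
        _pair_distance(index, occs[i], occs[i + 1]) for i in range(len(occs) - 1)
    ]


def tree_distance_iter(
    tree: ZipCodeTree,
    from_index: int,
    lookback: int = 500,
    max_gap: float = INF,
    read_window: tuple[int, int] | None = None,
):
    """Yield (occurrence_index, distance) for predecessors of a seed.

    Walks earlier occurrences (nearest first in tree order), computing the
    exact graph distance to the query seed; unreachable pairs are skipped.
    ``read_window`` (lo, hi) prefilters candidates by their seed's read
    offset before any distance work. Stops after examining ``lookback``
    candidates. Results come in non-decreasing distance order within the
    examined band.
    """
    occs = tree.occs
    s_occ = occs[from_index]
    found = []
    examined = 0
    scanned = 0
    scan_limit = max(4 * lookback, 256)
    lo_hi = read_window
    for j in range(from_index - 1, -1, -1):
        if examined >= lookback or scanned >= scan_limit:
            break
        scanned += 1
        if lo_hi is not None:
            off = occs[j][0].read_offset
            if off < lo_hi[0] or off >= lo_hi[1]:
                continue
        examined += 1
        d = _pair_distance(tree.index, occs[j], s_occ)
        if d < INF and d <= max_gap:
            found.append((j, d))
    found.sort(key=lambda t: (t[1], -t[0]))
    yield from found
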