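"""Snarl decomposition of a variation graph.

A *snarl* is a subgraph delimited by two boundary node sides that are

* separable — cutting the two boundary nodes into their component sides
  disconnects the subgraph between the boundaries from the rest of the
  graph, and
* minimal — no side of a node inside the subgraph is itself separable
  with either boundary.

Snarls abut one another on shared nodes, forming *chains* (alternating
node, snarl, node, ...); chains nest inside snarls, giving the snarl tree.
The decomposition is not unique in general; this module fixes one
canonical form (documented in the methods note) so results are
deterministic.

The decomposition here is definition-driven: candidate boundary pairs are
enumerated via bridge analysis of the biedged (side) graph, then verified
against the separability and minimality definitions directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ConsistencyError, InvalidPairError
from .graph import FORWARD, LEFT, REVERSE, RIGHT, NodeSide, OrientedNode, VariationGraph

__all__ = [
    "Snarl",
    "SnarlChain",
    "SnarlTree",
    "is_separable",
    "separable_content",
    "is_minimal",
    "decompose",
    "leaf_snarls",
]


# ---------------------------------------------------------------------------
# Definitional checks (also the oracle used by the test-suite)
# ---------------------------------------------------------------------------


def _cut_component(graph: VariationGraph, a: NodeSide, b: NodeSide) -> set[NodeSide]:
    """Connected side set containing ``a`` after cutting the nodes of ``a``
    and ``b`` into their component sides.

    Traversal may cross adjacency edges freely and node edges of every node
    except ``a.node_id`` and ``b.node_id``.
    """
    cut = {a.node_id, b.node_id}
    adj = graph.adjacency()
    seen = {a}
    stack = [a]
    while stack:
        s = stack.pop()
        for t in adj[s]:
            if t not in seen:
                seen.add(t)
                stack.append(t)
        if s.node_id not in cut:
            o = s.opposite()
            if o not in seen:
                seen.add(o)
                stack.append(o)
    return seen


def is_separable(graph: VariationGraph, a: NodeSide, b: NodeSide) -> bool:
    """Definitional separability check for a candidate boundary pair."""
    if a.node_id == b.node_id:
        raise InvalidPairError(f"boundary sides {a} and {b} are on the same node")
    comp = _cut_component(graph, a, b)
    return b in comp and a.opposite() not in comp and b.opposite() not in comp


def separable_content(graph: VariationGraph, a: NodeSide, b: NodeSide) -> frozenset[int]:
    """Node ids strictly between a separable pair (excludes the boundaries)."""
    comp = _cut_component(graph, a, b)
    return frozenset(s.node_id for s in comp) - {a.node_id, b.node_id}


def is_minimal(
    graph: VariationGraph,
    a: NodeSide,
    b: NodeSide,
    separable_pairs: set[tuple[NodeSide, NodeSide]] | None = None,
) -> bool:
    """True iff no side of a content node is separable with either boundary.

    ``separable_pairs`` may carry a precomputed set of separable pairs
    (canonically ordered tuples) to avoid repeated reachability scans.
    """

    def _sep(x, y):
        if separable_pairs is not None:
            return (min(x, y), max(x, y)) in separable_pairs
        return is_separable(graph, x, y)

    for nid in separable_content(graph, a, b):
        for side in (NodeSide(nid, LEFT), NodeSide(nid, RIGHT)):
            if _sep(a, side) or _sep(side, b):
                return False
    return True


# ---------------------------------------------------------------------------
# Tree data model
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Snarl:
    """A separable, minimal boundary pair and the subgraph between it.

    ``start``/``end`` face *into* the snarl; ``content`` excludes the
    boundary nodes. ``children`` holds the chains decomposing the content.
    """

    start: NodeSide
    end: NodeSide
    content: frozenset[int]
    children: list["SnarlChain"] = field(default_factory=list)
    parent_chain: "SnarlChain | None" = None

    @property
    def boundary_nodes(self) -> tuple[int, int]:
        return (self.start.node_id, self.end.node_id)

    def span_sides(self) -> set[NodeSide]:
        sides = {self.start, self.end}
        for nid in self.content:
            sides.add(NodeSide(nid, LEFT))
            sides.add(NodeSide(nid, RIGHT))
        return sides

    def __repr__(self):
        return f"Snarl({self.start}..{self.end}|{sorted(self.content)})"


@dataclass(eq=False)
class SnarlChain:
    """Alternating run of nodes and snarls sharing boundary nodes.

    ``nodes[i]`` is oriented in the chain direction; ``snarls[i]`` joins
    ``nodes[i]`` to ``nodes[i+1]``. A cyclic chain carries one extra snarl
    joining the last node back to the first.
    """

    nodes: list[OrientedNode]
    snarls: list[Snarl]
    cyclic: bool = False
    parent: Snarl | None = None

    @property
    def items(self) -> list:
        """Alternating item list: node id, snarl, node id, ..."""
        out: list = []
        for i, n in enumerate(self.nodes):
            out.append(n.node_id)
            if i < len(self.snarls):
                out.append(self.snarls[i])
        return out

    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]

    def __repr__(self):
        parts = []
        for i, n in enumerate(self.nodes):
            parts.append(repr(n))
            if i < len(self.snarls):
                parts.append(repr(self.snarls[i]))
        tag = " (cyclic)" if self.cyclic else ""
        return "Chain[" + ", ".join(parts) + f"]{tag}"


@dataclass(eq=False)
class SnarlTree:
    """Nested snarl/chain decomposition of a whole graph."""

    graph: VariationGraph
    roots: list[SnarlChain]
    node_chain: dict[int, tuple[SnarlChain, int]]
    # edges that could not be assigned to any snarl (pathological inputs:
    # e.g. a self-loop on a dangling chain end)
    unassigned_edges: list[tuple[NodeSide, NodeSide]] = field(default_factory=list)

    def all_snarls(self) -> list[Snarl]:
        out = []

        def _chain(chain):
            for s in chain.snarls:
                out.append(s)
                for c in s.children:
                    _chain(c)

        for root in self.roots:
            _chain(root)
        return out

    def all_chains(self) -> list[SnarlChain]:
        out = []

        def _chain(chain):
            out.append(chain)
            for s in chain.snarls:
                for c in s.children:
                    _chain(c)

        for root in self.roots:
            _chain(root)
        return out

    def to_json(self) -> str:
        def _snarl(s):
            return {
                "start": [s.start.node_id, "LR"[s.start.side]],
                "end": [s.end.node_id, "LR"[s.end.side]],
                "content": sorted(s.content),
                "children": [_chain(c) for c in s.children],
            }

        def _chain(c):
            return {
                "cyclic": c.cyclic,
                "nodes": [[n.node_id, "+-"[n.orientation]] for n in c.nodes],
                "snarls": [_snarl(s) for s in c.snarls],
            }

        return json.dumps([_chain(r) for r in self.roots], indent=1)


def leaf_snarls(tree: SnarlTree) -> list[Snarl]:
    """Snarls whose child chains are all single nodes (no nested snarls)."""
    return [
        s
        for s in tree.all_snarls()
        if all(len(c.snarls) == 0 and len(c.nodes) == 1 for c in s.children)
    ]


# ---------------------------------------------------------------------------
# Fast enumeration of separable-minimal pairs
# ---------------------------------------------------------------------------


def _adjacency_components(graph: VariationGraph):
    """Components of the side graph under adjacency edges only."""
    adj = graph.adjacency()
    comp: dict[NodeSide, int] = {}
    order = []
    for nid in sorted(graph.sequences):
        order.append(NodeSide(nid, LEFT))
        order.append(NodeSide(nid, RIGHT))
    nxt = 0
    for s0 in order:
        if s0 in comp:
            continue
        comp[s0] = nxt
        stack = [s0]
        while stack:
            s = stack.pop()
            for t in adj[s]:
                if t not in comp:
                    comp[t] = nxt
                    stack.append(t)
        nxt += 1
    counts = [0] * nxt
    for s in comp:
        counts[comp[s]] += 1
    return comp, counts


def _separable_pairs_fast(graph: VariationGraph):
    """All separable side pairs, with region-size estimates.

    For each node ``u``, node edges of all other nodes merge the
    adjacency components into a multigraph; a pair ``(u.*, v.*)`` can only
    be separable if the node edge of ``v`` is a bridge there, and the side
    conditions reduce to which side of the bridge each side lands on.
    Returns ``{(a, b) canonical: region_side_count}``.
    """
    acomp, acnt = _adjacency_components(graph)
    nodes = sorted(graph.sequences)
    n_ac = len(acnt)
    node_edge = {v: (acomp[NodeSide(v, LEFT)], acomp[NodeSide(v, RIGHT)]) for v in nodes}

    pairs: dict[tuple[NodeSide, NodeSide], int] = {}

    for u in nodes:
        # multigraph over adjacency components, labeled by node id
        adj: list[list[tuple[int, int]]] = [[] for _ in range(n_ac)]
        for v in nodes:
            if v == u:
                continue
            x, y = node_edge[v]
            if x == y:
                continue  # self-loop can never be a bridge
            adj[x].append((y, v))
            adj[y].append((x, v))

        tin = [-1] * n_ac
        tout = [0] * n_ac
        low = [0] * n_ac
        sub_sides = [0] * n_ac
        rootc = [-1] * n_ac
        bridges = []  # (node label, child_acomp)
        timer = 0
        for start in range(n_ac):
            if tin[start] != -1:
                continue
            # iterative DFS with bridge detection; one copy of the entry
            # edge is skipped per vertex so parallel edges act as back edges
            entry_label = {start: -1}
            skipped = {start: True}
            stack = [(start, iter(adj[start]))]
            tin[start] = low[start] = timer
            timer += 1
            sub_sides[start] = acnt[start]
            rootc[start] = start
            while stack:
                x, it = stack[-1]
                advanced = False
                for y, label in it:
                    if label == entry_label[x] and not skipped[x]:
                        skipped[x] = True
                        continue
                    if tin[y] == -1:
                        tin[y] = low[y] = timer
                        timer += 1
                        sub_sides[y] = acnt[y]
                        rootc[y] = start
                        entry_label[y] = label
                        skipped[y] = False
                        stack.append((y, iter(adj[y])))
                        advanced = True
                        break
                    else:
                        if tin[y] < low[x]:
                            low[x] = tin[y]
                if not advanced:
                    tout[x] = timer
                    stack.pop()
                    if stack:
                        px = stack[-1][0]
                        if low[x] < low[px]:
                            low[px] = low[x]
                        sub_sides[px] += sub_sides[x]
                        if low[x] > tin[px]:
                            bridges.append((entry_label[x], x))

        for label, child in bridges:
            v = label
            # region A = subtree(child); region B = rest of the root component
            c_tin, c_tout = tin[child], tout[child]

            def _in_sub(ac):
                return c_tin <= tin[ac] < c_tout

            for a_side in (NodeSide(u, LEFT), NodeSide(u, RIGHT)):
                ca = acomp[a_side]
                if rootc[ca] != rootc[child]:
                    continue
                a_in = _in_sub(ca)
                co = acomp[a_side.opposite()]
                if rootc[co] == rootc[child] and _in_sub(co) == a_in:
                    continue  # opposite side of u escapes into the region
                for b_side in (NodeSide(v, LEFT), NodeSide(v, RIGHT)):
                    cb = acomp[b_side]
                    if _in_sub(cb) != a_in:
                        continue
                    key = (min(a_side, b_side), max(a_side, b_side))
                    if a_in:
                        size = sub_sides[child]
                    else:
                        size = sub_sides[rootc[child]] - sub_sides[child]
                    pairs.setdefault(key, size)
    return pairs


def _separable_pairs_bruteforce(graph: VariationGraph):
    """Reference enumeration via the definitional check (small graphs)."""
    pairs = {}
    nodes = sorted(graph.sequences)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            for a in (NodeSide(u, LEFT), NodeSide(u, RIGHT)):
                for b in (NodeSide(v, LEFT), NodeSide(v, RIGHT)):
                    if is_separable(graph, a, b):
                        key = (min(a, b), max(a, b))
                        comp = _cut_component(graph, a, b)
                        pairs[key] = len(comp)
    return pairs


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def _minimal_pairs(graph: VariationGraph, sep: dict):
    """Filter separable pairs down to the minimal ones.

    For each side the partner with the smallest region is the only
    minimality candidate (regions of one side are nested); candidates are
    then verified against the definition, and a pair is kept when both
    sides choose each other.
    """
    sep_set = set(sep)
    partners: dict[NodeSide, list[tuple[int, NodeSide]]] = {}
    for (a, b), size in sep.items():
        partners.setdefault(a, []).append((size, b))
        partners.setdefault(b, []).append((size, a))
    choice: dict[NodeSide, NodeSide | None] = {}
    for side, cand in partners.items():
        cand.sort()
        chosen = None
        for _, other in cand:
            if is_minimal(graph, side, other, sep_set):
                chosen = other
                break
        choice[side] = chosen
    out = []
    for (a, b) in sep:
        if choice.get(a) == b and choice.get(b) == a:
            out.append((a, b))
    return out


def _nested(inner: Snarl, outer: Snarl) -> bool:
    return (
        inner.start.node_id in outer.content
        and inner.end.node_id in outer.content
        and inner.content <= outer.content
    )


def _compatible(s: Snarl, t: Snarl) -> bool:
    """Whether two candidate snarls can coexist in one decomposition:
    properly nested, or disjoint (sharing at most boundary nodes on
    opposite sides)."""
    if _nested(s, t) or _nested(t, s):
        return True
    span_s = set(s.content) | {s.start.node_id, s.end.node_id}
    span_t = set(t.content) | {t.start.node_id, t.end.node_id}
    if s.content & span_t or t.content & span_s:
        return False
    # shared boundary nodes must be attached on distinct sides
    return not ({s.start, s.end} & {t.start, t.end})


def _select_compatible(graph: VariationGraph, candidates: list[Snarl]) -> list[Snarl]:
    """Greedy canonical choice among mutually incompatible candidates.

    The decomposition is not unique: a site of variation can equally be
    viewed from its mirror boundaries, which bound the *rest* of the
    graph. Mirror views betray themselves by enclosing the component's
    dangling chain ends (tips) in their content, or by same-sided
    boundaries; both are deprioritized, then smaller content wins, then
    boundary sides, keeping each candidate compatible with all kept so
    far.
    """
    adj = graph.adjacency()

    def has_tip(s: Snarl) -> bool:
        for nid in s.content:
            if not adj[NodeSide(nid, LEFT)] or not adj[NodeSide(nid, RIGHT)]:
                return True
        return False

    order = sorted(
        candidates,
        key=lambda s: (
            has_tip(s),
            s.start.side == s.end.side,
            len(s.content),
            min(s.start, s.end),
            max(s.start, s.end),
        ),
    )
    kept: list[Snarl] = []
    for s in order:
        if all(_compatible(s, t) for t in kept):
            kept.append(s)
    return kept


def _node_components(graph: VariationGraph) -> dict[int, int]:
    """Connected components over nodes (edges + node integrity)."""
    adj = graph.adjacency()
    comp: dict[int, int] = {}
    cid = 0
    for nid in sorted(graph.sequences):
        if nid in comp:
            continue
        stack = [nid]
        comp[nid] = cid
        while stack:
            x = stack.pop()
            for side in (NodeSide(x, LEFT), NodeSide(x, RIGHT)):
                for t in adj[side]:
                    if t.node_id not in comp:
                        comp[t.node_id] = cid
                        stack.append(t.node_id)
        cid += 1
    return comp


def _assemble_level(
    level_nodes: set[int],
    level_snarls: list[Snarl],
    parent: Snarl | None,
) -> tuple[list[SnarlChain], list[int]]:
    """Chain up one nesting level; returns (chains, orphan node ids)."""
    attach: dict[NodeSide, Snarl] = {}
    dropped: list[Snarl] = []
    for s in sorted(level_snarls, key=lambda s: (min(s.start, s.end), max(s.start, s.end))):
        if s.start in attach or s.end in attach:
            dropped.append(s)  # pathological double-attachment; keep first
            continue
        attach[s.start] = s
        attach[s.end] = s

    visited: set[int] = set()
    chains: list[SnarlChain] = []

    def _trace(start_node: int, entry: int) -> SnarlChain:
        nodes_out: list[OrientedNode] = []
        snarls_out: list[Snarl] = []
        nid, side_in = start_node, entry
        cyclic = False
        while True:
            visited.add(nid)
            nodes_out.append(OrientedNode(nid, FORWARD if side_in == LEFT else REVERSE))
            exit_side = NodeSide(nid, 1 - side_in)
            snarl = attach.get(exit_side)
            if snarl is None:
                break
            other = snarl.end if snarl.start == exit_side else snarl.start
            snarls_out.append(snarl)
            if other.node_id == start_node and other.side == entry:
                cyclic = True
                break
            nid, side_in = other.node_id, other.side
        return SnarlChain(nodes_out, snarls_out, cyclic=cyclic, parent=parent)

    # linear chains start at a node side with no snarl attached
    for nid in sorted(level_nodes):
        if nid in visited:
            continue
        free = [s for s in (LEFT, RIGHT) if NodeSide(nid, s) not in attach]
        if not free:
            continue
        chain = _trace(nid, free[0])
        # canonical direction: lexicographically smaller node-id sequence
        ids = chain.node_ids()
        if ids[::-1] < ids:
            chain = _flip_chain(chain)
        chains.append(chain)

    # what remains are cycles
    for nid in sorted(level_nodes):
        if nid not in visited:
            chains.append(_trace(nid, LEFT))

    orphans = [n for n in sorted(level_nodes) if n not in visited]
    # re-orient snarls so start comes first along the chain
    for chain in chains:
        for i, s in enumerate(chain.snarls):
            upstream_exit = chain.nodes[i].exit_side
            if s.start != upstream_exit:
                s.start, s.end = s.end, s.start
            s.parent_chain = chain
    chains.sort(key=lambda c: c.nodes[0].node_id)
    return chains, orphans


def _flip_chain(chain: SnarlChain) -> SnarlChain:
    return SnarlChain(
        [n.flip() for n in chain.nodes[::-1]],
        chain.snarls[::-1],
        cyclic=chain.cyclic,
        parent=chain.parent,
    )


def decompose(graph: VariationGraph, _bruteforce: bool = False) -> SnarlTree:
    """Compute the canonical snarl tree of a graph.

    Every emitted snarl satisfies the definitional separable+minimal check;
    chains are maximal; the result is deterministic. ``_bruteforce``
    switches candidate enumeration to the quadratic definitional scan
    (useful for cross-checks).
    """
    if _bruteforce:
        sep = _separable_pairs_bruteforce(graph)
    else:
        sep = _separable_pairs_fast(graph)
    minimal = _minimal_pairs(graph, sep)

    candidates = [
        Snarl(a, b, separable_content(graph, a, b)) for a, b in sorted(minimal)
    ]
    snarls = _select_compatible(graph, candidates)

    comp = _node_components(graph)
    by_comp: dict[int, list[Snarl]] = {}
    for s in snarls:
        by_comp.setdefault(comp[s.start.node_id], []).append(s)

    roots: list[SnarlChain] = []

    def _contains(outer: Snarl, inner: Snarl) -> bool:
        return (
            inner.start.node_id in outer.content and inner.end.node_id in outer.content
        )

    def _build(node_set: set[int], snarl_list: list[Snarl], parent: Snarl | None):
        maximal = [
            s
            for s in snarl_list
            if not any(o is not s and _contains(o, s) for o in snarl_list)
        ]
        covered: set[int] = set()
        for s in maximal:
            covered |= s.content
        level_nodes = node_set - covered
        chains, _ = _assemble_level(level_nodes, maximal, parent)
        for s in maximal:
            sub = [t for t in snarl_list if t is not s and _contains(s, t)]
            s.children = _build(set(s.content), sub, s)
        return chains

    comp_ids = sorted(set(comp.values()))
    for cid in comp_ids:
        cnodes = {n for n, c in comp.items() if c == cid}
        roots.extend(_build(cnodes, by_comp.get(cid, []), None))

    node_chain: dict[int, tuple[SnarlChain, int]] = {}
    tree = SnarlTree(graph, roots, node_chain)
    for chain in tree.all_chains():
        for i, n in enumerate(chain.nodes):
            node_chain[n.node_id] = (chain, i)

    # edge partition bookkeeping: find edges no snarl span covers
    spans = [(s, s.span_sides()) for s in tree.all_snarls()]
    for a, b in sorted(graph.edges):
        if not any(a in sp and b in sp for _, sp in spans):
            tree.unassigned_edges.append((a, b))
    return tree


def edge_assignment(tree: SnarlTree):
    """Map each graph edge to the smallest snarl containing it (or None)."""
    spans = sorted(
        ((s, s.span_sides()) for s in tree.all_snarls()),
        key=lambda p: len(p[0].content),
    )
    out = {}
    for a, b in sorted(tree.graph.edges):
        owner = None
        for s, sp in spans:
            if a in sp and b in sp:
                owner = s
                break
        out[(a, b)] = owner
    return out


def check_tree(tree: SnarlTree) -> None:
    """Raise ConsistencyError unless the partition invariants hold."""
    graph = tree.graph
    seen_nodes: list[int] = []
    for chain in tree.all_chains():
        seen_nodes.extend(chain.node_ids())
    if sorted(seen_nodes) != sorted(graph.sequences):
        raise ConsistencyError("node partition violated: each node must sit in exactly one chain")
    assignment = edge_assignment(tree)
    for edge, owner in assignment.items():
        if owner is None and edge not in tree.unassigned_edges:
            raise ConsistencyError(f"edge {edge} not assigned to any snarl")
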