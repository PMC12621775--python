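"""Zip codes, seed ordering and zip-code-tree distance iteration."""

import pytest
from oracles import all_positions, oracle_min_distance

from snarlmap.distance import INF, build_distance_index
from snarlmap.graph import FORWARD, Position
from snarlmap.seeds import Seed
from snarlmap.snarls import decompose
from snarlmap.zipcodes import (
    build_zip_forest,
    compute_zipcode,
    tree_distance_iter,
    zip_sort_key,
)


def mkseed(read_offset, pos, k=3):
    return Seed(read_offset, pos, hash((pos, read_offset)) & 0xFFFF, (), k)


class TestZipCode:
    def test_depth_of_snarl_content_seed(self, G1_index):
        z = compute_zipcode(G1_index, Position(2, FORWARD, 0))
        kinds = [r[0] for r in z.records]
        assert kinds == ["root", "chain", "snarl", "chain", "node"]

    def test_depth_of_top_chain_seed(self, G1_index):
        z = compute_zipcode(G1_index, Position(1, FORWARD, 2))
        kinds = [r[0] for r in z.records]
        assert kinds == ["root", "chain", "node"]

    def test_same_node_zipcodes_differ_only_in_offset(self, G1_index):
        z1 = compute_zipcode(G1_index, Position(4, FORWARD, 0))
        z2 = compute_zipcode(G1_index, Position(4, FORWARD, 2))
        assert z1.records[:-1] == z2.records[:-1]
        assert z1.records[-1] != z2.records[-1]


class TestSortKey:
    def test_same_node_orders_by_offset(self, G1_index):
        k0 = zip_sort_key(compute_zipcode(G1_index, Position(1, FORWARD, 0)))
        k3 = zip_sort_key(compute_zipcode(G1_index, Position(1, FORWARD, 3)))
        assert k0 < k3

    def test_chain_order_across_the_snarl(self, G1_index):
        k1 = zip_sort_key(compute_zipcode(G1_index, Position(1, FORWARD, 0)))
        k2 = zip_sort_key(compute_zipcode(G1_index, Position(2, FORWARD, 0)))
        k4 = zip_sort_key(compute_zipcode(G1_index, Position(4, FORWARD, 0)))
        assert k1 < k2 < k4

    def test_sibling_alleles_rank_deterministically(self, G1_index):
        ka = zip_sort_key(compute_zipcode(G1_index, Position(2, FORWARD, 0)))
        kb = zip_sort_key(compute_zipcode(G1_index, Position(3, FORWARD, 0)))
        assert ka != kb  # one branch consistently first

    @pytest.mark.parametrize("seed", range(5))
    def test_key_order_consistent_with_reachability(self, random_graph, seed):
        """Forward-oriented positions that can reach each other sort in
        reach order (acyclic fixtures)."""
        g = random_graph(seed, max_nodes=15)
        idx = build_distance_index(g, decompose(g))
        pos = [p for p in all_positions(g) if p.orientation == FORWARD]
        keys = {p: zip_sort_key(compute_zipcode(idx, p)) for p in pos}
        for a in pos[::2]:
            for b in pos[::2]:
                if a == b:
                    continue
                d_ab = oracle_min_distance(g, a, b)
                d_ba = oracle_min_distance(g, b, a)
                # one-way reachability implies strict key order (loops can
                # go both ways and carry no order)
                if d_ab < INF and d_ba == INF:
                    assert keys[a] < keys[b], (a, b)


class TestTreeBuild:
    def test_three_seed_fixture(self, G1_index):
        seeds = [
            mkseed(0, Position(1, FORWARD, 3)),
            mkseed(1, Position(2, FORWARD, 0)),
            mkseed(2, Position(4, FORWARD, 0)),
        ]
        forest = build_zip_forest(seeds, G1_index)
        fwd = forest[0]
        assert [o[0].read_offset for o in fwd.occs] == [0, 1, 2]
        assert fwd.dists == [0, 0]
        assert "snarl" in fwd.dump()

    def test_single_seed(self, G1_index):
        forest = build_zip_forest([mkseed(0, Position(1, FORWARD, 0))], G1_index)
        assert len(forest[0]) == 1

    def test_parallel_alleles_present_but_unlinked(self, G1_index):
        seeds = [
            mkseed(0, Position(2, FORWARD, 0)),
            mkseed(1, Position(3, FORWARD, 0)),
        ]
        forest = build_zip_forest(seeds, G1_index)
        fwd = forest[0]
        assert len(fwd) == 2
        assert fwd.dists == [INF]
        for i in range(len(fwd)):
            for j, d in tree_distance_iter(fwd, i):
                raise AssertionError("parallel alleles must never be linked")

    def test_loop_seed_duplicated(self, G3_index):
        seeds = [mkseed(0, Position(2, FORWARD, 0))]
        forest = build_zip_forest(seeds, G3_index)
        fwd = forest[0]
        assert len(fwd) == 2  # two unrolled copies
        preds = list(tree_distance_iter(fwd, 1))
        assert preds == [(0, 2)]  # around the loop: 2 bases strictly between

    def test_deterministic_occurrence_order(self, G1_index):
        seeds1 = [
            mkseed(5, Position(4, FORWARD, 1)),
            mkseed(0, Position(1, FORWARD, 2)),
            mkseed(3, Position(3, FORWARD, 0)),
        ]
        f1 = build_zip_forest(list(seeds1), G1_index)
        f2 = build_zip_forest(list(reversed(seeds1)), G1_index)
        key = lambda f: [(o[0].read_offset, o[0].pos, o[1]) for t in f for o in t.occs]
        assert key(f1) == key(f2)
        assert f1[0].dump() == f2[0].dump()


class TestIterator:
    def test_fig_style_order_and_distances(self, G1_index):
        seeds = [
            mkseed(0, Position(1, FORWARD, 3)),  # seed1, last base before bubble
            mkseed(1, Position(2, FORWARD, 0)),  # seed2 in bubble
            mkseed(2, Position(4, FORWARD, 0)),  # seed3 after bubble
        ]
        forest = build_zip_forest(seeds, G1_index)
        fwd = forest[0]
        got = list(tree_distance_iter(fwd, 2))
        assert got == [(1, 0), (0, 1)]

    def test_first_seed_has_no_predecessors(self, G1_index):
        seeds = [mkseed(0, Position(1, FORWARD, 0)), mkseed(1, Position(4, FORWARD, 0))]
        forest = build_zip_forest(seeds, G1_index)
        assert list(tree_distance_iter(forest[0], 0)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_yielded_distances_are_exact_and_sound(self, random_graph, seed):
        """Every yielded predecessor distance equals the brute-force
        minimum distance; infinite pairs are never yielded."""
        g = random_graph(seed, max_nodes=20)
        idx = build_distance_index(g, decompose(g))
        pos = [p for p in all_positions(g) if p.offset == 0][:14]
        seeds = [mkseed(i, p) for i, p in enumerate(pos)]
        for tree in build_zip_forest(seeds, idx):
            for i in range(len(tree)):
                for j, d in tree_distance_iter(tree, i):
                    a, b = tree.occs[j][0].pos, tree.occs[i][0].pos
                    want = (
                        oracle_min_distance(g, a, b)
                        if (a != b or tree.occs[j][1] == tree.occs[i][1])
                        else oracle_min_distance(g, a, b, same_pos_zero=False)
                    )
                    assert d == want
                    assert d < INF
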