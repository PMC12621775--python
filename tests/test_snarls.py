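"""Snarl decomposition: separability, minimality, chains and nesting."""

import pytest
from oracles import bruteforce_separable_minimal_pairs, definitional_snarl_check

from snarlmap.errors import InvalidPairError
from snarlmap.graph import LEFT, RIGHT, NodeSide, VariationGraph, parse_gfa
from snarlmap.sim import random_variation_graph
from snarlmap.snarls import check_tree, decompose, is_separable, leaf_snarls


class TestIsSeparable:
    def test_bubble_boundaries_separate(self, G1):
        assert is_separable(G1, NodeSide(1, RIGHT), NodeSide(4, LEFT))

    def test_partial_bubble_does_not(self, G1):
        # node 3 escapes to node 4 around the candidate pair
        assert not is_separable(G1, NodeSide(1, RIGHT), NodeSide(2, RIGHT))

    def test_same_node_pair_rejected(self, G1):
        with pytest.raises(InvalidPairError):
            is_separable(G1, NodeSide(1, LEFT), NodeSide(1, RIGHT))


class TestDecompose:
    def test_single_node_graph(self):
        g = VariationGraph()
        g.add_node(1, "ACGT")
        tree = decompose(g)
        assert len(tree.roots) == 1
        assert tree.roots[0].node_ids() == [1]
        assert tree.all_snarls() == []

    def test_g1_bubble(self, G1):
        tree = decompose(G1)
        (root,) = tree.roots
        assert root.node_ids() == [1, 4]
        (snarl,) = root.snarls
        assert {snarl.start, snarl.end} == {NodeSide(1, RIGHT), NodeSide(4, LEFT)}
        assert snarl.content == frozenset({2, 3})

    def test_g2_inversion_contained(self, G2):
        tree = decompose(G2)
        (root,) = tree.roots
        assert root.node_ids() == [1, 3]
        (snarl,) = root.snarls
        assert {snarl.start, snarl.end} == {NodeSide(1, RIGHT), NodeSide(3, LEFT)}
        assert snarl.content == frozenset({2})

    def test_fast_and_bruteforce_enumeration_agree(self, random_graph):
        for seed in range(10):
            g = random_graph(seed, max_nodes=16)
            t1 = decompose(g)
            t2 = decompose(g, _bruteforce=True)
            key = lambda t: sorted(
                (min(s.start, s.end), max(s.start, s.end)) for s in t.all_snarls()
            )
            assert key(t1) == key(t2)


class TestLeafSnarls:
    def test_g1_single_snarl_is_leaf(self, G1):
        tree = decompose(G1)
        assert leaf_snarls(tree) == tree.all_snarls()

    def test_nested_snp_in_insertion(self):
        # insertion branch carrying its own SNP: outer snarl (1..4) with an
        # inner bubble (2..2b) nested inside it
        text = (
            "S\t1\tAAC\nS\t2\tG\nS\t3\tT\nS\t4\tC\nS\t5\tGG\nS\t6\tACT\n"
            "L\t1\t+\t6\t+\t0M\n"  # skip the insertion entirely
            "L\t1\t+\t2\t+\t0M\n"
            "L\t2\t+\t3\t+\t0M\nL\t2\t+\t4\t+\t0M\n"
            "L\t3\t+\t5\t+\t0M\nL\t4\t+\t5\t+\t0M\n"
            "L\t5\t+\t6\t+\t0M\n"
            "P\thap1\t1+,6+\t*\nP\thap2\t1+,2+,3+,5+,6+\t*\nP\thap3\t1+,2+,4+,5+,6+\t*\n"
        )
        g = parse_gfa(text)
        tree = decompose(g)
        leaves = leaf_snarls(tree)
        assert len(leaves) == 1
        assert leaves[0].content == frozenset({3, 4})
        # the outer insertion site is a snarl but not a leaf
        assert len(tree.all_snarls()) == 2

    def test_snarl_free_graph(self):
        g = VariationGraph()
        g.add_node(1, "AC")
        tree = decompose(g)
        assert leaf_snarls(tree) == []


class TestInvariants:
    @pytest.mark.parametrize("seed", range(40))
    def test_every_snarl_passes_definitional_check_and_partitions(
        self, random_graph, seed
    ):
        g = random_graph(seed, max_nodes=40)
        tree = decompose(g)
        for snarl in tree.all_snarls():
            assert definitional_snarl_check(g, snarl), snarl
        check_tree(tree)
        assert not tree.unassigned_edges

    @pytest.mark.parametrize("seed", range(12))
    def test_bruteforce_pairs_are_boundaries_or_incompatible_mirrors(
        self, random_graph, seed
    ):
        """Each definitionally separable+minimal pair either appears as a
        snarl boundary or is a mirror view excluded by the canonical
        compatible-subset choice."""
        from snarlmap.snarls import Snarl, _compatible, separable_content

        g = random_graph(seed, max_nodes=14)
        tree = decompose(g)
        chosen = tree.all_snarls()
        boundary_pairs = {
            (min(s.start, s.end), max(s.start, s.end)) for s in chosen
        }
        for a, b in bruteforce_separable_minimal_pairs(g):
            if (a, b) in boundary_pairs:
                continue
            cand = Snarl(a, b, separable_content(g, a, b))
            assert any(not _compatible(cand, s) for s in chosen), (a, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_relabeling_invariance(self, random_graph, seed):
        g = random_graph(seed, max_nodes=25)
        n = len(g.sequences)
        # relabel node i -> n + 1 - i (order-reversing permutation)
        perm = {nid: n + 1 - nid for nid in g.sequences}
        g2 = VariationGraph()
        for nid, seq in g.sequences.items():
            g2.add_node(perm[nid], seq)
        for a, b in g.edges:
            g2.add_edge(NodeSide(perm[a.node_id], a.side), NodeSide(perm[b.node_id], b.side))
        t1, t2 = decompose(g), decompose(g2)

        def snarl_keys(tree, mapping=None):
            out = set()
            for s in tree.all_snarls():
                x = s.start if mapping is None else NodeSide(mapping[s.start.node_id], s.start.side)
                y = s.end if mapping is None else NodeSide(mapping[s.end.node_id], s.end.side)
                out.add((min(x, y), max(x, y)))
            return out

        assert snarl_keys(t1, perm) == snarl_keys(t2)

    def test_json_dump_is_valid(self, G1):
        import json

        doc = json.loads(decompose(G1).to_json())
        assert doc[0]["nodes"] == [[1, "+"], [4, "+"]]
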