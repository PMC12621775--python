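"""Extension kernels: WFA, local haplotype enumeration, banded graph
alignment, X-drop tails, chain stitching."""

import numpy as np
import pytest
from oracles import enumerate_walk_strings, nw_affine

from snarlmap.align import (
    ExtensionParams,
    Scoring,
    banded_graph_align,
    enumerate_local_haplotypes,
    extend_chain,
    wfa_align,
    xdrop_tail_align,
)
from snarlmap.chain import ChainingParams, chain_anchors
from snarlmap.distance import build_distance_index
from snarlmap.graph import FORWARD, REVERSE, Position, revcomp, walk_sequence
from snarlmap.seeds import SeedingParams, build_minimizer_index, select_seeds
from snarlmap.snarls import decompose
from snarlmap.zipcodes import build_zip_forest

SC = Scoring()


def ops_spans(ops):
    q = sum(l for op, l in ops if op in "=XI")
    t = sum(l for op, l in ops if op in "=XD")
    return q, t


class TestWFA:
    def test_identity(self):
        score, ops = wfa_align("ACGT", "ACGT", SC)
        assert score == 4 * SC.match
        assert ops == [("=", 4)]

    def test_single_deletion(self):
        score, ops = wfa_align("ACGT", "AGT", SC)
        assert score == 3 * SC.match - SC.gap_open - SC.gap_extend

    def test_empty_cases(self):
        assert wfa_align("", "", SC) == (0, [])
        assert wfa_align("AC", "", SC)[1] == [("I", 2)]
        assert wfa_align("", "AC", SC)[1] == [("D", 2)]

    def test_score_budget_failure_is_a_value(self):
        assert wfa_align("AAAA", "TTTT", SC, max_score_gap=3) is None

    @pytest.mark.parametrize("trial", range(150))
    def test_score_equals_full_affine_dp(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 201))
        q = "".join("ACGT"[c] for c in rng.integers(0, 4, n))
        t = []
        for ch in q:
            r = rng.random()
            if r < 0.07:
                continue
            if r < 0.13:
                t.append("ACGT"[rng.integers(0, 4)])
            t.append(ch if rng.random() > 0.08 else "ACGT"[rng.integers(0, 4)])
        t = "".join(t) or "A"
        got = wfa_align(q, t, SC)
        assert got is not None
        score, ops = got
        assert score == nw_affine(q, t, SC)
        assert ops_spans(ops) == (len(q), len(t))
        assert SC.score_ops(ops) == score


class TestEnumerateLocalHaplotypes:
    def test_bubble_gives_both_allele_strings(self, G1):
        res = enumerate_local_haplotypes(
            G1, Position(1, FORWARD, 3), Position(4, FORWARD, 0)
        )
        assert sorted(s for _, s in res) == ["A", "C"]

    def test_adjacent_positions_on_one_node(self, G1):
        res = enumerate_local_haplotypes(
            G1, Position(1, FORWARD, 2), Position(1, FORWARD, 3)
        )
        assert [(len(st), s) for st, s in res] == [(1, "")]

    def test_limit_caps_results(self, G1):
        res = enumerate_local_haplotypes(
            G1, Position(1, FORWARD, 3), Position(4, FORWARD, 0), limit=1
        )
        assert len(res) == 1

    def test_loop_walks_enumerated(self, G3):
        # hapB traverses node 2 twice: both single and double traversals
        res = enumerate_local_haplotypes(
            G3, Position(1, FORWARD, 2), Position(3, FORWARD, 0)
        )
        strings = sorted(s for _, s in res)
        assert "CGA" in strings and "CGACGA" in strings

    def test_reverse_orientation_walks(self, G2):
        res = enumerate_local_haplotypes(
            G2, Position(1, FORWARD, 2), Position(3, FORWARD, 0)
        )
        assert sorted(s for _, s in res) == [revcomp("TTG"), "TTG"]


class TestBandedGraphAlign:
    @pytest.mark.parametrize(
        "query", ["A", "C", "AC", "", "G"]
    )
    def test_full_band_matches_walk_enumeration_oracle(self, G1, query):
        frm, to = Position(1, FORWARD, 3), Position(4, FORWARD, 0)
        res = banded_graph_align(query, G1, frm, to, band_width=16, scoring=SC)
        want = max(
            nw_affine(query, s, SC)
            for s in enumerate_walk_strings(G1, frm, to)
        )
        assert res is not None and res.score == want

    def test_inversion_graph_oracle(self, G2):
        frm, to = Position(1, FORWARD, 2), Position(3, FORWARD, 0)
        for query in ("TTG", "CAA", "TTGA", "CA"):
            res = banded_graph_align(query, G2, frm, to, band_width=16, scoring=SC)
            want = max(
                nw_affine(query, s, SC) for s in enumerate_walk_strings(G2, frm, to)
            )
            assert res.score == want

    def test_query_equal_to_unique_walk(self, G2):
        res = banded_graph_align(
            "AT", G2, Position(1, FORWARD, 0), Position(2, FORWARD, 0), 8, SC
        )
        assert res.ops == [("=", 2)]
        assert res.score == 2 * SC.match

    def test_empty_query_adjacent_positions(self, G1):
        res = banded_graph_align(
            "", G1, Position(2, FORWARD, 0), Position(4, FORWARD, 0), 8, SC
        )
        assert res.score == 0 and res.ops == []

    def test_no_walk_within_band_fails(self, G1):
        # query far longer than any walk between the positions, tiny band
        res = banded_graph_align(
            "A" * 50, G1, Position(1, FORWARD, 3), Position(4, FORWARD, 0), 2, SC
        )
        assert res is None

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graph_full_band_oracle(self, seed):
        # loop-free graphs so the walk enumeration oracle is exhaustive
        from snarlmap.sim import GraphSimParams, simulate_graph

        g = simulate_graph(
            GraphSimParams(
                backbone_len=60,
                snp_rate=0.06,
                indel_rate=0.02,
                inversion_count=1,
                inversion_len=8,
                haplotype_count=3,
                seed=seed,
            )
        )
        rng = np.random.default_rng(seed)
        nodes = sorted(g.sequences)
        frm = Position(nodes[0], FORWARD, 0)
        to = Position(nodes[-1], FORWARD, g.node_len(nodes[-1]) - 1)
        strings = enumerate_walk_strings(g, frm, to, max_len=100, max_walks=5000)
        assert strings and len(strings) < 5000  # enumeration is complete
        pick = strings[int(rng.integers(len(strings)))]
        # mutate the picked walk string into a query
        q = "".join(
            c if rng.random() > 0.15 else "ACGT"[rng.integers(0, 4)] for c in pick
        )
        res = banded_graph_align(q, g, frm, to, band_width=len(q) + 40, scoring=SC)
        want = max(nw_affine(q, s, SC) for s in strings)
        assert res is not None and res.score == want


class TestXDrop:
    def test_matching_tail_fully_aligned(self, G1):
        res = xdrop_tail_align("AACA", G1, Position(1, FORWARD, 3), 1, 100, SC)
        assert res.right_clip == 0 and res.ops == [("=", 4)]

    def test_garbage_tail_clipped(self, G1):
        res = xdrop_tail_align("GGGGGGGG", G1, Position(1, FORWARD, 3), 1, 20, SC)
        assert res.right_clip == 8 and res.score == 0

    def test_empty_tail(self, G1):
        res = xdrop_tail_align("", G1, Position(1, FORWARD, 3), 1, 100, SC)
        assert res.ops == [] and res.score == 0

    def test_left_extension_mirrors(self, G1):
        res = xdrop_tail_align("GATTC", G1, Position(4, FORWARD, 0), -1, 100, SC)
        assert res.left_clip == 0
        assert res.ops == [("=", 5)]
        assert res.spans[0][0].node_id == 1


def _best_extension(graph, read, k, w):
    tree = decompose(graph)
    index = build_distance_index(graph, tree)
    sp = SeedingParams(k=k, w=w)
    midx = build_minimizer_index(graph, sp)
    seeds = select_seeds(read, midx, sp)
    forest = build_zip_forest(seeds, index)
    params = ChainingParams()
    best = None
    for t in forest:
        for c in chain_anchors(t, params):
            if best is None or c.score > best.score:
                best = c
    assert best is not None
    return extend_chain(read, best, graph, index, ExtensionParams(), None)


class TestExtendChain:
    def test_perfect_g1_read(self, G1):
        read = walk_sequence(G1, G1.walks[0])  # GATTAACA
        path = _best_extension(G1, read, k=3, w=1)
        assert [s.node_id for s in path.steps] == [1, 2, 4]
        assert all(o == FORWARD for _, o in path.steps)
        assert path.ops == [("=", len(read))]
        assert path.score == len(read) * SC.match
        assert path.left_clip == path.right_clip == 0

    def test_snp_read_picks_matching_allele(self, G1):
        read = walk_sequence(G1, G1.walks[1])  # hapB via node 3
        path = _best_extension(G1, read, k=3, w=1)
        assert [s.node_id for s in path.steps] == [1, 3, 4]
        assert path.ops == [("=", len(read))]

    def test_inversion_read_uses_reverse_step(self, G2):
        hapB = next(w for w in G2.walks if w.name == "hapB")
        read = walk_sequence(G2, hapB)
        path = _best_extension(G2, read, k=3, w=1)
        assert (2, REVERSE) in [(s.node_id, s.orientation) for s in path.steps]
        assert path.ops == [("=", len(read))]

    def test_score_recomputes_from_ops(self, random_graph):
        g = random_graph(7, max_nodes=40)
        read = walk_sequence(g, g.haplotype_walks()[0])[5:80]
        path = _best_extension(g, read, k=7, w=3)
        assert SC.score_ops(path.ops) == path.score
        # read accounting: ops + clips cover the read exactly
        assert path.read_span + path.left_clip + path.right_clip == len(read)
        # walk accounting: ops consume exactly the spanned graph bases
        assert path.walk_span == sum(hi - lo for _, lo, hi in path.spans)
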