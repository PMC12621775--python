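"""Synthetic pangenome and read generation, and mapping evaluation."""

import pytest

from snarlmap.errors import EvaluationError, GenerationError
from snarlmap.graph import parse_gfa, walk_sequence, write_gfa
from snarlmap.sim import (
    EvalSummary,
    GraphSimParams,
    ReadSimParams,
    TruthRecord,
    error_preset,
    evaluate_mappings,
    simulate_graph,
    simulate_reads,
    write_fastq,
)
from snarlmap.snarls import decompose


class TestSimulateGraph:
    def test_no_events_gives_single_node_chain(self):
        g = simulate_graph(
            GraphSimParams(backbone_len=200, snp_rate=0, indel_rate=0, seed=1)
        )
        assert len(g.sequences) == 1
        tree = decompose(g)
        assert tree.all_snarls() == []
        seqs = {walk_sequence(g, w) for w in g.walks}
        assert len(seqs) == 1  # all haplotypes identical

    def test_one_snp_gives_one_bubble_snarl(self):
        g = simulate_graph(
            GraphSimParams(backbone_len=100, snp_rate=0, indel_rate=0, seed=2)
        )
        # rebuild with exactly one SNP by raising the rate until one lands
        for seed in range(100):
            g = simulate_graph(
                GraphSimParams(backbone_len=60, snp_rate=0.02, indel_rate=0, seed=seed)
            )
            if len(g.sequences) == 4:  # left, ref, alt, right
                break
        else:
            pytest.fail("no single-SNP graph produced")
        tree = decompose(g)
        snarls = tree.all_snarls()
        assert len(snarls) == 1
        assert len(snarls[0].content) == 2

    def test_determinism_byte_identical_gfa(self):
        p = GraphSimParams(
            backbone_len=500,
            snp_rate=0.01,
            indel_rate=0.002,
            inversion_count=1,
            duplication_count=1,
            inversion_len=30,
            duplication_len=30,
            seed=9,
        )
        assert write_gfa(simulate_graph(p)) == write_gfa(simulate_graph(p))

    def test_invalid_rate_rejected(self):
        with pytest.raises(GenerationError):
            simulate_graph(GraphSimParams(snp_rate=1.5))

    def test_impossible_event_placement_rejected(self):
        with pytest.raises(GenerationError):
            simulate_graph(
                GraphSimParams(backbone_len=50, inversion_count=5, inversion_len=30)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_generated_graphs_validate_and_decompose(self, random_graph, seed):
        g = random_graph(seed, max_nodes=60)
        g.validate()  # walks, edges, sequences all consistent
        tree = decompose(g)
        got = sorted(n for c in tree.all_chains() for n in c.node_ids())
        assert got == sorted(g.sequences)

    def test_round_trips_through_gfa(self):
        p = GraphSimParams(backbone_len=300, snp_rate=0.01, seed=4)
        g = simulate_graph(p)
        g2 = parse_gfa(write_gfa(g))
        assert g2.sequences == g.sequences
        assert len(g2.reference_walks()) == 1


class TestSimulateReads:
    @pytest.fixture()
    def graph(self):
        return simulate_graph(
            GraphSimParams(backbone_len=3000, snp_rate=0.005, seed=5, haplotype_count=3)
        )

    def test_zero_error_reads_are_exact_substrings(self, graph):
        rp = ReadSimParams(
            read_len_min=100, read_len_max=300, count=20, seed=1,
            sub_rate=0, ins_rate=0, del_rate=0,
        )
        reads, truth = simulate_reads(graph, graph.haplotype_walks(), rp)
        seqs = {w.name: walk_sequence(graph, w) for w in graph.haplotype_walks()}
        from snarlmap.graph import revcomp

        for (name, seq, _), t in zip(reads, truth):
            frag = seqs[t.haplotype][t.hap_start : t.hap_end]
            if t.strand == "-":
                frag = revcomp(frag)
            assert seq == frag

    def test_substitution_rate_recovered(self, graph):
        rp = ReadSimParams(
            read_len_min=2000, read_len_max=2500, count=10, seed=2,
            sub_rate=0.05, ins_rate=0, del_rate=0,
        )
        reads, truth = simulate_reads(graph, graph.haplotype_walks(), rp)
        seqs = {w.name: walk_sequence(graph, w) for w in graph.haplotype_walks()}
        from snarlmap.graph import revcomp

        mism = total = 0
        for (name, seq, _), t in zip(reads, truth):
            frag = seqs[t.haplotype][t.hap_start : t.hap_end]
            if t.strand == "-":
                frag = revcomp(frag)
            mism += sum(a != b for a, b in zip(seq, frag))
            total += len(frag)
        assert total > 10_000
        assert abs(mism / total - 0.05) < 0.01

    def test_same_seed_identical_fastq(self, graph):
        rp = ReadSimParams(read_len_min=100, read_len_max=200, count=10, seed=7)
        r1, _ = simulate_reads(graph, graph.haplotype_walks(), rp)
        r2, _ = simulate_reads(graph, graph.haplotype_walks(), rp)
        assert write_fastq(r1) == write_fastq(r2)

    def test_presets(self):
        assert error_preset("hifi")["sub_rate"] < error_preset("ont")["sub_rate"]
        with pytest.raises(GenerationError):
            error_preset("nanopore9")

    def test_truth_tsv_round_trip(self, graph):
        rp = ReadSimParams(read_len_min=100, read_len_max=200, count=5, seed=3)
        _, truth = simulate_reads(graph, graph.haplotype_walks(), rp)
        for t in truth:
            assert TruthRecord.from_tsv(t.to_tsv()) == t


class TestEvaluateMappings:
    def _perfect_gaf(self, graph, mapper, reads):
        from snarlmap.mapper import write_gaf

        alns = []
        for name, seq, _ in reads:
            alns.extend(mapper.map_read(name, seq))
        return write_gaf(alns, graph=graph)

    def test_perfect_output_all_correct(self, G1):
        from snarlmap.mapper import Mapper, MapperParams
        from snarlmap.seeds import SeedingParams

        mapper = Mapper(G1, MapperParams(seeding=SeedingParams(k=3, w=1)))
        hap = G1.walks[0]
        reads = [("r0", walk_sequence(G1, hap), "I" * 8)]
        truth = [TruthRecord("r0", "hapA", 0, 8, "+", [(1, 0, 4), (2, 0, 1), (4, 0, 3)])]
        summary = evaluate_mappings(self._perfect_gaf(G1, mapper, reads), truth, G1)
        assert summary.counts() == (1, 0, 0)

    def test_shifted_interval_counted_incorrect(self, G1):
        gaf = "r0\t8\t0\t8\t+\t>1>2>4\t8\t0\t8\t8\t8\t60\tAS:i:8\ttp:A:P\n"
        truth = [TruthRecord("r0", "hapA", 0, 8, "+", [(9, 0, 8)])]
        G1.add_node(9, "ACGTACGT")
        summary = evaluate_mappings(gaf, truth, G1)
        assert summary.counts() == (0, 1, 0)

    def test_known_number_of_wrong_placements(self, G1):
        # three records point at the wrong allele node entirely
        lines = []
        truth = []
        for i in range(5):
            wrong = i < 3
            path = ">3" if wrong else ">2"
            lines.append(f"r{i}\t1\t0\t1\t+\t{path}\t1\t0\t1\t1\t1\t60\tAS:i:1\ttp:A:P")
            truth.append(TruthRecord(f"r{i}", "hapA", 4, 5, "+", [(2, 0, 1)]))
        summary = evaluate_mappings("\n".join(lines) + "\n", truth, G1)
        assert summary.counts() == (2, 3, 0)

    def test_unknown_read_name_is_an_error(self, G1):
        gaf = "ghost\t1\t0\t1\t+\t>2\t1\t0\t1\t1\t1\t60\n"
        with pytest.raises(EvaluationError):
            evaluate_mappings(gaf, [], G1)

    def test_missing_reads_counted_unmapped(self, G1):
        truth = [TruthRecord("r0", "hapA", 0, 8, "+", [(1, 0, 4)])]
        summary = evaluate_mappings("", truth, G1)
        assert summary.counts() == (0, 0, 1)

    def test_roc_tsv_shape(self):
        summary = EvalSummary({60: [10, 1], 30: [5, 2]}, 3, 0.5)
        text = summary.roc_tsv()
        lines = text.strip().splitlines()
        assert lines[0].startswith("mapq\t")
        assert lines[1].split("\t")[0] == "60"
        assert lines[-1].startswith("unmapped\t3")
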