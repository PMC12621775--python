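"""End-to-end mapping, MAPQ and GAF serialization."""

import io

import numpy as np
import pytest

from snarlmap.errors import SnarlmapError
from snarlmap.graph import FORWARD, REVERSE, revcomp, walk_sequence
from snarlmap.mapper import (
    Mapper,
    MapperParams,
    compute_mapq,
    parse_gaf,
    write_gaf,
)
from snarlmap.seeds import SeedingParams


def toy_mapper(graph, k=3, w=1):
    return Mapper(graph, MapperParams(seeding=SeedingParams(k=k, w=w)))


class TestMapRead:
    def test_error_free_read_maps_perfectly(self, G1):
        mapper = toy_mapper(G1)
        read = walk_sequence(G1, G1.walks[0])
        (aln,) = mapper.map_read("r", read)
        assert [s.node_id for s in aln.path.steps] == [1, 2, 4]
        assert aln.read_start == 0 and aln.read_end == len(read)
        assert aln.mapq >= 0

    def test_reverse_strand_read(self, G1):
        mapper = toy_mapper(G1)
        read = revcomp(walk_sequence(G1, G1.walks[0]))
        (aln,) = mapper.map_read("r", read)
        assert aln.path.matches() == len(read)

    def test_unrelated_read_is_unmapped(self, G1):
        mapper = toy_mapper(G1)
        # no 3-mer of this read occurs in G1's haplotypes
        assert mapper.map_read("r", "GGGGGGGGGGGG") == []
        assert mapper.stats["unmapped"] == 1

    def test_loop_read_visits_node_twice(self, G3):
        mapper = toy_mapper(G3)
        hapB = next(w for w in G3.walks if w.name == "hapB")
        read = walk_sequence(G3, hapB)  # traverses node 2 twice
        (aln,) = mapper.map_read("r", read)
        visits = [s.node_id for s in aln.path.steps]
        assert visits.count(2) == 2
        assert aln.path.matches() == len(read)


class TestComputeMapq:
    def test_no_secondary_gives_cap(self):
        assert compute_mapq(100, None, 0, 100) == 60

    def test_equal_scores_give_zero(self):
        assert compute_mapq(50, 50, 0, 100) == 0

    def test_formula_value(self):
        assert compute_mapq(100, 50, 0, 100) == 30

    def test_primary_below_secondary_is_an_error(self):
        with pytest.raises(SnarlmapError):
            compute_mapq(10, 20, 0, 100)

    def test_clamped_to_range(self):
        for p, s in [(100, 0), (100, 99), (1, 0)]:
            assert 0 <= compute_mapq(p, s, 0, 100) <= 60


class TestGAF:
    def test_path_column_forward(self, G1):
        mapper = toy_mapper(G1)
        read = walk_sequence(G1, G1.walks[0])
        alns = mapper.map_read("r", read)
        gaf = write_gaf(alns, graph=G1, reads={"r": read})
        fields = gaf.strip().split("\t")
        assert fields[5] == ">1>2>4"
        assert fields[1] == str(len(read))
        assert "cs:Z:" + f":{len(read)}" in gaf

    def test_inversion_path_glyph(self, G2):
        mapper = toy_mapper(G2)
        hapB = next(w for w in G2.walks if w.name == "hapB")
        gaf = write_gaf(mapper.map_read("r", walk_sequence(G2, hapB)), graph=G2)
        assert "<2" in gaf.split("\t")[5]

    def test_unmapped_read_emits_no_record(self, G1):
        mapper = toy_mapper(G1)
        assert write_gaf(mapper.map_read("r", "GGGGGGGGGG"), graph=G1) == ""

    def test_round_trip(self, G1):
        mapper = toy_mapper(G1)
        read = walk_sequence(G1, G1.walks[1])
        alns = mapper.map_read("r", read)
        gaf = write_gaf(alns, graph=G1, reads={"r": read})
        (rec,) = parse_gaf(io.StringIO(gaf))
        aln = alns[0]
        assert rec.name == "r"
        assert rec.steps == aln.path.steps
        assert (rec.qstart, rec.qend) == (aln.read_start, aln.read_end)
        assert rec.pstart == aln.path.start_offset
        assert rec.pend - rec.pstart == aln.path.walk_span
        assert rec.matches == aln.path.matches()
        assert rec.mapq == aln.mapq
        assert rec.score == aln.score

    def test_determinism_byte_identical(self, G1):
        read = walk_sequence(G1, G1.walks[0])
        outs = []
        for _ in range(2):
            mapper = toy_mapper(G1)
            outs.append(write_gaf(mapper.map_read("r", read), graph=G1, reads={"r": read}))
        assert outs[0] == outs[1]


@pytest.fixture(scope="module")
def synthetic_pipeline():
    from snarlmap.sim import (
        GraphSimParams,
        ReadSimParams,
        error_preset,
        simulate_graph,
        simulate_reads,
    )

    g = simulate_graph(
        GraphSimParams(
            backbone_len=8000,
            snp_rate=0.002,
            indel_rate=0.0004,
            inversion_count=1,
            duplication_count=1,
            inversion_len=60,
            duplication_len=60,
            haplotype_count=6,
            seed=21,
        )
    )
    mapper = Mapper(g, MapperParams(seeding=SeedingParams(k=21, w=8)))
    rp = ReadSimParams(
        read_len_min=400, read_len_max=1500, count=25, seed=2, **error_preset("ont")
    )
    reads, truth = simulate_reads(g, g.haplotype_walks(), rp)
    return g, mapper, reads, truth


class TestPipelineOnSyntheticGraph:
    def test_most_reads_correct(self, synthetic_pipeline):
        from snarlmap.sim import evaluate_mappings

        g, mapper, reads, truth = synthetic_pipeline
        alns = []
        for name, seq, _ in reads:
            alns.extend(mapper.map_read(name, seq))
        summary = evaluate_mappings(write_gaf(alns, graph=g), truth, g)
        correct, incorrect, unmapped = summary.counts()
        assert correct >= 0.9 * len(reads)

    def test_secondary_alignments_flagged(self, synthetic_pipeline):
        g, mapper, reads, truth = synthetic_pipeline
        mapper.params.max_alignments = 3
        try:
            for name, seq, _ in reads[:5]:
                alns = mapper.map_read(name, seq)
                if len(alns) > 1:
                    assert alns[0].secondary is False
                    assert all(a.secondary for a in alns[1:])
                    assert all(a.score <= alns[0].score for a in alns[1:])
        finally:
            mapper.params.max_alignments = 1
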