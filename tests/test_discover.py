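"""Discovery-read selection, exact mapping, clustering, extension, merging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirquest.discover import (
    Cluster,
    CandidateLocus,
    MappedRead,
    assign_genomic_context,
    cluster_by_position,
    extend_cluster,
    map_reads_exact,
    merge_adjacent_candidates,
    select_discovery_reads,
    two_arm_reads,
)
from mirquest.io import read_gff3, revcomp, write_gff3
from mirquest.quantify import ReadRecord
from mirquest.simulate import plant_hairpin
from mirquest.structure import fold_nussinov
from oracles import union_find_clusters
from conftest import random_seq


def read(seq: str, count: int = 20, rid: str = "r1") -> ReadRecord:
    return ReadRecord(rid, seq, count, "pooled")


class TestSelectDiscoveryReads:
    @pytest.mark.parametrize(
        "length,copies,kept",
        [
            (22, 50, True),
            (35, 50, False),   # must be shorter than 35 nt
            (34, 10, True),    # inclusive copy threshold
            (22, 3, False),
            (22, 10, True),
        ],
    )
    def test_length_and_copy_rules(self, length, copies, kept):
        r = read("A" * length, copies)
        assert (r in select_discovery_reads([r])) is kept

    def test_strict_mode_excludes_exact_threshold(self):
        r = read("A" * 22, 10)
        assert select_discovery_reads([r], inclusive=False) == []
        assert select_discovery_reads([read("A" * 22, 11)], inclusive=False)


class TestMapReadsExact:
    def test_planted_read_maps_once(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": random_seq(rng, 5000)}
        seq = genome["chr1"][1000:1022]
        placements, log = map_reads_exact([read(seq)], genome)
        assert len(placements) == 1
        mr = placements[0]
        assert (mr.start, mr.end, mr.strand) == (1000, 1022, "+")
        assert log.empty

    def test_absent_read_logged(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": random_seq(rng, 2000)}
        placements, log = map_reads_exact([read("ACGT" * 6)], genome)
        assert placements == []
        assert list(log.reason) == ["unplaced"]

    def test_minus_strand_identity(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": random_seq(rng, 5000)}
        seq = revcomp(genome["chr1"][2000:2022])
        placements, _ = map_reads_exact([read(seq)], genome)
        assert len(placements) == 1
        mr = placements[0]
        assert mr.strand == "-"
        assert revcomp(genome["chr1"][mr.start:mr.end]) == seq

    def test_multimapper_dropped(self):
        unit = "ACGTGGCCTTAAGGCCAAGGTT"
        genome = {"chr1": ("N" * 10).join([unit] * 7)}
        placements, log = map_reads_exact([read(unit)], genome, max_loci=5)
        assert placements == []
        assert list(log.reason) == ["multimapped"]


class TestClusterByPosition:
    def _mapped(self, positions, length=22, strand="+"):
        return [
            MappedRead(read("A" * length, rid=f"r{i}"), "chr1", p, p + length, strand)
            for i, p in enumerate(positions)
        ]

    def test_identical_loci_one_cluster(self):
        clusters = cluster_by_position(self._mapped([100, 100]))
        assert len(clusters) == 1 and len(clusters[0].reads) == 2

    def test_distant_reads_two_clusters(self):
        clusters = cluster_by_position(self._mapped([100, 1100]))
        assert len(clusters) == 2

    def test_transitive_chaining_matches_union_find(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            starts = sorted(int(rng.integers(0, 600)) for _ in range(12))
            mapped = self._mapped(starts)
            clusters = cluster_by_position(mapped, max_gap=10)
            got = sorted(
                frozenset(mapped.index(mr) for mr in c.reads) for c in clusters
            )
            expected = union_find_clusters([(m.start, m.end) for m in mapped], max_gap=10)
            assert got == expected

    def test_small_gap_chain_is_one_cluster(self):
        # a-b-c with 5 nt gaps: transitively one cluster
        clusters = cluster_by_position(self._mapped([100, 127, 154]), max_gap=10)
        assert len(clusters) == 1 and len(clusters[0].reads) == 3

    def test_strands_never_mix(self):
        mapped = self._mapped([100]) + self._mapped([105], strand="-")
        clusters = cluster_by_position(mapped)
        assert len(clusters) == 2

    def test_idempotent(self):
        mapped = self._mapped([100, 108, 140])
        once = cluster_by_position(mapped, max_gap=10)
        again = cluster_by_position(
            [mr for c in once for mr in c.reads], max_gap=10
        )
        assert [(c.start, c.end, len(c.reads)) for c in once] == [
            (c.start, c.end, len(c.reads)) for c in again
        ]


class TestExtendCluster:
    def _genome(self, n=5000, seed=3):
        return {"chr1": random_seq(np.random.default_rng(seed), n)}

    def test_midgenome_22nt_read_gives_222nt_offset_100(self):
        genome = self._genome()
        seq = genome["chr1"][2000:2022]
        cluster = Cluster("chr1", "+", 2000, 2022, [MappedRead(read(seq), "chr1", 2000, 2022, "+")])
        cand = extend_cluster(cluster, genome, flank=100)
        assert len(cand.precursor_sequence) == 222
        assert cand.reads[0][1] == 100

    def test_left_edge_clamps_flank_and_offset(self):
        genome = self._genome()
        seq = genome["chr1"][40:62]
        cluster = Cluster("chr1", "+", 40, 62, [MappedRead(read(seq), "chr1", 40, 62, "+")])
        cand = extend_cluster(cluster, genome, flank=100)
        assert cand.start == 0
        assert cand.reads[0][1] == 40
        assert len(cand.precursor_sequence) == 162

    def test_minus_strand_precursor_is_reverse_complement(self):
        genome = self._genome()
        plus_seq = genome["chr1"][2000:2022]
        minus_read = revcomp(plus_seq)
        cluster = Cluster("chr1", "-", 2000, 2022, [MappedRead(read(minus_read), "chr1", 2000, 2022, "-")])
        cand = extend_cluster(cluster, genome, flank=100)
        assert cand.precursor_sequence == revcomp(genome["chr1"][1900:2122])
        off = cand.reads[0][1]
        assert cand.precursor_sequence[off:off + 22] == minus_read

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            extend_cluster(Cluster("chr1", "+", 0, 0, []), self._genome())


def build_two_arm_case(loop: int = 14, seed: int = 12):
    """Plant one hairpin and return genome plus mature/star read records."""
    rng = np.random.default_rng(seed)
    genome = random_seq(rng, 4000)
    mature = random_seq(rng, 21)
    genome, row = plant_hairpin(genome, mature, loop, 1800, "+", 0.0, rng)
    star = genome[row["star_start"]:row["star_end"]]
    g = {"chr1": genome}
    reads = [read(mature, rid="mat"), read(star, rid="star")]
    return g, row, reads


class TestMergeAdjacentCandidates:
    def _candidates(self, loop, seed=12, max_gap=10):
        g, row, reads = build_two_arm_case(loop, seed)
        placements, _ = map_reads_exact(reads, g)
        clusters = cluster_by_position(placements, max_gap=max_gap)
        return g, [
            extend_cluster(c, g, candidate_id=f"cand{i + 1}")
            for i, c in enumerate(clusters)
        ]

    def test_arm_clusters_merge_into_one_candidate(self):
        g, cands = self._candidates(loop=14)  # loop > max_gap: two clusters
        assert len(cands) == 2
        merged = merge_adjacent_candidates(cands, g, max_separation=50)
        assert len(merged) == 1
        assert len(merged[0].reads) == 2
        structure = fold_nussinov(merged[0].precursor_sequence)
        assert two_arm_reads(merged[0], structure)

    def test_distant_candidates_untouched(self):
        rng = np.random.default_rng(5)
        genome = {"chr1": random_seq(rng, 30_000)}
        cands = []
        for i, pos in enumerate((2000, 12_000)):
            seq = genome["chr1"][pos:pos + 22]
            cluster = Cluster("chr1", "+", pos, pos + 22, [MappedRead(read(seq, rid=f"r{i}"), "chr1", pos, pos + 22, "+")])
            cands.append(extend_cluster(cluster, genome, candidate_id=f"cand{i}"))
        merged = merge_adjacent_candidates(cands, genome)
        assert [c.candidate_id for c in merged] == ["cand0", "cand1"]

    def test_same_arm_neighbours_not_merged(self):
        """Two clusters both on the 5' arm side of unrelated sequence stay separate."""
        rng = np.random.default_rng(8)
        genome = {"chr1": random_seq(rng, 8000)}
        reads_ = []
        for i, pos in enumerate((3000, 3030)):
            seq = genome["chr1"][pos:pos + 20]
            reads_.append(MappedRead(read(seq, rid=f"r{i}"), "chr1", pos, pos + 20, "+"))
        cands = [
            extend_cluster(Cluster("chr1", "+", mr.start, mr.end, [mr]), genome, candidate_id=f"cand{i}")
            for i, mr in enumerate(reads_)
        ]
        merged = merge_adjacent_candidates(cands, genome)
        # random sequence: the two reads do not pair with each other
        assert len(merged) == 2

    def test_merging_is_idempotent(self):
        g, cands = self._candidates(loop=14)
        once = merge_adjacent_candidates(cands, g)
        twice = merge_adjacent_candidates(once, g)
        assert [(c.candidate_id, c.start, c.end) for c in once] == [
            (c.candidate_id, c.start, c.end) for c in twice
        ]


class TestGenomicContext:
    def _annotation(self):
        return pd.DataFrame(
            [
                {"seqid": "chr1", "source": "t", "type": "gene", "start0": 1000, "end0": 3000,
                 "score": ".", "strand": "+", "phase": ".", "attributes": "ID=g1"},
                {"seqid": "chr1", "source": "t", "type": "exon", "start0": 1000, "end0": 1200,
                 "score": ".", "strand": "+", "phase": ".", "attributes": "ID=e1"},
            ]
        )

    def _cand(self, start, end, strand="+"):
        return CandidateLocus("c1", "chr1", start, end, strand, "A" * (end - start), [])

    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (1100, 1150, "+", "exon"),
            (1500, 1600, "+", "intron"),
            (5000, 5100, "+", "intergenic"),
            (1100, 1150, "-", "intergenic"),  # strand-aware
        ],
    )
    def test_priority_and_strand(self, start, end, strand, expected):
        assert assign_genomic_context(self._cand(start, end, strand), self._annotation()) == expected


class TestGff3RoundTrip:
    def test_intervals_survive_export_import(self, tmp_path):
        feats = pd.DataFrame(
            [
                {"seqid": "chr1", "source": "mirquest", "type": "miRNA_candidate",
                 "start0": 0, "end0": 222, "score": ".", "strand": "+", "phase": ".",
                 "attributes": "ID=cand1"},
                {"seqid": "chr1", "source": "mirquest", "type": "miRNA_candidate",
                 "start0": 1517, "end0": 1739, "score": ".", "strand": "-", "phase": ".",
                 "attributes": "ID=cand2"},
            ]
        )
        path = tmp_path / "cands.gff3"
        write_gff3(feats, path)
        back = read_gff3(path)
        assert list(back.start0) == [0, 1517]
        assert list(back.end0) == [222, 1739]
        assert list(back.start) == [1, 1518]  # 1-based inclusive on disk
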