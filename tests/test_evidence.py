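"""Similarity search, false-positive exclusion, adapters, ab-initio score,
mature proposals and verdict integration."""

from __future__ import annotations

import numpy as np
import pytest

from mirquest.discover import CandidateLocus, MappedRead
from mirquest.evidence import (
    ABINITIO_CUTOFF,
    FamilyHit,
    NcRNARecord,
    SimilarityHit,
    exclude_false_positives,
    integrate_evidence,
    parse_hhmmir_scores,
    parse_infernal_tblout,
    propose_mature,
    score_abinitio,
    similarity_search,
    smith_waterman,
)
from mirquest.io import revcomp
from mirquest.quantify import ReadRecord
from mirquest.simulate import plant_hairpin
from mirquest.structure import fold_nussinov, hairpin_features, parse_dotbracket
from oracles import sw_retention_oracle
from conftest import random_seq


def candidate(seq: str, reads=(), cid="cand1", context="intergenic", chrom="chr1", strand="+"):
    return CandidateLocus(cid, chrom, 0, len(seq), strand, seq, list(reads), context)


def mk_read(seq, offset, rid="r1"):
    rr = ReadRecord(rid, seq, 20, "pooled")
    return (MappedRead(rr, "chr1", offset, offset + len(seq), "+"), offset)


class TestSimilaritySearch:
    def _db(self, *records):
        return [NcRNARecord(f"db{i}", seq, rtype) for i, (seq, rtype) in enumerate(records)]

    def test_exact_embedded_subject_fully_covered(self):
        rng = np.random.default_rng(1)
        subject = random_seq(rng, 22)
        query = random_seq(rng, 100) + subject + random_seq(rng, 100)
        hits = similarity_search(query, self._db((subject, "miRNA")), candidate_id="c")
        assert len(hits) == 1
        assert hits[0].subject_coverage == 100.0
        assert hits[0].identity == 100.0
        assert hits[0].query_coverage < 80.0  # retained through the subject side

    def test_low_identity_rejected(self):
        rng = np.random.default_rng(2)
        subject = random_seq(rng, 30)
        mutated = list(subject)
        for pos in range(0, 30, 3):  # 33% substitutions -> ~70% identity
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        query = random_seq(rng, 60) + "".join(mutated) + random_seq(rng, 60)
        hits = similarity_search(query, self._db((subject, "miRNA")), candidate_id="c")
        assert hits == []

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            similarity_search("ACGT" * 30, [], candidate_id="c")

    def test_agrees_with_exhaustive_sw_oracle(self):
        """Seeded search reproduces exhaustive local-alignment retention."""
        rng = np.random.default_rng(33)
        n_checked = 0
        for trial in range(120):
            subject = random_seq(rng, int(rng.integers(18, 50)))
            kind = trial % 3
            if kind == 0:  # unrelated
                query = random_seq(rng, 250)
            elif kind == 1:  # planted clean or near-clean copy
                copy = list(subject)
                for _ in range(int(rng.integers(0, 2))):
                    copy[int(rng.integers(len(copy)))] = "ACGT"[int(rng.integers(4))]
                query = random_seq(rng, 100) + "".join(copy) + random_seq(rng, 100)
            else:  # heavily mutated copy
                copy = list(subject)
                for pos in range(0, len(copy), 3):
                    copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
                query = random_seq(rng, 100) + "".join(copy) + random_seq(rng, 100)
            got = bool(
                similarity_search(query, [NcRNARecord("s", subject, "miRNA")], candidate_id="c")
            )
            expected = sw_retention_oracle(query, subject)
            assert got == expected, (trial, kind)
            n_checked += 1
        assert n_checked == 120


class TestSmithWaterman:
    def test_perfect_substring(self):
        score, q_iv, s_iv, matches, cols = smith_waterman("AAACGTACGTAAA", "CGTACGT")
        assert score == 7 and matches == 7 and cols == 7
        assert q_iv == (3, 10) and s_iv == (0, 7)

    def test_no_similarity_zero(self):
        assert smith_waterman("AAAA", "TTTT")[0] == 0


class TestExcludeFalsePositives:
    def _cands(self):
        return [
            candidate("A" * 50, cid="c_exon", context="exon"),
            candidate("A" * 50, cid="c_sno", context="intergenic"),
            candidate("A" * 50, cid="c_trna", context="intron"),
            candidate("A" * 50, cid="c_ok", context="intergenic"),
        ]

    def _simhits(self):
        mk = lambda cid, stype: SimilarityHit(cid, "s", stype, 10.0, 95.0, 100.0, 20, 1e-9)
        return {
            "c_sno": [mk("c_sno", "snoRNA")],
            "c_ok": [mk("c_ok", "miRNA"), mk("c_ok", "unclassified_RNA")],
            "c_exon": [mk("c_exon", "snoRNA")],
        }

    def test_reasons_and_priority(self):
        kept, excluded = exclude_false_positives(
            self._cands(), self._simhits(), trna_calls={"c_trna", "c_exon"}
        )
        reasons = {c.candidate_id: r for c, r in excluded}
        assert reasons == {
            "c_exon": "exon_overlap",       # exon beats its snoRNA hit and tRNA call
            "c_sno": "non_miRNA_ncRNA_match",
            "c_trna": "tRNA_call",
        }
        assert [c.candidate_id for c in kept] == ["c_ok"]

    def test_partition(self):
        cands = self._cands()
        kept, excluded = exclude_false_positives(cands, self._simhits(), {"c_trna"})
        assert len(kept) + len(excluded) == len(cands)

    def test_mirna_and_unclassified_hits_do_not_exclude(self):
        kept, excluded = exclude_false_positives(
            [candidate("A" * 50, cid="c_ok")], self._simhits(), set()
        )
        assert excluded == []


TBLOUT = """\
#target name  accession query name accession mdl mdl from mdl to seq from seq to strand trunc pass gc bias score E-value inc description
cand4 - mir-245 RF00816 cm 1 86 98 182 + no 1 0.43 0.0 29.76 1.2e-06 ! -
cand9 - mir-450 RF00708 cm 1 80 33 112 + no 1 0.41 0.0 30.4 3e-07 ! -
cand9 - mir-245 RF00816 cm 1 86 120 35 - no 1 0.41 0.0 24.9 0.002 ? -
"""


class TestExternalAdapters:
    def test_tblout_rows_above_cutoff_retained(self, tmp_path):
        path = tmp_path / "hits.tblout"
        path.write_text(TBLOUT)
        hits = parse_infernal_tblout(path, cutoff=25.0)
        assert [(h.candidate_id, h.family_id) for h in hits] == [
            ("cand4", "mir-245"),
            ("cand9", "mir-450"),
        ]
        h = hits[0]
        assert h.bit_score == 29.76
        assert (h.start, h.end, h.strand) == (97, 182, "+")  # 0-based half-open

    def test_below_cutoff_dropped(self, tmp_path):
        path = tmp_path / "hits.tblout"
        path.write_text(TBLOUT)
        assert all(h.bit_score >= 25.0 for h in parse_infernal_tblout(path))

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tblout"
        path.write_text("cand1 - fam RF1 cm 1 2 3\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_infernal_tblout(path)

    def test_hhmmir_scores_flag_subthreshold(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("cand1 0.67\ncand2 0.73\n# comment\n")
        scores = parse_hhmmir_scores(path, cutoff=0.71)
        assert scores["cand1"] == (0.67, False)  # recorded though below cutoff
        assert scores["cand2"] == (0.73, True)

    def test_hhmmir_malformed_raises(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("cand1 notanumber\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_hhmmir_scores(path)


def planted_precursor(rng, mature_len=21, loop=10, flank=100):
    genome = random_seq(rng, 2 * flank + mature_len * 2 + loop)
    mature = random_seq(rng, mature_len)
    genome, row = plant_hairpin(genome, mature, loop, flank, "+", 0.0, rng)
    return genome, (flank, flank + mature_len)


class TestScoreAbinitio:
    def test_planted_hairpin_scores_above_cutoff(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            seq, read_iv = planted_precursor(rng)
            feats = hairpin_features(fold_nussinov(seq), read_iv)
            assert score_abinitio(feats) >= ABINITIO_CUTOFF

    def test_shuffled_sequences_mostly_below_cutoff(self):
        rng = np.random.default_rng(45)
        below = 0
        trials = 60
        for _ in range(trials):
            seq, read_iv = planted_precursor(rng)
            shuffled = list(seq)
            rng.shuffle(shuffled)
            feats = hairpin_features(fold_nussinov("".join(shuffled)), read_iv)
            if score_abinitio(feats) < ABINITIO_CUTOFF:
                below += 1
        assert below / trials >= 0.9

    def test_monotone_in_paired_fraction(self):
        base = {
            "paired_fraction": 0.5, "longest_read_stack_pairs": 10.0,
            "read_paired_fraction": 0.8, "energy_per_nt": -0.9, "loop_length": 10.0,
        }
        scores = []
        for pf in (0.3, 0.5, 0.7, 0.9):
            feats = dict(base, paired_fraction=pf)
            scores.append(score_abinitio(feats))
        assert scores == sorted(scores)


class TestProposeMature:
    def _case(self):
        # perfect 20-bp stem, 8 nt loop: read = 5' arm
        rng = np.random.default_rng(7)
        arm = random_seq(rng, 20)
        seq = arm + random_seq(rng, 8) + revcomp(arm)
        structure = fold_nussinov(seq)
        rr = ReadRecord("r1", arm, 30, "pooled")
        cand = candidate(seq, [(MappedRead(rr, "chr1", 0, 20, "+"), 0)])
        return cand, structure

    def test_star_on_opposite_arm_with_two_nt_offset(self):
        cand, structure = self._case()
        proposals = propose_mature(cand, structure)
        kinds = {p.kind: p for p in proposals}
        assert kinds["read"].interval == (0, 20) and kinds["read"].arm == "5p"
        star = kinds["star"]
        assert star.arm == "3p"
        # partners of read positions are [28, 48); +2 nt duplex overhang
        assert star.interval == (30, 48)

    def test_loop_only_read_gives_no_proposals(self):
        rng = np.random.default_rng(8)
        arm = random_seq(rng, 15)
        loop = random_seq(rng, 12)
        seq = arm + loop + revcomp(arm)
        structure = fold_nussinov(seq)
        rr = ReadRecord("r1", loop, 30, "pooled")
        cand = candidate(seq, [(MappedRead(rr, "chr1", 15, 27, "+"), 15)])
        structure2 = parse_dotbracket(seq, "(" * 15 + "." * 12 + ")" * 15)
        assert propose_mature(cand, structure2) == []

    def test_duplex_proposals_disjoint(self):
        cand, structure = self._case()
        proposals = propose_mature(cand, structure)
        read_iv = next(p.interval for p in proposals if p.kind == "read")
        star_iv = next(p.interval for p in proposals if p.kind == "star")
        assert read_iv[1] <= star_iv[0] or star_iv[1] <= read_iv[0]


class TestIntegrateEvidence:
    def _two_arm_candidate(self):
        rng = np.random.default_rng(9)
        arm = random_seq(rng, 20)
        seq = random_seq(rng, 30) + arm + random_seq(rng, 10) + revcomp(arm) + random_seq(rng, 30)
        structure = fold_nussinov(seq)
        r1 = ReadRecord("m", arm, 30, "pooled")
        r2 = ReadRecord("s", revcomp(arm), 15, "pooled")
        cand = candidate(
            seq,
            [(MappedRead(r1, "chr1", 30, 50, "+"), 30), (MappedRead(r2, "chr1", 60, 80, "+"), 60)],
        )
        return cand, structure

    def _family_hit(self, cid, start=25, end=85):
        return FamilyHit(cid, "mir-245", "RF00816", 29.76, start, end, "+")

    def test_two_arm_with_family_hit_is_strong(self):
        cand, structure = self._two_arm_candidate()
        rec = integrate_evidence(cand, structure, [], [self._family_hit("cand1")], 0.5)
        assert rec.two_arm and rec.verdict_tier == "strong"

    def test_single_channel_overlap_none_is_weak(self):
        seq = "AAAT" * 20 + "GGGCGCGC" + "TTTA" * 20  # little clean structure
        rr = ReadRecord("r", "AAATAAATAAATAAATAAAT", 12, "pooled")
        cand = candidate(seq, [(MappedRead(rr, "chr1", 0, 20, "+"), 0)])
        structure = parse_dotbracket(seq, "." * len(seq))  # no helix at all
        rec = integrate_evidence(cand, structure, [], [], 0.99)
        assert rec.read_overlap.value == "No"
        assert rec.verdict_tier == "weak"

    def test_one_channel_with_overlap_is_supported(self):
        rng = np.random.default_rng(10)
        arm = random_seq(rng, 20)
        seq = arm + random_seq(rng, 8) + revcomp(arm)
        structure = fold_nussinov(seq)
        rr = ReadRecord("r", arm, 12, "pooled")
        cand = candidate(seq, [(MappedRead(rr, "chr1", 0, 20, "+"), 0)])
        rec = integrate_evidence(cand, structure, [], [], 0.95)
        assert rec.read_overlap.value in ("Total", "Partially")
        # two-arm does not hold (single read), one channel (abinitio) positive
        assert rec.verdict_tier in ("supported", "strong")

    def test_exclusion_overrides_everything(self):
        cand, structure = self._two_arm_candidate()
        rec = integrate_evidence(
            cand, structure, [], [self._family_hit("cand1")], 0.99,
            exclusion_reason="exon_overlap",
        )
        assert rec.verdict_tier == "excluded"
        assert rec.exclusion_reason == "exon_overlap"

    def test_adding_channels_never_lowers_tier(self):
        order = {"weak": 0, "supported": 1, "strong": 2}
        cand, structure = self._two_arm_candidate()
        sim = [SimilarityHit("cand1", "s", "miRNA", 10.0, 95.0, 100.0, 20, 1e-9)]
        fam = [self._family_hit("cand1")]
        tiers = []
        for channels in ([], [sim], [sim, fam]):
            sims = channels[0] if len(channels) >= 1 else []
            fams = channels[1] if len(channels) >= 2 else []
            rec = integrate_evidence(cand, structure, sims, fams, 0.2)
            tiers.append(order[rec.verdict_tier])
        assert tiers == sorted(tiers)

    def test_verdict_deterministic(self):
        cand, structure = self._two_arm_candidate()
        r1 = integrate_evidence(cand, structure, [], [], 0.9)
        r2 = integrate_evidence(cand, structure, [], [], 0.9)
        assert r1.verdict_tier == r2.verdict_tier
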