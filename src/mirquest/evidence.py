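"""Per-candidate evidence collection and verdict integration.

Each putative precursor is examined through independent channels — a
seeded local-alignment similarity search against a curated ncRNA database
(identity >= 80% and coverage >= 80% of query or subject), structural
family hits from external covariance-model search output (bit score >= 25),
an ab-initio hairpin score (a logistic stand-in for an HMM-based precursor
classifier, cutoff 0.71), and the read-in-stem overlap class — and the
channels are combined into a deterministic verdict tier.  False-positive
rules run first: candidates on known exons, candidates matching non-miRNA
ncRNA types, and candidates called as tRNAs are excluded.

Tier rules (operationalising a manual-curation step):

* ``excluded`` — failed a false-positive rule (one primary reason,
  priority exon > ncRNA-type > tRNA);
* ``strong``   — reads on both arms of one stem (a sequenced mature/star
  duplex, possibly from merging adjacent candidates), or a structural
  family hit covering the read with read overlap != NONE;
* ``supported``— at least one positive channel with read overlap != NONE,
  or two or more positive channels;
* ``weak``     — anything else (no channel, or one channel with the read
  outside every stem).

Sub-threshold ab-initio scores are recorded rather than dropped: published
candidate tables list such scores as predictions, so the tier rules — not
the raw cutoff alone — decide the verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .discover import CandidateLocus, two_arm_reads
from .io import parse_description_fields, read_fasta
from .structure import OverlapClass, SecondaryStructure, classify_read_overlap, extract_helices

__all__ = [
    "NcRNARecord",
    "SimilarityHit",
    "FamilyHit",
    "MatureProposal",
    "EvidenceRecord",
    "load_ncrna_db",
    "smith_waterman",
    "similarity_search",
    "exclude_false_positives",
    "parse_infernal_tblout",
    "parse_hhmmir_scores",
    "score_abinitio",
    "ABINITIO_WEIGHTS",
    "ABINITIO_CUTOFF",
    "propose_mature",
    "integrate_evidence",
]

_NON_EXCLUDING_TYPES = {"miRNA", "unclassified_RNA", "unclassified RNA"}


@dataclass(frozen=True)
class NcRNARecord:
    id: str
    sequence: str
    rtype: str


def load_ncrna_db(path: str | Path) -> list[NcRNARecord]:
    """Load a curated ncRNA FASTA whose descriptions carry ``type=`` labels."""
    records = []
    for rid, desc, seq in read_fasta(path):
        rtype = parse_description_fields(desc).get("type")
        if not rtype:
            raise ValueError(f"ncRNA record {rid} lacks a type= label")
        records.append(NcRNARecord(rid, seq.replace("U", "T"), rtype))
    return records


@dataclass(frozen=True)
class SimilarityHit:
    candidate_id: str
    subject_id: str
    subject_type: str
    query_coverage: float   # percent
    subject_coverage: float # percent
    identity: float         # percent
    score: int
    evalue_proxy: float
    query_interval: tuple[int, int] = (0, 0)
    subject_interval: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class FamilyHit:
    candidate_id: str
    family_id: str
    accession: str
    bit_score: float
    start: int   # candidate-local, 0-based
    end: int     # half-open
    strand: str


@dataclass(frozen=True)
class MatureProposal:
    kind: str       # "read" | "star"
    interval: tuple[int, int]
    sequence: str
    arm: str        # "5p" | "3p"


@dataclass
class EvidenceRecord:
    """The integrated per-candidate evidence row (one report-table line)."""

    candidate_id: str
    genomic_context: str
    normalized_counts: dict[str, float]
    similarity_hits: list[SimilarityHit]
    family_hits: list[FamilyHit]
    abinitio_score: float | None
    abinitio_positive: bool
    energy: float
    energy_is_proxy: bool
    read_overlap: OverlapClass
    two_arm: bool
    verdict_tier: str
    exclusion_reason: str | None = None


# -- local alignment --------------------------------------------------------

def smith_waterman(
    query: str, subject: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, tuple[int, int], tuple[int, int], int, int]:
    """Best local alignment (linear gap penalty) with deterministic traceback.

    Returns (score, query_interval, subject_interval, matches,
    alignment_columns).  Ties prefer the smallest end cell and, during
    traceback, diagonal over vertical over horizontal moves.
    """
    n, m = len(query), len(subject)
    h = [[0] * (m + 1) for _ in range(n + 1)]
    best, best_cell = 0, (0, 0)
    for i in range(1, n + 1):
        qi = query[i - 1]
        row = h[i]
        prev = h[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if qi == subject[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            v = diag
            if up > v:
                v = up
            if left > v:
                v = left
            if v < 0:
                v = 0
            row[j] = v
            if v > best:
                best, best_cell = v, (i, j)
    if best == 0:
        return 0, (0, 0), (0, 0), 0, 0
    i, j = best_cell
    matches = cols = 0
    while i > 0 and j > 0 and h[i][j] > 0:
        diag = h[i - 1][j - 1] + (match if query[i - 1] == subject[j - 1] else mismatch)
        if h[i][j] == diag:
            matches += query[i - 1] == subject[j - 1]
            cols += 1
            i -= 1
            j -= 1
        elif h[i][j] == h[i - 1][j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    qi0, sj0 = i, j
    return best, (qi0, best_cell[0]), (sj0, best_cell[1]), matches, cols


def _evalue_proxy(score: int, query_len: int, db_len: int, lam: float = 1.1, k: float = 0.35) -> float:
    """Karlin–Altschul-style proxy E-value from score and search-space size.

    Not a calibrated statistic — the retention rule relies on identity and
    coverage; this proxy only orders hits and filters pathological ones.
    """
    return k * query_len * max(db_len, 1) * math.exp(-lam * score)


def _seed_exists(query: str, subject: str, word_size: int) -> bool:
    if len(subject) < word_size or len(query) < word_size:
        return False
    words = {subject[i:i + word_size] for i in range(len(subject) - word_size + 1)}
    return any(query[i:i + word_size] in words for i in range(len(query) - word_size + 1))


def similarity_search(
    candidate: CandidateLocus | str,
    ncrna_db: list[NcRNARecord],
    word_size: int = 6,
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    max_evalue: float = 10.0,
    candidate_id: str | None = None,
) -> list[SimilarityHit]:
    """Seeded local similarity search of a candidate against the ncRNA DB.

    Subjects sharing an exact ``word_size``-mer with the candidate are
    aligned by Smith–Waterman (+1/-1/-2); a hit is retained when identity
    >= ``min_identity`` and either query or subject coverage reaches
    ``min_coverage`` (short mature subjects inside a long precursor pass on
    the subject side, e.g. 13% query but 97% subject coverage).  The
    E-value proxy is a permissive search-stage pre-filter only: identity
    and coverage are the decisive retention rule, because the proxy does
    not reproduce a real aligner's statistics and a legitimate ~80%
    identity hit over a short subject carries a large nominal E-value.
    """
    if not ncrna_db:
        raise ValueError("empty ncRNA database")
    if isinstance(candidate, CandidateLocus):
        query = candidate.precursor_sequence
        cid = candidate.candidate_id
    else:
        query = candidate
        cid = candidate_id or "query"
    db_len = sum(len(r.sequence) for r in ncrna_db)
    hits: list[SimilarityHit] = []
    for rec in ncrna_db:
        if not _seed_exists(query, rec.sequence, word_size):
            continue
        score, q_iv, s_iv, matches, cols = smith_waterman(query, rec.sequence)
        if cols == 0:
            continue
        identity = 100.0 * matches / cols
        qcov = 100.0 * (q_iv[1] - q_iv[0]) / len(query)
        scov = 100.0 * (s_iv[1] - s_iv[0]) / len(rec.sequence)
        evalue = _evalue_proxy(score, len(query), db_len)
        if identity >= min_identity and (qcov >= min_coverage or scov >= min_coverage) and evalue <= max_evalue:
            hits.append(
                SimilarityHit(
                    cid, rec.id, rec.rtype,
                    round(qcov, 2), round(scov, 2), round(identity, 2),
                    score, evalue, q_iv, s_iv,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


# -- false-positive exclusion ----------------------------------------------

def exclude_false_positives(
    candidates: list[CandidateLocus],
    similarity_hits: dict[str, list[SimilarityHit]],
    trna_calls: set[str] | None = None,
) -> tuple[list[CandidateLocus], list[tuple[CandidateLocus, str]]]:
    """Apply the conservative false-positive rules.

    A candidate is excluded when it overlaps a known exon
    (``genomic_context == "exon"``), when it matches a non-miRNA ncRNA type
    in the database above the similarity cutoffs, or when an external tRNA
    caller flagged it.  Exactly one primary reason is recorded per
    exclusion (priority exon > ncRNA-type > tRNA); kept plus excluded
    partition the input.
    """
    trna_calls = trna_calls or set()
    kept: list[CandidateLocus] = []
    excluded: list[tuple[CandidateLocus, str]] = []
    for cand in candidates:
        if cand.genomic_context == "exon":
            excluded.append((cand, "exon_overlap"))
            continue
        bad_types = [
            h for h in similarity_hits.get(cand.candidate_id, [])
            if h.subject_type not in _NON_EXCLUDING_TYPES
        ]
        if bad_types:
            excluded.append((cand, "non_miRNA_ncRNA_match"))
            continue
        if cand.candidate_id in trna_calls:
            excluded.append((cand, "tRNA_call"))
            continue
        kept.append(cand)
    return kept, excluded


# -- external evidence adapters ---------------------------------------------

def parse_infernal_tblout(
    path: str | Path, cutoff: float = 25.0
) -> list[FamilyHit]:
    """Parse covariance-model search tabular output (``--tblout`` dialect).

    Rows below the bit-score cutoff are dropped; sequence coordinates are
    converted to candidate-local 0-based half-open intervals with the
    strand preserved (reverse-strand rows arrive with from > to).
    """
    hits: list[FamilyHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 15:
            raise ValueError(f"malformed tblout row at line {lineno}: expected >= 15 fields")
        try:
            seq_from = int(fields[7])
            seq_to = int(fields[8])
            strand = fields[9]
            bit_score = float(fields[14])
        except ValueError as err:
            raise ValueError(f"malformed tblout row at line {lineno}: {err}") from None
        if strand not in "+-":
            raise ValueError(f"malformed tblout row at line {lineno}: bad strand {strand!r}")
        if bit_score < cutoff:
            continue
        lo, hi = min(seq_from, seq_to), max(seq_from, seq_to)
        hits.append(
            FamilyHit(
                candidate_id=fields[0],
                family_id=fields[2],
                accession=fields[3],
                bit_score=bit_score,
                start=lo - 1,
                end=hi,
                strand=strand,
            )
        )
    return hits


def parse_hhmmir_scores(
    path: str | Path, cutoff: float = 0.71
) -> dict[str, tuple[float, bool]]:
    """Parse a two-column (candidate_id, score) ab-initio score file.

    All scores are recorded; the boolean marks whether the score reaches
    the cutoff.  Below-cutoff scores are flagged, not discarded.
    """
    out: dict[str, tuple[float, bool]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"malformed score row at line {lineno}")
        try:
            score = float(fields[1])
        except ValueError:
            raise ValueError(f"malformed score at line {lineno}: {fields[1]!r}") from None
        out[fields[0]] = (score, score >= cutoff)
    return out


# -- built-in ab-initio stand-in -------------------------------------------

#: Logistic weights of the built-in hairpin classifier, calibrated once on
#: synthetic draws (planted precursors as positives, shuffled sequences as
#: negatives) and frozen.  The dominant term is the longest strictly
#: stacked helix overlapping the read: true precursors carry the read on a
#: long uninterrupted duplex, which maximum-pairing folds of random
#: sequence essentially never produce.
ABINITIO_WEIGHTS = {
    "longest_read_stack_pairs": 0.9,
    "read_paired_fraction": 2.0,
    "paired_fraction": 1.5,
    "energy_per_nt": -1.5,
    "loop_length": -0.02,
}
ABINITIO_INTERCEPT = -13.61
ABINITIO_CUTOFF = 0.71


def score_abinitio(features: dict[str, float]) -> float:
    """Logistic hairpin-likeness score in [0, 1] from fold features."""
    z = ABINITIO_INTERCEPT
    for name, w in ABINITIO_WEIGHTS.items():
        z += w * features[name]
    return 1.0 / (1.0 + math.exp(-z))


# -- mature proposal --------------------------------------------------------

def propose_mature(
    candidate: CandidateLocus, structure: SecondaryStructure
) -> list[MatureProposal]:
    """Propose mature/star sequences for a candidate from its fold.

    Proposal 1 is the original read itself when it overlaps a stem
    (totally or partially); proposal 2 is the star: the positions paired
    with the read, shifted 3' by the characteristic 2 nt duplex overhang.
    Reads confined to loops yield no proposals.
    """
    helices = extract_helices(structure)
    if not helices:
        return []
    partner = structure.partner()
    n = len(structure)
    proposals: list[MatureProposal] = []
    for start, end in candidate.read_intervals():
        if end > n:
            continue
        if classify_read_overlap(structure, (start, end)) is OverlapClass.NONE:
            continue
        mid = (start + end) / 2
        arm = "5p" if mid < n / 2 else "3p"
        seq = candidate.precursor_sequence[start:end]
        proposals.append(MatureProposal("read", (start, end), seq, arm))
        partners = sorted(partner[p] for p in range(start, end) if p in partner)
        if partners:
            lo, hi = partners[0], partners[-1] + 1
            lo2, hi2 = min(lo + 2, n), min(hi + 2, n)
            star_arm = "5p" if (lo2 + hi2) / 2 < n / 2 else "3p"
            proposals.append(
                MatureProposal(
                    "star", (lo2, hi2),
                    candidate.precursor_sequence[lo2:hi2], star_arm,
                )
            )
    return proposals


# -- verdict integration -----------------------------------------------------

def integrate_evidence(
    candidate: CandidateLocus,
    structure: SecondaryStructure,
    similarity_hits: list[SimilarityHit],
    family_hits: list[FamilyHit],
    abinitio_score: float | None,
    normalized_counts: dict[str, float] | None = None,
    exclusion_reason: str | None = None,
    abinitio_cutoff: float = ABINITIO_CUTOFF,
) -> EvidenceRecord:
    """Combine all evidence channels into a deterministic verdict tier."""
    overlap = OverlapClass.NONE
    order = {OverlapClass.NONE: 0, OverlapClass.PARTIAL: 1, OverlapClass.TOTAL: 2}
    for iv in candidate.read_intervals():
        if 0 <= iv[0] < iv[1] <= len(structure):
            oc = classify_read_overlap(structure, iv)
            if order[oc] > order[overlap]:
                overlap = oc
    two_arm = two_arm_reads(candidate, structure)

    abinitio_positive = abinitio_score is not None and abinitio_score >= abinitio_cutoff
    similarity_positive = bool(similarity_hits)
    family_positive = bool(family_hits)
    n_channels = sum([abinitio_positive, similarity_positive, family_positive])

    family_covers_read = any(
        any(h.start <= iv[0] and iv[1] <= h.end for iv in candidate.read_intervals())
        for h in family_hits
    )

    if exclusion_reason is not None:
        tier = "excluded"
    elif two_arm or (family_covers_read and overlap is not OverlapClass.NONE):
        tier = "strong"
    elif (n_channels >= 1 and overlap is not OverlapClass.NONE) or n_channels >= 2:
        tier = "supported"
    else:
        tier = "weak"

    return EvidenceRecord(
        candidate_id=candidate.candidate_id,
        genomic_context=candidate.genomic_context,
        normalized_counts=dict(normalized_counts or {}),
        similarity_hits=list(similarity_hits),
        family_hits=list(family_hits),
        abinitio_score=abinitio_score,
        abinitio_positive=abinitio_positive,
        energy=structure.energy_score,
        energy_is_proxy=structure.energy_is_proxy,
        read_overlap=overlap,
        two_arm=two_arm,
        verdict_tier=tier,
        exclusion_reason=exclusion_reason,
    )
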