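"""Novel-miRNA candidate discovery from reads matching no known miRNA.

Abundant short reads (< 35 nt, >= 10 copies by default) are mapped exactly
to the genome on both strands, clustered by position, and each cluster is
extended by 100 nt on both sides into a putative precursor — an extension
chosen because ~98% of annotated human precursor hairpins are shorter than
135 nt, so the window almost surely contains the full hairpin around the
read.  Candidates at adjacent loci whose reads fall on opposite arms of a
single stem after folding the joint interval are merged into one locus,
the situation that arises when the mature and star products of one
precursor were sequenced and clustered separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .io import revcomp
from .quantify import ReadRecord
from .structure import SecondaryStructure, extract_helices, fold_nussinov

__all__ = [
    "MappedRead",
    "Cluster",
    "CandidateLocus",
    "select_discovery_reads",
    "map_reads_exact",
    "cluster_by_position",
    "extend_cluster",
    "merge_adjacent_candidates",
    "assign_genomic_context",
]


@dataclass(frozen=True)
class MappedRead:
    """An exact genomic placement of a read (0-based half-open)."""

    read: ReadRecord
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class Cluster:
    chrom: str
    strand: str
    start: int
    end: int
    reads: list[MappedRead]


@dataclass
class CandidateLocus:
    """A cluster extended into a putative precursor window.

    ``precursor_sequence`` is the strand-adjusted genome substring (DNA
    alphabet); ``reads`` carry each read's offset within the precursor in
    transcript orientation.
    """

    candidate_id: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor_sequence: str
    reads: list[tuple[MappedRead, int]]
    genomic_context: str = "intergenic"
    merged_from: tuple[str, ...] = ()

    def read_intervals(self) -> list[tuple[int, int]]:
        """Precursor-local (offset, offset+len) intervals of the reads."""
        return [
            (off, off + len(mr.read.sequence)) for mr, off in self.reads
        ]


def select_discovery_reads(
    unmatched_reads: list[ReadRecord],
    min_copies: int = 10,
    max_len: int = 35,
    inclusive: bool = True,
) -> list[ReadRecord]:
    """Keep abundant short reads for discovery.

    A read is kept when its length is below ``max_len`` and its copy count
    reaches ``min_copies`` (>= by default; ``inclusive=False`` switches to
    a strict > threshold).
    """
    out = []
    for read in unmatched_reads:
        if len(read.sequence) >= max_len:
            continue
        if (read.count >= min_copies) if inclusive else (read.count > min_copies):
            out.append(read)
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    idx = haystack.find(needle)
    while idx != -1:
        hits.append(idx)
        idx = haystack.find(needle, idx + 1)
    return hits


def map_reads_exact(
    reads: list[ReadRecord],
    genome: dict[str, str],
    max_loci: int = 5,
) -> tuple[list[MappedRead], pd.DataFrame]:
    """Exact-match reads to both genome strands.

    Reads with more than ``max_loci`` placements, or none at all, are
    dropped and logged with the reason.  Returns (placements, dropped-log).
    """
    placements: list[MappedRead] = []
    dropped: list[dict] = []
    for read in reads:
        mine: list[MappedRead] = []
        rc = revcomp(read.sequence)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for pos in _find_all(seq, read.sequence):
                mine.append(MappedRead(read, chrom, pos, pos + len(read.sequence), "+"))
            for pos in _find_all(seq, rc):
                mine.append(MappedRead(read, chrom, pos, pos + len(read.sequence), "-"))
        if not mine:
            dropped.append({"read_id": read.id, "count": read.count, "reason": "unplaced", "n_loci": 0})
        elif len(mine) > max_loci:
            dropped.append({"read_id": read.id, "count": read.count, "reason": "multimapped", "n_loci": len(mine)})
        else:
            placements.extend(mine)
    log = pd.DataFrame(dropped, columns=["read_id", "count", "reason", "n_loci"])
    return placements, log


def cluster_by_position(mapped: list[MappedRead], max_gap: int = 10) -> list[Cluster]:
    """Group placements on one chrom/strand whose gaps are <= ``max_gap``.

    Clusters are maximal under transitive chaining and reported sorted by
    (chrom, strand, start).
    """
    clusters: list[Cluster] = []
    keyed: dict[tuple[str, str], list[MappedRead]] = {}
    for mr in mapped:
        keyed.setdefault((mr.chrom, mr.strand), []).append(mr)
    for (chrom, strand) in sorted(keyed):
        group = sorted(keyed[(chrom, strand)], key=lambda m: (m.start, m.end, m.read.id))
        current: Cluster | None = None
        for mr in group:
            if current is not None and mr.start - current.end <= max_gap:
                current.end = max(current.end, mr.end)
                current.reads.append(mr)
            else:
                if current is not None:
                    clusters.append(current)
                current = Cluster(chrom, strand, mr.start, mr.end, [mr])
        if current is not None:
            clusters.append(current)
    return clusters


def extend_cluster(
    cluster: Cluster,
    genome: dict[str, str],
    flank: int = 100,
    candidate_id: str = "cand",
) -> CandidateLocus:
    """Extend a cluster by ``flank`` nt both sides into a putative precursor.

    The interval is clamped at chromosome ends; for a single 22 nt read
    away from the edges the precursor is 222 nt with the read at offset
    100.  Read offsets are given in transcript orientation: on the minus
    strand the precursor is the reverse complement of the genomic window
    and offsets count from its 3' genomic end.
    """
    if not cluster.reads:
        raise ValueError("cannot extend an empty cluster")
    chrom_seq = genome[cluster.chrom]
    start = max(0, cluster.start - flank)
    end = min(len(chrom_seq), cluster.end + flank)
    window = chrom_seq[start:end]
    if cluster.strand == "-":
        precursor = revcomp(window)
        offsets = [(mr, end - mr.end) for mr in cluster.reads]
    else:
        precursor = window
        offsets = [(mr, mr.start - start) for mr in cluster.reads]
    return CandidateLocus(
        candidate_id, cluster.chrom, start, end, cluster.strand, precursor, offsets
    )


def _reads_on_arms(
    structure: SecondaryStructure,
    intervals_a: list[tuple[int, int]],
    intervals_b: list[tuple[int, int]],
    min_arm_frac: float = 0.5,
) -> bool:
    """True when some helix has reads of A on one arm and reads of B on the other."""
    for helix in extract_helices(structure):
        for first, second in (
            (helix.five_prime_interval, helix.three_prime_interval),
            (helix.three_prime_interval, helix.five_prime_interval),
        ):
            a_on = any(_overlap_frac(iv, first) >= min_arm_frac for iv in intervals_a)
            b_on = any(_overlap_frac(iv, second) >= min_arm_frac for iv in intervals_b)
            if a_on and b_on:
                return True
    return False


def _overlap_frac(read_iv: tuple[int, int], arm_iv: tuple[int, int]) -> float:
    lo = max(read_iv[0], arm_iv[0])
    hi = min(read_iv[1], arm_iv[1])
    width = read_iv[1] - read_iv[0]
    return max(0, hi - lo) / width if width else 0.0


def two_arm_reads(candidate: CandidateLocus, structure: SecondaryStructure) -> bool:
    """Does the candidate carry reads on both arms of one of its stems?"""
    ivs = candidate.read_intervals()
    for helix in extract_helices(structure):
        on5 = any(_overlap_frac(iv, helix.five_prime_interval) >= 0.5 for iv in ivs)
        on3 = any(_overlap_frac(iv, helix.three_prime_interval) >= 0.5 for iv in ivs)
        if on5 and on3:
            return True
    return False


def merge_adjacent_candidates(
    candidates: list[CandidateLocus],
    genome: dict[str, str],
    max_separation: int = 50,
    fold: Callable[[str], SecondaryStructure] = fold_nussinov,
    min_arm_frac: float = 0.5,
) -> list[CandidateLocus]:
    """Merge neighbouring candidates that share one hairpin stem.

    Two candidates on the same chrom/strand whose extended intervals
    overlap or lie within ``max_separation`` nt are folded over their joint
    genomic interval; they merge when their original reads sit on opposite
    arms of a single helix of that fold — the signature of a mature/star
    pair sequenced from one precursor.  The operation is idempotent.
    """
    pool = sorted(candidates, key=lambda c: (c.chrom, c.strand, c.start, c.end))
    merged = True
    while merged:
        merged = False
        for i in range(len(pool) - 1):
            a, b = pool[i], pool[i + 1]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if b.start - a.end > max_separation:
                continue
            union_start = min(a.start, b.start)
            union_end = max(a.end, b.end)
            window = genome[a.chrom][union_start:union_end]
            seq = revcomp(window) if a.strand == "-" else window
            structure = fold(seq)

            def local(c: CandidateLocus) -> list[tuple[int, int]]:
                out = []
                for mr, _off in c.reads:
                    if a.strand == "-":
                        off = union_end - mr.end
                    else:
                        off = mr.start - union_start
                    out.append((off, off + len(mr.read.sequence)))
                return out

            if not _reads_on_arms(structure, local(a), local(b), min_arm_frac):
                continue
            reads = a.reads + b.reads
            if a.strand == "-":
                new_reads = [(mr, union_end - mr.end) for mr, _ in reads]
            else:
                new_reads = [(mr, mr.start - union_start) for mr, _ in reads]
            joined = CandidateLocus(
                candidate_id=f"{a.candidate_id}+{b.candidate_id}",
                chrom=a.chrom,
                start=union_start,
                end=union_end,
                strand=a.strand,
                precursor_sequence=seq,
                reads=new_reads,
                genomic_context=a.genomic_context,
                merged_from=tuple(
                    list(a.merged_from or (a.candidate_id,))
                    + list(b.merged_from or (b.candidate_id,))
                ),
            )
            pool = pool[:i] + [joined] + pool[i + 2:]
            merged = True
            break
    return pool


_CONTEXT_PRIORITY = {"exon": 2, "intron": 1, "intergenic": 0}


def assign_genomic_context(
    candidate: CandidateLocus, annotation: pd.DataFrame
) -> str:
    """Classify a candidate as exon, intron or intergenic (strand-aware).

    The annotation DataFrame uses 0-based half-open ``start0``/``end0``
    with ``type`` in {gene, exon, ...}.  Overlap with an exon wins over
    intron (inside a gene but outside its exons), which wins over
    intergenic.
    """
    if annotation is None or annotation.empty:
        return "intergenic"
    context = "intergenic"
    for _, feat in annotation.iterrows():
        if feat["seqid"] != candidate.chrom or feat["strand"] != candidate.strand:
            continue
        if feat["end0"] <= candidate.start or feat["start0"] >= candidate.end:
            continue
        if feat["type"] == "exon":
            return "exon"
        if feat["type"] == "gene" and _CONTEXT_PRIORITY[context] < 1:
            context = "intron"
    return context
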