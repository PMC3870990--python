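"""Mature-miRNA quantification: contaminant filtering, reference matching,
multi-hit family collapsing and per-library counting.

Reads are collapsed to unique sequences per library before matching, each
carrying its copy count.  Matching against the mature reference is
5'-anchored with a small terminal shift and a substitution budget (no
indels); reads hitting several precursor variants are kept only when at
most ``max_hits`` references are hit and all belong to a single miRNA
family, in which case the count is attributed to the family key (e.g. two
genomic copies of one miRNA counted under the shared family name).
Everything else is discarded as ambiguous.  A per-library ledger accounts
for every input read copy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import parse_description_fields, read_fasta, read_fastq

__all__ = [
    "ReadRecord",
    "MatureReference",
    "ContaminantRecord",
    "Hit",
    "AssignmentResult",
    "load_reads",
    "load_mature_reference",
    "load_contaminants",
    "family_key_from_name",
    "filter_contaminants",
    "match_mature",
    "assign_read",
    "quantify",
]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """A unique small-RNA read sequence with its copy count."""

    id: str
    sequence: str
    count: int
    library_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if not self.sequence or set(self.sequence) - _VALID_BASES:
            raise ValueError(f"illegal read sequence {self.sequence!r}")


@dataclass(frozen=True)
class MatureReference:
    mature_name: str
    sequence: str
    precursor_ids: tuple[str, ...]
    family_key: str

    def __post_init__(self) -> None:
        if not self.family_key:
            raise ValueError("family_key must be non-empty")


@dataclass(frozen=True)
class ContaminantRecord:
    id: str
    sequence: str
    klass: str


@dataclass(frozen=True)
class Hit:
    reference: MatureReference
    mismatches: int
    offset: int


@dataclass(frozen=True)
class AssignmentResult:
    read: ReadRecord
    status: str  # assigned | discarded_multihit | unmatched | contaminant
    label: str | None = None
    n_hits: int = 0
    contaminant_class: str | None = None


def family_key_from_name(name: str) -> str:
    """Derive a family key by stripping a trailing ``-<digit>`` copy suffix.

    ``hsa-mir-103a-1`` and ``hsa-mir-103a-2`` both yield ``hsa-mir-103a``;
    an explicit family map overrides this heuristic when provided.
    """
    head, dash, tail = name.rpartition("-")
    if dash and tail.isdigit():
        return head
    return name


def load_reads(path: str | Path, library_from_id: bool = True) -> list[ReadRecord]:
    """Load FASTQ/FASTA reads, collapsing identical sequences per library.

    With ``library_from_id`` the library is the ``|``-separated prefix of
    each read id (the synthetic bundle's convention); otherwise all reads
    belong to library ``L1``.  Collapsed FASTA with ``count=N`` in the
    description is honoured.
    """
    path = Path(path)
    raw: list[tuple[str, str, str, int]] = []
    if path.suffix in (".fastq", ".fq"):
        for rid, seq in read_fastq(path):
            lib = rid.split("|", 1)[0] if library_from_id and "|" in rid else "L1"
            raw.append((rid, lib, seq, 1))
    else:
        for rid, desc, seq in read_fasta(path):
            lib = rid.split("|", 1)[0] if library_from_id and "|" in rid else "L1"
            count = int(parse_description_fields(desc).get("count", 1))
            raw.append((rid, lib, seq, count))
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for _rid, lib, seq, cnt in raw:
        counts[(lib, seq)] += cnt
    records = []
    for idx, ((lib, seq), cnt) in enumerate(sorted(counts.items()), start=1):
        records.append(ReadRecord(f"{lib}_u{idx:06d}", seq, cnt, lib))
    return records


def load_mature_reference(
    fasta_path: str | Path, family_map_path: str | Path | None = None
) -> list[MatureReference]:
    """Load the mature reference FASTA plus optional family map TSV.

    The family map has columns mature_name, precursor_id, family_key; in
    its absence families fall back to the name-suffix heuristic.
    """
    fam_by_name: dict[str, str] = {}
    precursors: dict[str, list[str]] = defaultdict(list)
    if family_map_path is not None:
        fam = pd.read_csv(family_map_path, sep="\t")
        for _, row in fam.iterrows():
            fam_by_name[row["mature_name"]] = row["family_key"]
            precursors[row["mature_name"]].append(row["precursor_id"])
    refs = []
    for rid, desc, seq in read_fasta(fasta_path):
        family = fam_by_name.get(rid) or parse_description_fields(desc).get(
            "family", family_key_from_name(rid)
        )
        refs.append(
            MatureReference(
                rid,
                seq.replace("U", "T"),
                tuple(precursors.get(rid, [rid])),
                family,
            )
        )
    return refs


def load_contaminants(path: str | Path) -> list[ContaminantRecord]:
    records = []
    for rid, desc, seq in read_fasta(path):
        klass = parse_description_fields(desc).get("class")
        if not klass:
            raise ValueError(f"contaminant record {rid} lacks a class= label")
        records.append(ContaminantRecord(rid, seq, klass))
    return records


def _hamming_window(read: str, ref: str, offset: int) -> int:
    """Mismatches of ``read`` against ``ref`` at the given offset (substring scan)."""
    window = ref[offset: offset + len(read)]
    return sum(1 for a, b in zip(read, window) if a != b or a == "N" or b == "N")


def filter_contaminants(
    reads: list[ReadRecord],
    contaminant_db: list[ContaminantRecord],
    max_mismatch: int = 0,
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Remove reads matching any contaminant record, tallied per class.

    A read matches when it occurs as a substring of a contaminant sequence
    within the mismatch budget (exact substring search when the budget is
    zero).  Returns (kept, removed-with-class); kept plus removed partition
    the input.
    """
    kept: list[ReadRecord] = []
    removed: list[tuple[ReadRecord, str]] = []
    for read in reads:
        hit_class: str | None = None
        for rec in contaminant_db:
            if len(read.sequence) > len(rec.sequence):
                continue
            if max_mismatch == 0:
                if read.sequence in rec.sequence:
                    hit_class = rec.klass
                    break
            else:
                for off in range(len(rec.sequence) - len(read.sequence) + 1):
                    if _hamming_window(read.sequence, rec.sequence, off) <= max_mismatch:
                        hit_class = rec.klass
                        break
                if hit_class:
                    break
        if hit_class is None:
            kept.append(read)
        else:
            removed.append((read, hit_class))
    return kept, removed


def match_mature(
    read: ReadRecord | str,
    references: list[MatureReference],
    max_mismatch: int = 2,
    max_shift: int = 2,
    min_overlap: int = 15,
) -> list[Hit]:
    """Find mature references matching a read, 5'-anchored.

    The mature start is placed within ``max_shift`` nt of the read start
    (offset ``o``: read position where the mature begins, possibly
    negative); substitutions are counted over the overlapping window and N
    bases always mismatch.  Terminal bases outside the overlap — a trimmed
    read end or a templated 3' tail beyond the mature — are not penalised,
    but the overlap must reach ``min_overlap`` nt.  One best hit (fewest
    mismatches, then smallest |offset|) is reported per reference.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < 15:
        raise ValueError("reads shorter than 15 nt are not matched")
    hits: list[Hit] = []
    for ref in references:
        best: tuple[int, int, int] | None = None  # (mismatches, |offset|, offset)
        for o in range(-max_shift, max_shift + 1):
            # read position i aligns with mature position i - o
            lo = max(0, o)
            hi = min(len(seq), o + len(ref.sequence))
            overlap = hi - lo
            if overlap < min(min_overlap, len(ref.sequence)):
                continue
            mm = sum(
                1
                for i in range(lo, hi)
                if seq[i] != ref.sequence[i - o] or seq[i] == "N" or ref.sequence[i - o] == "N"
            )
            if mm <= max_mismatch:
                cand = (mm, abs(o), o)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            hits.append(Hit(ref, best[0], best[2]))
    return hits


def assign_read(
    read: ReadRecord,
    hits: list[Hit],
    max_hits: int = 5,
    cap_on: str = "hits",
) -> AssignmentResult:
    """Apply the multi-hit collapse rule to a read's reference hits.

    No hits → unmatched.  A single hit is assigned to the mature name.
    2..``max_hits`` hits that all share one family key are collapsed and
    assigned to the family key; more hits, or hits spanning two or more
    families, are discarded as ambiguous.  With ``cap_on="families"`` the
    cap is applied to the number of distinct families after collapsing
    instead of distinct reference hits.
    """
    n = len(hits)
    if n == 0:
        return AssignmentResult(read, "unmatched")
    if n == 1:
        return AssignmentResult(read, "assigned", hits[0].reference.mature_name, 1)
    families = {h.reference.family_key for h in hits}
    if cap_on == "families":
        if len(families) == 1:
            return AssignmentResult(read, "assigned", families.pop(), n)
        return AssignmentResult(read, "discarded_multihit", n_hits=n)
    if n <= max_hits and len(families) == 1:
        return AssignmentResult(read, "assigned", families.pop(), n)
    return AssignmentResult(read, "discarded_multihit", n_hits=n)


def quantify(
    assignments: list[AssignmentResult], library_id: str
) -> tuple[dict[str, int], dict[str, int]]:
    """Sum read copy counts per assigned label for one library.

    Returns (counts, ledger); the ledger tallies copies by status
    (assigned / unmatched / discarded_multihit / contaminant) and always
    sums to the library's total input copies.
    """
    counts: dict[str, int] = defaultdict(int)
    ledger: dict[str, int] = defaultdict(int)
    for res in assignments:
        if res.read.library_id != library_id:
            raise ValueError(
                f"assignment for library {res.read.library_id} passed to {library_id}"
            )
        ledger[res.status] += res.read.count
        if res.status == "assigned":
            counts[res.label] += res.read.count
    ledger["total"] = sum(v for k, v in ledger.items() if k != "total")
    return dict(counts), dict(ledger)
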