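"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation under test: explicit enumeration for folding, brute-force
Hamming scans for mature matching, union-find for positional clustering,
Biopython's pairwise aligner for local alignment, and naive per-position
set arithmetic for read-in-stem classification.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def best_fold_score_enum(seq: str, min_loop: int = 3) -> int:
    """Optimal pair-score sum over nested structures, by interval recursion.

    Recursive formulation (first base unpaired, or paired with each
    admissible partner) with memoisation on the interval — independent of
    the iterative DP and traceback under test.
    """
    rna = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            s = PAIR_SCORES.get((rna[i], rna[k]), 0)
            if s:
                best = max(best, s + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(rna) - 1)


def all_structures(seq: str, min_loop: int = 3):
    """Yield every nested structure (as a frozenset of pairs) — full enumeration.

    Exponential; only for short sequences.
    """
    rna = seq.upper().replace("T", "U")

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in rec(rest):
            yield s
        # first paired with k
        for idx, k in enumerate(rest):
            if k - first <= min_loop:
                continue
            if (rna[first], rna[k]) not in PAIR_SCORES:
                continue
            inside = tuple(p for p in rest[:idx])
            outside = tuple(p for p in rest[idx + 1:])
            for si in rec(inside):
                for so in rec(outside):
                    yield si | so | {(first, k)}

    yield from rec(tuple(range(len(rna))))


def best_fold_score_full(seq: str, min_loop: int = 3) -> int:
    rna = seq.upper().replace("T", "U")
    best = 0
    for struct in all_structures(rna, min_loop):
        score = sum(PAIR_SCORES[(rna[i], rna[j])] for i, j in struct)
        best = max(best, score)
    return best


def hamming_match_oracle(
    read: str, references, max_mismatch: int = 2, max_shift: int = 2, min_overlap: int = 15
):
    """Brute-force scan over all references and offsets (mirrors the matching rule)."""
    names = []
    for ref in references:
        found = False
        for o in range(-max_shift, max_shift + 1):
            lo = max(0, o)
            hi = min(len(read), o + len(ref.sequence))
            if hi - lo < min(min_overlap, len(ref.sequence)):
                continue
            mm = 0
            for i in range(lo, hi):
                a, b = read[i], ref.sequence[i - o]
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mismatch:
                found = True
                break
        if found:
            names.append(ref.mature_name)
    return set(names)


def union_find_clusters(intervals, max_gap: int):
    """Cluster (start, end) intervals by transitive gap <= max_gap, via union-find."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(frozenset(g) for g in groups.values())


def sw_retention_oracle(
    query: str, subject: str, min_identity: float = 80.0, min_coverage: float = 80.0
) -> bool:
    """Retention decision from Biopython's exhaustive local aligner (+1/-1/-2)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    if aligner.score(query, subject) <= 0:
        return False
    aln = aligner.align(query, subject)[0]
    qa, sa = str(aln[0]), str(aln[1])
    cols = len(qa)
    matches = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    identity = 100.0 * matches / cols if cols else 0.0
    q_span = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    s_span = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    qcov = 100.0 * q_span / len(query)
    scov = 100.0 * s_span / len(subject)
    return identity >= min_identity and (qcov >= min_coverage or scov >= min_coverage)


def overlap_class_oracle(helices, read_interval) -> str:
    """Per-position membership count in helix arms (naive loops)."""
    member = set()
    for h in helices:
        for iv in (h.five_prime_interval, h.three_prime_interval):
            for p in range(iv[0], iv[1]):
                member.add(p)
    inside = [p in member for p in range(read_interval[0], read_interval[1])]
    if all(inside):
        return "Total"
    if not any(inside):
        return "No"
    return "Partially"
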