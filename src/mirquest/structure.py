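"""RNA secondary-structure utilities for putative precursor analysis.

The built-in folder is a pair-scored Nussinov dynamic program, not a
thermodynamic model: it maximises a stacking-free sum of pair scores
(GC > AU > GU) over all pseudoknot-free structures with a minimum hairpin
loop.  Its ``energy_score`` is a stability *proxy* (more negative = more
stable) and is never a free energy in kcal/mol; externally computed
dot-bracket strings and free energies (e.g. from RNAfold) can be injected
through :func:`parse_dotbracket` and the Vienna-file readers in
:mod:`mirquest.io` and flow through the rest of the pipeline unchanged.

Downstream, the question asked of every candidate precursor is whether the
sequenced read lies in a *stem*: :func:`extract_helices` decomposes a
structure into maximal runs of stacked pairs (tolerating small bulges) and
:func:`classify_read_overlap` reports TOTAL / PARTIAL / NONE membership of
the read interval in the union of helix arms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "SecondaryStructure",
    "Helix",
    "OverlapClass",
    "PAIR_SCORES",
    "fold_nussinov",
    "parse_dotbracket",
    "extract_helices",
    "classify_read_overlap",
    "hairpin_features",
    "length_quantile",
]

#: Pair scores (magnitudes) used by the built-in folder.  The signed
#: ``energy_score`` of a fold is minus the sum of these over its pairs.
PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# 4x4 score matrix indexed by _BASE_INDEX; 0 = cannot pair.
_SCORE_MATRIX = np.zeros((4, 4), dtype=np.int32)
for (_a, _b), _s in PAIR_SCORES.items():
    _SCORE_MATRIX[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _s


def as_rna(sequence: str) -> str:
    """Return the RNA view (T→U, uppercase) of a DNA or RNA string."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class Helix:
    """A maximal run of (near-)stacked base pairs.

    ``five_prime_interval`` and ``three_prime_interval`` are 0-based
    half-open position ranges on the two arms; positions inside them that
    are not base-paired are bulges (gap size bounded by the extraction
    tolerance).
    """

    five_prime_interval: tuple[int, int]
    three_prime_interval: tuple[int, int]
    n_pairs: int
    bulge_positions: tuple[int, ...] = ()

    def arm_positions(self) -> set[int]:
        a, b = self.five_prime_interval
        c, d = self.three_prime_interval
        return set(range(a, b)) | set(range(c, d))


class OverlapClass(enum.Enum):
    """Read-versus-stem overlap call: is the read inside helix arms?"""

    TOTAL = "Total"
    PARTIAL = "Partially"
    NONE = "No"


@dataclass
class SecondaryStructure:
    """A nested (pseudoknot-free) secondary structure.

    ``energy_score`` is the folder's pair-score proxy unless the structure
    was imported together with an external free energy, in which case it is
    that energy in kcal/mol (callers track which through ``energy_is_proxy``).
    """

    sequence: str
    dot_bracket: str
    pairs: list[tuple[int, int]]
    energy_score: float
    energy_is_proxy: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def validate(self, min_loop: int = 3) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError(
                "dot-bracket length %d != sequence length %d"
                % (len(self.dot_bracket), len(self.sequence))
            )
        depth = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif ch != ".":
                raise ValueError(f"illegal dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < len(self.sequence)):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValueError("position paired twice")
            seen.add(i)
            seen.add(j)
        # hairpin-loop check: a pair whose enclosed span contains no other
        # paired position closes a hairpin and needs >= min_loop unpaired.
        paired = seen
        for i, j in self.pairs:
            if not any(p in paired for p in range(i + 1, j)):
                if j - i - 1 < min_loop:
                    raise ValueError(f"hairpin loop of pair ({i},{j}) shorter than {min_loop}")


def _encode(sequence: str) -> np.ndarray:
    rna = as_rna(sequence)
    enc = np.empty(len(rna), dtype=np.int8)
    for idx, ch in enumerate(rna):
        enc[idx] = _BASE_INDEX.get(ch, -1)
    return enc


@njit(cache=True)
def _nussinov_fill(enc, min_loop, smat):  # pragma: no cover - numba kernel
    n = enc.size
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            ai = enc[i]
            if ai >= 0:
                for k in range(i + min_loop + 1, j + 1):
                    ak = enc[k]
                    if ak < 0:
                        continue
                    s = smat[ai, ak]
                    if s > 0:
                        v = s
                        if k - 1 >= i + 1:
                            v += m[i + 1, k - 1]
                        if k + 1 <= j:
                            v += m[k + 1, j]
                        if v > best:
                            best = v
            m[i, j] = best
    return m


def fold_nussinov(
    sequence: str,
    min_loop: int = 3,
    scoring: dict[tuple[str, str], int] | None = None,
) -> SecondaryStructure:
    """Fold ``sequence`` with the pair-scored Nussinov dynamic program.

    Maximises the summed pair score over nested structures whose hairpin
    loops hold at least ``min_loop`` unpaired bases.  Ties are broken
    deterministically during traceback: at each subinterval the 5'-most
    base is paired (with its smallest admissible partner) whenever pairing
    attains the optimum, otherwise it is left unpaired.

    Returns a :class:`SecondaryStructure` whose ``energy_score`` is minus
    the optimal pair-score sum.  Sequences too short to fold return the
    all-unpaired structure with score 0.
    """
    if scoring is None:
        smat = _SCORE_MATRIX
    else:
        smat = np.zeros((4, 4), dtype=np.int32)
        for (a, b), s in scoring.items():
            smat[_BASE_INDEX[a], _BASE_INDEX[b]] = abs(s)
    rna = as_rna(sequence)
    n = len(rna)
    if n < min_loop + 2:
        return SecondaryStructure(rna, "." * n, [], 0.0)
    enc = _encode(rna)
    m = _nussinov_fill(enc, min_loop, smat)

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or m[i, j] == 0:
            continue
        target = m[i, j]
        chosen = -1
        if enc[i] >= 0:
            for k in range(i + min_loop + 1, j + 1):
                if enc[k] < 0:
                    continue
                s = smat[enc[i], enc[k]]
                if s <= 0:
                    continue
                v = s
                if k - 1 >= i + 1:
                    v += m[i + 1, k - 1]
                if k + 1 <= j:
                    v += m[k + 1, j]
                if v == target:
                    chosen = k
                    break
        if chosen < 0:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            if chosen - 1 >= i + 1:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    score = -float(m[0, n - 1])
    return SecondaryStructure(rna, "".join(db), pairs, score)


def parse_dotbracket(sequence: str, dot_bracket: str) -> SecondaryStructure:
    """Build a structure from an externally supplied dot-bracket string.

    Accepts the plain Vienna dialect (``(``, ``)``, ``.``).  Raises
    ``ValueError`` on length mismatch or unbalanced brackets.
    """
    rna = as_rna(sequence)
    if len(rna) != len(dot_bracket):
        raise ValueError(
            "sequence length %d != structure length %d" % (len(rna), len(dot_bracket))
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"illegal dot-bracket character {ch!r} at position {idx}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    pairs.sort()
    score = -float(
        sum(PAIR_SCORES.get((rna[i], rna[j]), 0) for i, j in pairs)
    )
    return SecondaryStructure(rna, dot_bracket, pairs, score)


def extract_helices(structure: SecondaryStructure, bulge_tol: int = 2) -> list[Helix]:
    """Decompose a structure into maximal helices (runs of stacked pairs).

    Two consecutive pairs (i1,j1), (i2,j2) with i2>i1 and j2<j1 extend the
    same helix when the unpaired gap on each arm is at most ``bulge_tol``
    nucleotides.  Helices are reported sorted by 5' start, with arm
    intervals covering any tolerated bulge positions.
    """
    pairs = sorted(structure.pairs)
    helices: list[Helix] = []
    run: list[tuple[int, int]] = []

    def flush() -> None:
        if not run:
            return
        i0, j0 = run[0]
        i1, j1 = run[-1]
        arm5 = (i0, i1 + 1)
        arm3 = (j1, j0 + 1)
        paired = {p for pr in run for p in pr}
        bulges = tuple(
            p
            for p in list(range(*arm5)) + list(range(*arm3))
            if p not in paired
        )
        helices.append(Helix(arm5, arm3, len(run), bulges))
        run.clear()

    for pair in pairs:
        if not run:
            run.append(pair)
            continue
        pi, pj = run[-1]
        i, j = pair
        gap5 = i - pi - 1
        gap3 = pj - j - 1
        if i > pi and j < pj and 0 <= gap5 <= bulge_tol and 0 <= gap3 <= bulge_tol:
            run.append(pair)
        else:
            flush()
            run.append(pair)
    flush()
    helices.sort(key=lambda h: h.five_prime_interval[0])
    return helices


def classify_read_overlap(
    structure: SecondaryStructure,
    read_interval: tuple[int, int],
    bulge_tol: int = 2,
) -> OverlapClass:
    """Classify a read interval against the union of helix arm intervals.

    TOTAL when every read position lies inside some helix arm, NONE when no
    position does, PARTIAL otherwise.  Arm intervals include tolerated
    bulges, so reads spanning a small interior bulge still call TOTAL.
    """
    start, end = read_interval
    if not (0 <= start < end <= len(structure)):
        raise IndexError(f"read interval {read_interval} outside structure of length {len(structure)}")
    arm_union: set[int] = set()
    for h in extract_helices(structure, bulge_tol=bulge_tol):
        arm_union.update(h.arm_positions())
    n = end - start
    hits = sum(1 for p in range(start, end) if p in arm_union)
    if hits == n:
        return OverlapClass.TOTAL
    if hits == 0:
        return OverlapClass.NONE
    return OverlapClass.PARTIAL


def hairpin_features(
    structure: SecondaryStructure,
    read_interval: tuple[int, int] | None = None,
    bulge_tol: int = 2,
) -> dict[str, float]:
    """Summary features of a (putative precursor) structure.

    Returns ``paired_fraction`` (fraction of bases in a pair),
    ``longest_helix_pairs`` (pair count of the longest helix),
    ``longest_read_helix_pairs`` (longest helix whose arms overlap the read;
    0 without a read), ``loop_length`` (unpaired span enclosed by the
    innermost pair of the longest helix), ``energy_per_nt``,
    ``read_paired_fraction`` (fraction of read positions inside helix arms),
    ``arm_symmetry`` (shorter/longer arm length of the longest helix), and
    the strictly stacked counterparts ``longest_stack_pairs`` /
    ``longest_read_stack_pairs`` (helix decomposition with zero bulge
    tolerance).  Strict stacks are the discriminative signal for hairpin
    recognition: a true precursor carries its mature read on one arm of a
    long uninterrupted duplex, while maximum-pairing folds of random
    sequence reach comparable pairing only through heavily bulged helices.
    """
    n = len(structure)
    pairs = structure.pairs
    paired_fraction = 2 * len(pairs) / n if n else 0.0
    helices = extract_helices(structure, bulge_tol=bulge_tol)
    longest = max(helices, key=lambda h: h.n_pairs, default=None)
    if longest is None:
        longest_pairs = 0
        loop_length = float(n)
        arm_symmetry = 0.0
    else:
        longest_pairs = longest.n_pairs
        inner_i = longest.five_prime_interval[1] - 1
        inner_j = longest.three_prime_interval[0]
        loop_length = float(inner_j - inner_i - 1)
        l5 = longest.five_prime_interval[1] - longest.five_prime_interval[0]
        l3 = longest.three_prime_interval[1] - longest.three_prime_interval[0]
        arm_symmetry = min(l5, l3) / max(l5, l3)
    stacks = extract_helices(structure, bulge_tol=0)
    longest_stack = max((h.n_pairs for h in stacks), default=0)
    read_paired_fraction = 0.0
    longest_read_helix = 0
    longest_read_stack = 0
    if read_interval is not None:
        start, end = read_interval
        read_pos = set(range(start, end))
        arm_union: set[int] = set()
        for h in helices:
            arm_union.update(h.arm_positions())
        width = max(end - start, 1)
        read_paired_fraction = len(read_pos & arm_union) / width
        for h in helices:
            if read_pos & h.arm_positions():
                longest_read_helix = max(longest_read_helix, h.n_pairs)
        for h in stacks:
            if read_pos & h.arm_positions():
                longest_read_stack = max(longest_read_stack, h.n_pairs)
    return {
        "paired_fraction": paired_fraction,
        "longest_helix_pairs": float(longest_pairs),
        "longest_read_helix_pairs": float(longest_read_helix),
        "longest_stack_pairs": float(longest_stack),
        "longest_read_stack_pairs": float(longest_read_stack),
        "loop_length": loop_length,
        "energy_per_nt": structure.energy_score / n if n else 0.0,
        "read_paired_fraction": read_paired_fraction,
        "arm_symmetry": arm_symmetry,
    }


def length_quantile(lengths: Sequence[int] | Iterable[int], q: float = 0.98) -> int:
    """Inclusive lower quantile: smallest L with fraction(lengths <= L) >= q.

    This is the statistic behind the choice of the ±100 nt precursor
    extension: 98% of annotated human precursor hairpins are shorter than
    135 nt, so a read plus 100 nt of flank on each side covers nearly any
    true precursor containing it.
    """
    values = sorted(lengths)
    if not values:
        raise ValueError("empty length list")
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    n = len(values)
    for idx, v in enumerate(values, start=1):
        if idx / n >= q:
            return v
    return values[-1]
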