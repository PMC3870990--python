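"""Expression comparison between small-RNA libraries.

Counts are normalized by the highest expression value of the library
(max-normalization), so every profile becomes a relative-abundance vector
with maximum ``scale``.  Differential expression is a pure fold-change
rule — a label is called when both libraries express it above a floor and
the larger normalized value is at least ``min_fold`` times the smaller —
with zero-versus-nonzero labels routed to the uniquely-expressed report
instead of producing infinite folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "ExpressionProfile",
    "normalize_max",
    "call_differential",
    "unique_expressed",
    "top_expressed",
    "common_mirna_percentage",
]


@dataclass
class ExpressionProfile:
    """Per-library mapping of miRNA/family label to raw and normalized abundance."""

    library_id: str
    raw: dict[str, int]
    normalized: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in self.raw.items():
            if v < 0:
                raise ValueError(f"negative raw count for {label}")

    def labels(self) -> set[str]:
        return set(self.raw)

    def detected(self, min_count: int = 1) -> set[str]:
        return {k for k, v in self.raw.items() if v >= min_count}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": k, "raw_count": self.raw[k], "normalized": self.normalized.get(k, float("nan"))}
            for k in sorted(self.raw)
        ]
        return pd.DataFrame(rows, columns=["label", "raw_count", "normalized"])


def normalize_max(
    profile: ExpressionProfile, scale: float = 1.0, global_max: int | None = None
) -> ExpressionProfile:
    """Normalize by the library's highest raw count (times ``scale``).

    ``global_max`` switches to a shared maximum across libraries for the
    dataset-wide variant of the rule.  An all-zero profile normalizes to
    all zeros; an empty profile is an error.
    """
    if not profile.raw:
        raise ValueError("cannot normalize an empty profile")
    denom = global_max if global_max is not None else max(profile.raw.values())
    norm = {
        k: (v / denom * scale if denom > 0 else 0.0) for k, v in profile.raw.items()
    }
    return ExpressionProfile(profile.library_id, dict(profile.raw), norm)


def _default_floor(*profiles: ExpressionProfile) -> float:
    positives = [
        v for p in profiles for v in p.normalized.values() if v > 0
    ]
    return min(positives) if positives else 0.0


def call_differential(
    prof_a: ExpressionProfile,
    prof_b: ExpressionProfile,
    min_fold: float = 2.0,
    floor: float | None = None,
) -> pd.DataFrame:
    """Call labels whose normalized abundance differs by >= ``min_fold``.

    Only labels expressed above the floor in *both* libraries enter the
    table (the default floor is the smallest nonzero normalized value, so
    it separates expressed from absent); zero-vs-nonzero labels belong in
    :func:`unique_expressed`.  Rows report fold_change = larger/smaller and
    the library with the higher value, sorted by descending fold.
    """
    if not prof_a.normalized or not prof_b.normalized:
        raise ValueError("profiles must be normalized before differential calling")
    if floor is None:
        floor = _default_floor(prof_a, prof_b)
    rows = []
    for label in sorted(prof_a.labels() | prof_b.labels()):
        na = prof_a.normalized.get(label, 0.0)
        nb = prof_b.normalized.get(label, 0.0)
        if na < floor or nb < floor or na <= 0 or nb <= 0:
            continue
        fold = max(na, nb) / min(na, nb)
        if fold >= min_fold:
            rows.append(
                {
                    "label": label,
                    "norm_A": na,
                    "norm_B": nb,
                    "fold_change": fold,
                    "direction": prof_a.library_id if na > nb else prof_b.library_id,
                }
            )
    df = pd.DataFrame(rows, columns=["label", "norm_A", "norm_B", "fold_change", "direction"])
    return df.sort_values(["fold_change", "label"], ascending=[False, True]).reset_index(drop=True)


def unique_expressed(
    prof_a: ExpressionProfile, prof_b: ExpressionProfile, min_count: int = 10
) -> tuple[set[str], set[str]]:
    """Labels expressed in exactly one library at >= ``min_count`` raw copies."""
    labels = prof_a.labels() | prof_b.labels()
    only_a = {
        l for l in labels
        if prof_a.raw.get(l, 0) >= min_count and prof_b.raw.get(l, 0) == 0
    }
    only_b = {
        l for l in labels
        if prof_b.raw.get(l, 0) >= min_count and prof_a.raw.get(l, 0) == 0
    }
    return only_a, only_b


def top_expressed(profile: ExpressionProfile, n: int = 10) -> tuple[pd.DataFrame, float]:
    """Top-``n`` labels by raw count and their cumulative fraction of copies.

    Ties rank lexicographically.  The fraction is relative to all assigned
    copies in the profile, mirroring statements like "the ten most abundant
    miRNAs account for X% of miRNA-mapped reads".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not profile.raw:
        raise ValueError("profile is empty")
    ranked = sorted(profile.raw.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    total = sum(profile.raw.values())
    top_sum = sum(v for _, v in ranked)
    df = pd.DataFrame(ranked, columns=["label", "raw_count"])
    df["rank"] = range(1, len(df) + 1)
    return df[["rank", "label", "raw_count"]], (top_sum / total if total else 0.0)


def common_mirna_percentage(detected_sample: set[str], detected_reference: set[str]) -> float:
    """Percent of the sample's detected labels shared with the reference.

    100 x |sample ∩ reference| / |sample|, rounded half-up to two decimals
    (e.g. 219 of 313 detected → 69.97).
    """
    if not detected_sample:
        raise ValueError("sample set is empty")
    pct = Decimal(100 * len(detected_sample & detected_reference)) / Decimal(
        len(detected_sample)
    )
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
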