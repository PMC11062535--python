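"""Cross-algorithm and cross-position comparison of mined pattern sets.

Pattern identity everywhere is (kind, items): a contiguous pattern "ab"
and the itemset {a, b} never match, even though they print alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .mining import Pattern, UniquePatternSet


def round_half_up(x: float, ndigits: int) -> float:
    """Half-up rounding to the precision used in printed score tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def jaccard(X: set, Y: set) -> float:
    """Jaccard similarity J(X, Y) = |X ∩ Y| / |X ∪ Y|.

    0 means no shared patterns, 1 an exact match. Undefined (raises) when
    both sets are empty.
    """
    union = len(X | Y)
    if union == 0:
        raise ValueError("Jaccard similarity is undefined for two empty sets")
    return len(X & Y) / union


def exact_overlap(X: set, Y: set) -> set:
    """Patterns present in both sets under exact (kind, items) identity."""
    return X & Y


def similarity_matrix(sets_by_algorithm: Mapping[str, set]) -> pd.DataFrame:
    """Symmetric unit-diagonal Jaccard matrix over algorithm tags."""
    tags = list(sets_by_algorithm)
    mat = pd.DataFrame(1.0, index=tags, columns=tags)
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            s = jaccard(sets_by_algorithm[a], sets_by_algorithm[b])
            mat.loc[a, b] = mat.loc[b, a] = s
    return mat


@dataclass
class OverlapReport:
    """Exact-match overlap of two unique pattern sets plus where the
    overlap sits in each side's frequency ranking."""

    side_a: str
    side_b: str
    overlap: set[Pattern]
    ranks_a: dict[Pattern, int]
    ranks_b: dict[Pattern, int]
    freqs_a: dict[Pattern, int]
    freqs_b: dict[Pattern, int]
    top_k_overlap: set[Pattern]
    bottom_k_overlap: set[Pattern]
    k: int


def _ranked(ups: UniquePatternSet, *, most_frequent: bool) -> list[Pattern]:
    """Patterns ordered by extraction frequency; ties by item order."""
    sign = -1 if most_frequent else 1
    return sorted(ups.provenance, key=lambda p: (sign * ups.frequency(p), p.items))


def topk_bottomk_overlap(ups_a: UniquePatternSet, ups_b: UniquePatternSet,
                         k: int = 50) -> OverlapReport:
    """Overlap among each side's k most frequent and k least frequent
    patterns, plus the full exact-match overlap with per-side ranks.

    Frequency is the number of player-match corpora a pattern was
    extracted from; ties break by frequency then lexicographic items.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_a = _ranked(ups_a, most_frequent=True)
    top_b = _ranked(ups_b, most_frequent=True)
    bottom_a = _ranked(ups_a, most_frequent=False)
    bottom_b = _ranked(ups_b, most_frequent=False)
    overlap = exact_overlap(ups_a.pattern_keys(), ups_b.pattern_keys())
    return OverlapReport(
        side_a=ups_a.algorithm,
        side_b=ups_b.algorithm,
        overlap=overlap,
        ranks_a={p: r + 1 for r, p in enumerate(top_a)},
        ranks_b={p: r + 1 for r, p in enumerate(top_b)},
        freqs_a={p: ups_a.frequency(p) for p in ups_a.provenance},
        freqs_b={p: ups_b.frequency(p) for p in ups_b.provenance},
        top_k_overlap=set(top_a[:k]) & set(top_b[:k]),
        bottom_k_overlap=set(bottom_a[:k]) & set(bottom_b[:k]),
        k=k,
    )


@dataclass
class PositionPartition:
    """Shared / A-only / B-only split of two positions' pattern sets."""

    position_a: str
    position_b: str
    shared: set[Pattern]
    only_a: set[Pattern]
    only_b: set[Pattern]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            f"{self.position_a}_only": len(self.only_a),
            f"{self.position_b}_only": len(self.only_b),
        }


def position_partition(patterns_by_position: Mapping[str, set]) -> PositionPartition:
    """Partition two positions' pattern sets into shared and exclusive
    parts; |A only| = |A| - |shared| and likewise for B."""
    if len(patterns_by_position) != 2:
        raise ValueError(
            f"exactly two positions required, got {sorted(patterns_by_position)}"
        )
    (pa, sa), (pb, sb) = sorted(patterns_by_position.items())
    shared = sa & sb
    return PositionPartition(pa, pb, shared, sa - shared, sb - shared)


def patterns_by_position(ups: UniquePatternSet) -> dict[str, set[Pattern]]:
    """Split a unique union by the positions of its provenance corpora."""
    out: dict[str, set[Pattern]] = {}
    for pattern, records in ups.provenance.items():
        for _, _, position, _ in records:
            out.setdefault(position, set()).add(pattern)
    return out


def overlap_report_frame(report: OverlapReport) -> pd.DataFrame:
    """Tabular view of the full overlap: pattern, per-side frequency rank."""
    rows = [
        (p.items, report.freqs_a[p], report.ranks_a[p],
         report.freqs_b[p], report.ranks_b[p])
        for p in sorted(report.overlap)
    ]
    return pd.DataFrame(
        rows, columns=["pattern", "freq_a", "rank_a", "freq_b", "rank_b"]
    )
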