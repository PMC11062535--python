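"""The three pattern miners and their brute-force reference oracles.

Patterns come in three flavours, one per miner:

* **contiguous** — substrings of movement sequences, mined closed with a
  length cap (the LCCspm route);
* **subsequence** — longest common subsequences of clustered sequences
  (the SMP/LCS route);
* **itemset** — unordered duplicate-free character sets mined closed
  (the AprioriClose route).

Support is sequence-level throughout: the fraction of sequences in a
player-match corpus containing at least one occurrence of the pattern.
A pattern is *closed* when no frequent super-pattern has the same
support count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import edlib
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering

from .discretize import DiscreteSequenceSet

PATTERN_KINDS = ("contiguous", "subsequence", "itemset")
ALGORITHMS = ("LCCspm", "LCS", "AprioriClose")
#: Which pattern kind each miner produces.
KIND_OF_ALGORITHM = {"LCCspm": "contiguous", "LCS": "subsequence", "AprioriClose": "itemset"}

DEFAULT_MINSUP = 0.05
DEFAULT_MAX_LEN = 20
DEFAULT_N_CLUSTERS = 25

#: Slack for "support_count / n >= minsup" so exact fractions are not lost
#: to floating-point representation.
_SUPPORT_TOL = 1e-9


@dataclass(frozen=True, order=True)
class Pattern:
    """Pattern identity: its kind plus its items.

    ``items`` is the ordered character string for contiguous/subsequence
    patterns and the lexicographically sorted duplicate-free character
    string for itemsets.
    """

    kind: str
    items: str

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not self.items:
            raise ValueError("a pattern must have at least one item")
        if self.kind == "itemset" and list(self.items) != sorted(set(self.items)):
            raise ValueError("itemset items must be strictly increasing")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class SupportedPattern:
    pattern: Pattern
    support_count: int
    relative_support: float

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("support count must be >= 1")
        if not (0 < self.relative_support <= 1 + _SUPPORT_TOL):
            raise ValueError("relative support must lie in (0, 1]")


@dataclass
class PatternSet:
    """Mined patterns of one algorithm on one player-match corpus."""

    algorithm: str
    player_id: str
    match_id: str
    position: str
    patterns: list[SupportedPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm tag {self.algorithm!r}")
        keys = [sp.pattern for sp in self.patterns]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate patterns within a pattern set")

    def __len__(self) -> int:
        return len(self.patterns)

    def pattern_keys(self) -> set[Pattern]:
        return {sp.pattern for sp in self.patterns}

    def support_of(self, pattern: Pattern) -> int | None:
        for sp in self.patterns:
            if sp.pattern == pattern:
                return sp.support_count
        return None

    @property
    def corpus_id(self) -> tuple[str, str, str]:
        return (self.player_id, self.match_id, self.position)


@dataclass
class MiningConfig:
    """Mining parameters: 5% support and a 20-item cap (2 s at 10 Hz) by
    default; ``n_clusters`` applies to the LCS stage only."""

    minsup: float = DEFAULT_MINSUP
    max_len: int = DEFAULT_MAX_LEN
    n_clusters: int = DEFAULT_N_CLUSTERS

    def __post_init__(self) -> None:
        if not (0 < self.minsup <= 1):
            raise ValueError(f"minsup must lie in (0, 1], got {self.minsup}")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def _corpus_symbols(corpus: DiscreteSequenceSet | Sequence[str]) -> list[str]:
    if isinstance(corpus, DiscreteSequenceSet):
        return corpus.symbols
    return list(corpus)


def _corpus_meta(corpus) -> tuple[str, str, str]:
    if isinstance(corpus, DiscreteSequenceSet):
        return corpus.corpus_id
    return ("", "", "")


def _make_set(algorithm, corpus, counts: dict[str, int], n: int, kind: str) -> PatternSet:
    pid, mid, pos = _corpus_meta(corpus)
    patterns = [
        SupportedPattern(Pattern(kind, items), c, c / n)
        for items, c in sorted(counts.items())
    ]
    return PatternSet(algorithm, pid, mid, pos, patterns)


# ---------------------------------------------------------------------------
# Closed contiguous mining (LCCspm)

def lccspm_mine(corpus, minsup: float = DEFAULT_MINSUP,
                max_len: int = DEFAULT_MAX_LEN) -> PatternSet:
    """Length-capped closed contiguous pattern mining.

    Returns every substring of length <= ``max_len`` contained in at least
    ``minsup`` of the corpus sequences and closed within the frequent set
    (patterns at the cap cannot be extended, so they are closed when
    frequent). Level-wise search: a (k+1)-substring can only be frequent
    at positions whose k-prefix is frequent.
    """
    seqs = _corpus_symbols(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    n = len(seqs)
    threshold = minsup * n - _SUPPORT_TOL
    frequent: dict[str, int] = {}
    alive: list[list[int]] = [list(range(len(s))) for s in seqs]
    k = 0
    while k < max_len and any(alive):
        k += 1
        level = Counter()
        per_seq = []
        for s, pos in zip(seqs, alive):
            pats = {s[i : i + k] for i in pos if i + k <= len(s)}
            per_seq.append(pats)
            level.update(pats)
        freq_k = {p: c for p, c in level.items() if c >= threshold}
        frequent.update(freq_k)
        if not freq_k:
            break
        alive = [
            [i for i in pos if i + k <= len(s) and s[i : i + k] in freq_k]
            for s, pos in zip(seqs, alive)
        ]
    closed = _closed_contiguous(frequent)
    return _make_set("LCCspm", corpus, closed, n, "contiguous")


def _closed_contiguous(frequent: dict[str, int]) -> dict[str, int]:
    """Drop patterns with a frequent one-character extension of equal
    support; equal-support chains make this equivalent to full closure."""
    non_closed = set()
    for q, c in frequent.items():
        if len(q) >= 2:
            for sub in (q[:-1], q[1:]):
                if frequent.get(sub) == c:
                    non_closed.add(sub)
    return {p: c for p, c in frequent.items() if p not in non_closed}


def lccspm_oracle(corpus, minsup: float = DEFAULT_MINSUP,
                  max_len: int = DEFAULT_MAX_LEN) -> PatternSet:
    """Brute-force reference: enumerate every substring of length <=
    ``max_len``, count sequence support, filter, then full pairwise
    closure. Refuses corpora above 10^4 total symbols."""
    seqs = _corpus_symbols(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    if sum(len(s) for s in seqs) > 10_000:
        raise ValueError("oracle guard: corpus too large for brute force")
    n = len(seqs)
    threshold = minsup * n - _SUPPORT_TOL
    counts = Counter()
    for s in seqs:
        subs = {
            s[i : i + L]
            for L in range(1, min(max_len, len(s)) + 1)
            for i in range(len(s) - L + 1)
        }
        counts.update(subs)
    frequent = {p: c for p, c in counts.items() if c >= threshold}
    closed = {}
    for p, c in frequent.items():
        if any(len(q) > len(p) and p in q and cq == c for q, cq in frequent.items()):
            continue
        closed[p] = c
    return _make_set("LCCspm", corpus, closed, n, "contiguous")


# ---------------------------------------------------------------------------
# Longest common subsequence (SMP/LCS stage)

def lcs_pair(s: str, t: str) -> str:
    """One longest common subsequence of ``s`` and ``t``.

    Deterministic: equal characters are always matched, and on a tied
    backtrack step the earlier characters of the first argument are
    preferred (the backtrack moves in ``s``).
    """
    if not s or not t:
        return ""
    m, n = len(s), len(t)
    tb = np.frombuffer(t.encode("latin-1"), dtype=np.uint8)
    sb = np.frombuffer(s.encode("latin-1"), dtype=np.uint8)
    L = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        eq = tb == sb[i - 1]
        # Row recurrence collapses to a running maximum of candidates.
        cand = np.where(eq, L[i - 1, :-1] + 1, L[i - 1, 1:])
        L[i, 1:] = np.maximum.accumulate(cand)
    out = []
    i, j = m, n
    while i > 0 and j > 0:
        if s[i - 1] == t[j - 1] and L[i, j] == L[i - 1, j - 1] + 1:
            out.append(s[i - 1])
            i -= 1
            j -= 1
        elif L[i - 1, j] >= L[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return "".join(reversed(out))


def is_subsequence(pattern: str, s: str) -> bool:
    it = iter(s)
    return all(ch in it for ch in pattern)


def normalized_edit_distance(s: str, t: str) -> float:
    if not s and not t:
        return 0.0
    d = edlib.align(s, t, task="distance")["editDistance"]
    return d / max(len(s), len(t))


def smp_lcs_mine(corpus, n_clusters: int = DEFAULT_N_CLUSTERS) -> PatternSet:
    """LCS patterns via the cluster-then-fold route.

    Sequences are clustered into ``min(n_clusters, |corpus|)`` groups by
    complete-linkage agglomerative clustering on normalized edit distance;
    within each cluster the members (ordered by descending length, then
    lexicographically) are folded pairwise through :func:`lcs_pair`.
    Support counts corpus sequences containing the result as a
    subsequence. The >20-item cap is applied downstream by
    :func:`filter_max_items`, mirroring the shared post-filter.
    """
    seqs = _corpus_symbols(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    n = len(seqs)
    k = min(n_clusters, n)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = normalized_edit_distance(seqs[i], seqs[j])
        labels = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="complete"
        ).fit_predict(D)
    counts: dict[str, int] = {}
    for c in range(k):
        members = sorted(
            (seqs[i] for i in np.flatnonzero(labels == c)),
            key=lambda s: (-len(s), s),
        )
        common = members[0]
        for s in members[1:]:
            common = lcs_pair(common, s)
            if not common:
                break
        if common and common not in counts:
            counts[common] = sum(1 for s in seqs if is_subsequence(common, s))
    return _make_set("LCS", corpus, counts, n, "subsequence")


# ---------------------------------------------------------------------------
# Closed itemset mining (AprioriClose)

def aprioriclose_mine(corpus, minsup: float = DEFAULT_MINSUP) -> PatternSet:
    """Frequent closed itemsets over the distinct characters of each
    sequence, items sorted lexicographically within each pattern.

    Enumerates closed sets directly by prefix-preserving closure extension
    (each closed set is generated exactly once from its tidset closure),
    which sidesteps the combinatorial blowup of the plain frequent-set
    lattice on long sequences.
    """
    seqs = _corpus_symbols(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    n = len(seqs)
    threshold = minsup * n - _SUPPORT_TOL
    trans = [frozenset(s) for s in seqs]
    items = sorted(set().union(*trans))
    order = {ch: i for i, ch in enumerate(items)}
    tids = {
        ch: frozenset(i for i, t in enumerate(trans) if ch in t) for ch in items
    }
    out: dict[str, int] = {}

    def closure_of(tidset: frozenset[int]) -> frozenset[str]:
        inter: set[str] | None = None
        for t in tidset:
            inter = set(trans[t]) if inter is None else inter & trans[t]
            if not inter:
                break
        return frozenset(inter or ())

    def extend(P: frozenset[str], T: frozenset[int], limit: int) -> None:
        for ch in items:
            if order[ch] <= limit or ch in P:
                continue
            T2 = T & tids[ch]
            if len(T2) < threshold:
                continue
            C = closure_of(T2)
            # Prefix-preservation: the closure may only add items beyond ch.
            if any(x not in P and order[x] < order[ch] for x in C):
                continue
            out["".join(sorted(C))] = len(T2)
            extend(C, T2, order[ch])

    all_tids = frozenset(range(n))
    root = closure_of(all_tids)
    if root and n >= threshold:
        out["".join(sorted(root))] = n
    extend(root, all_tids, -1)
    return _make_set("AprioriClose", corpus, out, n, "itemset")


def aprioriclose_oracle(corpus, minsup: float = DEFAULT_MINSUP) -> PatternSet:
    """Powerset-enumeration reference for closed frequent itemsets.
    Refuses corpora whose observed alphabet exceeds 20 symbols."""
    seqs = _corpus_symbols(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    n = len(seqs)
    threshold = minsup * n - _SUPPORT_TOL
    items = sorted(set().union(*(set(s) for s in seqs)))
    if len(items) > 20:
        raise ValueError("oracle guard: alphabet too large for powerset enumeration")
    bit = {ch: 1 << i for i, ch in enumerate(items)}
    tmasks = [sum(bit[ch] for ch in set(s)) for s in seqs]
    support = {}
    for mask in range(1, 1 << len(items)):
        c = sum(1 for t in tmasks if t & mask == mask)
        if c >= threshold:
            support[mask] = c
    closed = {}
    for mask, c in support.items():
        if any(
            support.get(mask | b) == c for ch, b in bit.items() if not mask & b
        ):
            continue
        key = "".join(ch for ch in items if mask & bit[ch])
        closed[key] = c
    return _make_set("AprioriClose", corpus, closed, n, "itemset")


# ---------------------------------------------------------------------------
# Post-processing

def filter_max_items(ps: PatternSet, max_items: int = DEFAULT_MAX_LEN) -> PatternSet:
    """Remove patterns with more than ``max_items`` items; supports untouched."""
    return PatternSet(
        ps.algorithm, ps.player_id, ps.match_id, ps.position,
        [sp for sp in ps.patterns if len(sp.pattern) <= max_items],
    )


@dataclass
class UniquePatternSet:
    """Duplicate-free union of per-corpus pattern sets of one algorithm.

    ``provenance`` maps each unique pattern to the list of
    (player_id, match_id, position, support_count) records of the corpora
    where it was extracted; its length is the pattern's cross-corpus
    extraction frequency (the ranking used downstream).
    """

    algorithm: str
    provenance: dict[Pattern, list[tuple[str, str, str, int]]]

    def __len__(self) -> int:
        return len(self.provenance)

    def pattern_keys(self) -> set[Pattern]:
        return set(self.provenance)

    def frequency(self, pattern: Pattern) -> int:
        return len(self.provenance[pattern])


def union_unique(pattern_sets: Iterable[PatternSet], algorithm: str) -> UniquePatternSet:
    """Mathematical union of per-corpus pattern sets with provenance."""
    prov: dict[Pattern, list[tuple[str, str, str, int]]] = {}
    for ps in pattern_sets:
        if ps.algorithm != algorithm:
            raise ValueError(
                f"pattern set tagged {ps.algorithm!r} cannot join a {algorithm!r} union"
            )
        for sp in ps.patterns:
            prov.setdefault(sp.pattern, []).append(
                (ps.player_id, ps.match_id, ps.position, sp.support_count)
            )
    return UniquePatternSet(algorithm, prov)


# ---------------------------------------------------------------------------
# Estimator-style wrappers

class _BaseMiner(BaseEstimator):
    """Shared scaffolding: ``mine`` one corpus; ``fit`` a list of corpora,
    storing per-corpus sets, the filtered sets and their unique union."""

    algorithm: str = ""

    def mine(self, corpus) -> PatternSet:  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X: Sequence[DiscreteSequenceSet], y=None):
        sets = [filter_max_items(self.mine(c), self._cap()) for c in X]
        self.pattern_sets_ = sets
        self.union_ = union_unique(sets, self.algorithm)
        return self

    def _cap(self) -> int:
        return getattr(self, "max_len", DEFAULT_MAX_LEN)


class LCCspmMiner(_BaseMiner):
    """Closed contiguous pattern miner (support + length parameters)."""

    algorithm = "LCCspm"

    def __init__(self, minsup: float = DEFAULT_MINSUP, max_len: int = DEFAULT_MAX_LEN):
        self.minsup = minsup
        self.max_len = max_len

    def mine(self, corpus) -> PatternSet:
        return lccspm_mine(corpus, self.minsup, self.max_len)


class SmpLcsMiner(_BaseMiner):
    """Cluster-then-fold longest-common-subsequence miner."""

    algorithm = "LCS"

    def __init__(self, n_clusters: int = DEFAULT_N_CLUSTERS, max_len: int = DEFAULT_MAX_LEN):
        self.n_clusters = n_clusters
        self.max_len = max_len

    def mine(self, corpus) -> PatternSet:
        return smp_lcs_mine(corpus, self.n_clusters)


class AprioriCloseMiner(_BaseMiner):
    """Frequent closed itemset miner."""

    algorithm = "AprioriClose"

    def __init__(self, minsup: float = DEFAULT_MINSUP, max_len: int = DEFAULT_MAX_LEN):
        self.minsup = minsup
        self.max_len = max_len

    def mine(self, corpus) -> PatternSet:
        return aprioriclose_mine(corpus, self.minsup)


MINERS = {"lccspm": LCCspmMiner, "lcs": SmpLcsMiner, "aprioriclose": AprioriCloseMiner}


# ---------------------------------------------------------------------------
# Pattern TSV dialects

_PATTERN_COLUMNS = [
    "algorithm", "kind", "items", "support_count", "relative_support",
    "player_id", "match_id", "position",
]


def write_pattern_sets(pattern_sets: Iterable[PatternSet], path) -> None:
    rows = [
        (ps.algorithm, sp.pattern.kind, sp.pattern.items, sp.support_count,
         sp.relative_support, ps.player_id, ps.match_id, ps.position)
        for ps in pattern_sets
        for sp in ps.patterns
    ]
    pd.DataFrame(rows, columns=_PATTERN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pattern_sets(path) -> list[PatternSet]:
    df = pd.read_csv(path, sep="\t", dtype={"player_id": str, "match_id": str})
    out = []
    for (alg, pid, mid, pos), grp in df.groupby(
        ["algorithm", "player_id", "match_id", "position"], sort=True
    ):
        patterns = [
            SupportedPattern(Pattern(r.kind, str(r.items)), int(r.support_count),
                             float(r.relative_support))
            for r in grp.itertuples()
        ]
        out.append(PatternSet(alg, str(pid), str(mid), str(pos), patterns))
    return out


def write_union(union: UniquePatternSet, path) -> None:
    rows = [
        (union.algorithm, p.kind, p.items, len(records),
         ";".join(f"{pid}|{mid}|{pos}|{sup}" for pid, mid, pos, sup in records))
        for p, records in sorted(union.provenance.items())
    ]
    pd.DataFrame(
        rows, columns=["algorithm", "kind", "items", "n_corpora", "provenance"]
    ).to_csv(path, sep="\t", index=False)


def read_union(path) -> UniquePatternSet:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"union file {path} holds no patterns")
    algorithm = df["algorithm"].iloc[0]
    prov: dict[Pattern, list[tuple[str, str, str, int]]] = {}
    for r in df.itertuples():
        records = []
        for chunk in str(r.provenance).split(";"):
            pid, mid, pos, sup = chunk.split("|")
            records.append((pid, mid, pos, int(sup)))
        prov[Pattern(r.kind, str(r.items))] = records
    return UniquePatternSet(algorithm, prov)
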