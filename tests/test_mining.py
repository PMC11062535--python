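"""Miners vs. brute-force oracles, closure, support and union semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movemine import (
    AprioriCloseMiner,
    LCCspmMiner,
    MiningConfig,
    Pattern,
    PatternSet,
    SmpLcsMiner,
    SupportedPattern,
    aprioriclose_mine,
    aprioriclose_oracle,
    filter_max_items,
    lccspm_mine,
    lccspm_oracle,
    lcs_pair,
    smp_lcs_mine,
    union_unique,
)
from movemine.mining import is_subsequence, read_pattern_sets, read_union, write_pattern_sets, write_union

from conftest import make_corpus, random_corpora


def as_dict(ps: PatternSet) -> dict:
    return {sp.pattern.items: sp.support_count for sp in ps.patterns}


def lcs_length_oracle(s: str, t: str) -> int:
    """Plain quadratic DP, kept independent of the production path."""
    prev = [0] * (len(t) + 1)
    for ch in s:
        cur = [0]
        for j, cht in enumerate(t, 1):
            cur.append(prev[j - 1] + 1 if ch == cht else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


class TestLccspm:
    def test_two_sequence_example(self):
        assert as_dict(lccspm_mine(["abab", "abc"], 1.0, 2)) == {"ab": 2}

    def test_single_symbol_corpus(self):
        assert as_dict(lccspm_mine(["e"], 0.5, 20)) == {"e": 1}

    def test_worked_sequence_closes_to_its_trigrams(self):
        got = as_dict(lccspm_mine(["ijfeikhddb"], 1.0, 3))
        trigrams = {"ijf", "jfe", "fei", "eik", "ikh", "khd", "hdd", "ddb"}
        assert got == {t: 1 for t in trigrams}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            lccspm_mine([], 0.5, 20)

    def test_minsup_above_top_support_yields_empty(self):
        assert as_dict(lccspm_mine(["ab", "cd"], 1.0, 20)) == {}
        assert as_dict(lccspm_oracle(["ab", "cd"], 1.0, 20)) == {}

    def test_matches_oracle_on_random_corpora(self, rng):
        corpora = random_corpora(rng, 60, "abcde", max_seqs=8, max_len=25)
        for corpus in corpora:
            minsup = float(rng.choice([0.2, 0.5, 1.0]))
            max_len = int(rng.integers(1, 8))
            assert as_dict(lccspm_mine(corpus, minsup, max_len)) == as_dict(
                lccspm_oracle(corpus, minsup, max_len)
            )

    def test_output_patterns_are_frequent_and_mutually_closed(self, rng):
        corpus = random_corpora(rng, 1, "abc", max_seqs=10, max_len=20)[0]
        ps = lccspm_mine(corpus, 0.3, 6)
        n = len(corpus)
        got = as_dict(ps)
        for items, c in got.items():
            assert c == sum(1 for s in corpus if items in s)
            assert c / n >= 0.3 - 1e-9
            for other, c2 in got.items():
                if other != items and items in other:
                    assert c2 != c  # closure: no equal-support superpattern

    def test_anti_monotonicity_of_the_frequent_set(self, rng):
        corpus = random_corpora(rng, 1, "abcd", max_seqs=8, max_len=20, min_len=3)[0]
        n = len(corpus)

        def frequent(minsup, max_len):
            out = set()
            for s in corpus:
                for L in range(1, max_len + 1):
                    for i in range(len(s) - L + 1):
                        out.add(s[i:i + L])
            return {
                p for p in out
                if sum(1 for s in corpus if p in s) / n >= minsup - 1e-9
            }

        # raising minsup never adds frequent patterns
        assert frequent(0.8, 5) <= frequent(0.4, 5)
        # raising the cap never removes short frequent patterns
        assert frequent(0.4, 5) <= frequent(0.4, 8)

    def test_oracle_guard_refuses_large_corpora(self):
        with pytest.raises(ValueError, match="guard"):
            lccspm_oracle(["a" * 6000, "b" * 6000], 0.5, 5)


class TestLcsPair:
    def test_identity_and_disjoint(self):
        assert lcs_pair("abc", "abc") == "abc"
        assert lcs_pair("abc", "xyz") == ""

    def test_classic_example_has_dp_length(self):
        out = lcs_pair("ABCBDAB", "BDCABA")
        assert len(out) == 4
        assert is_subsequence(out, "ABCBDAB") and is_subsequence(out, "BDCABA")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="abcd", max_size=25), st.text(alphabet="abcd", max_size=25))
    def test_output_is_common_subsequence_of_dp_length(self, s, t):
        out = lcs_pair(s, t)
        assert is_subsequence(out, s) and is_subsequence(out, t)
        assert len(out) == lcs_length_oracle(s, t)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="abc", max_size=30))
    def test_self_lcs_is_identity(self, s):
        assert lcs_pair(s, s) == s


class TestSmpLcs:
    def test_identical_pair_single_cluster_returns_the_sequence(self):
        ps = smp_lcs_mine(["uuvuv", "uuvuv"], n_clusters=1)
        assert as_dict(ps) == {"uuvuv": 2}

    def test_singleton_corpus_returns_the_sequence(self):
        assert as_dict(smp_lcs_mine(["efef"], n_clusters=25)) == {"efef": 1}

    def test_fold_of_two_sequences_has_dp_length(self):
        ps = smp_lcs_mine(["ABCBDAB", "BDCABA"], n_clusters=1)
        (items,) = as_dict(ps)
        assert len(items) == 4

    def test_supports_count_subsequence_containment(self):
        ps = smp_lcs_mine(["abab", "abba", "ab"], n_clusters=2)
        for sp in ps.patterns:
            expected = sum(
                1 for s in ["abab", "abba", "ab"] if is_subsequence(sp.pattern.items, s)
            )
            assert sp.support_count == expected

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            smp_lcs_mine([], 5)


class TestAprioriClose:
    def test_three_sequence_example(self):
        got = as_dict(aprioriclose_mine(["abc", "ab", "bc"], 2 / 3))
        assert got == {"b": 3, "ab": 2, "bc": 2}

    def test_single_item_corpus(self):
        assert as_dict(aprioriclose_mine(["a"], 1.0)) == {"a": 1}

    def test_no_universal_item_at_full_support(self):
        assert as_dict(aprioriclose_mine(["ab", "cd"], 1.0)) == {}

    def test_single_sequence_collapses_to_one_closed_set(self):
        got = as_dict(aprioriclose_mine(["bca"], 1.0))
        assert got == {"abc": 1}

    def test_items_are_sorted_and_duplicate_free(self, rng):
        corpus = random_corpora(rng, 1, "fedcba", max_seqs=8, max_len=15)[0]
        for sp in aprioriclose_mine(corpus, 0.25).patterns:
            items = sp.pattern.items
            assert list(items) == sorted(set(items))

    def test_matches_oracle_on_random_corpora(self, rng):
        corpora = random_corpora(rng, 60, "abcdefgh", max_seqs=8, max_len=12)
        for corpus in corpora:
            minsup = float(rng.choice([0.25, 0.5, 1.0]))
            assert as_dict(aprioriclose_mine(corpus, minsup)) == as_dict(
                aprioriclose_oracle(corpus, minsup)
            )

    def test_oracle_guard_refuses_wide_alphabets(self):
        import string

        with pytest.raises(ValueError, match="guard"):
            aprioriclose_oracle([string.ascii_letters[:25]], 0.5)


class TestFilterAndUnion:
    def test_filter_drops_only_oversize_patterns(self):
        ps = PatternSet("LCCspm", "p", "m", "hooker", [
            SupportedPattern(Pattern("contiguous", "a" * k), 1, 0.5)
            for k in (5, 20, 21)
        ])
        kept = filter_max_items(ps, 20)
        assert sorted(len(sp.pattern) for sp in kept.patterns) == [5, 20]

    def test_filter_identity_and_empty(self):
        empty = PatternSet("LCS", "p", "m", "hooker", [])
        assert len(filter_max_items(empty)) == 0
        ps = PatternSet("LCS", "p", "m", "hooker", [
            SupportedPattern(Pattern("subsequence", "ab"), 1, 1.0)
        ])
        assert as_dict(filter_max_items(ps)) == as_dict(ps)

    def test_union_records_provenance(self):
        a = lccspm_mine(make_corpus(["abab", "abc"]), 1.0, 2)
        b = lccspm_mine(make_corpus(["abcd"], match="m1"), 1.0, 2)
        u = union_unique([a, b], "LCCspm")
        ab = Pattern("contiguous", "ab")
        assert u.frequency(ab) == 2
        assert len(u) == len(a.pattern_keys() | b.pattern_keys())

    def test_union_of_disjoint_sets_sums_sizes(self):
        a = lccspm_mine(make_corpus(["ee"]), 1.0, 2)
        b = lccspm_mine(make_corpus(["ff"], match="m1"), 1.0, 2)
        u = union_unique([a, b], "LCCspm")
        assert len(u) == len(a) + len(b)

    def test_mixed_algorithm_tags_rejected(self):
        a = lccspm_mine(make_corpus(["ab"]), 1.0, 2)
        b = aprioriclose_mine(make_corpus(["ab"]), 1.0)
        with pytest.raises(ValueError):
            union_unique([a, b], "LCCspm")

    def test_pattern_identity_includes_kind(self):
        assert Pattern("contiguous", "ab") != Pattern("itemset", "ab")

    def test_itemset_pattern_validates_item_order(self):
        with pytest.raises(ValueError):
            Pattern("itemset", "ba")


class TestMinerEstimators:
    def test_fit_builds_filtered_sets_and_union(self):
        corpora = [make_corpus(["abab", "abc"]), make_corpus(["abab"], match="m1")]
        miner = LCCspmMiner(minsup=1.0, max_len=2).fit(corpora)
        assert len(miner.pattern_sets_) == 2
        assert Pattern("contiguous", "ab") in miner.union_.pattern_keys()
        assert miner.get_params() == {"minsup": 1.0, "max_len": 2}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MiningConfig(minsup=1.01)
        with pytest.raises(ValueError):
            MiningConfig(max_len=0)

    def test_all_three_miners_share_the_interface(self):
        corpora = [make_corpus(["uuv", "uuvf"])]
        for cls in (LCCspmMiner, SmpLcsMiner, AprioriCloseMiner):
            m = cls().fit(corpora)
            assert m.union_.algorithm == m.algorithm


class TestPatternIo:
    def test_pattern_tsv_round_trip(self, tmp_path):
        sets = [
            lccspm_mine(make_corpus(["abab", "abc"]), 0.5, 3),
            lccspm_mine(make_corpus(["abc"], match="m1"), 1.0, 3),
        ]
        path = tmp_path / "patterns.tsv"
        write_pattern_sets(sets, path)
        back = read_pattern_sets(path)
        assert {ps.corpus_id: as_dict(ps) for ps in back} == {
            ps.corpus_id: as_dict(ps) for ps in sets
        }

    def test_union_tsv_round_trip(self, tmp_path):
        sets = [
            lccspm_mine(make_corpus(["abab", "abc"]), 0.5, 3),
            lccspm_mine(make_corpus(["abc"], match="m1"), 1.0, 3),
        ]
        u = union_unique(sets, "LCCspm")
        path = tmp_path / "union.tsv"
        write_union(u, path)
        back = read_union(path)
        assert back.algorithm == "LCCspm"
        assert back.provenance == u.provenance
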