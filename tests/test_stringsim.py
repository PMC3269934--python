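"""Jaro, Jaro-Winkler and SoftTFIDF.

The character metrics are checked against an independently written
reference implementation (a straightforward transliteration of the
textbook definition, structured differently from the package's code) and
against hand-evaluated values; SoftTFIDF is checked against a
brute-force TF-IDF cosine when the secondary threshold is 1.0.
"""

from __future__ import annotations

import math
import random
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiminer.stringsim import (
    CorpusStats,
    SimilarityConfig,
    build_corpus_stats,
    jaro,
    jaro_winkler,
    soft_tfidf,
)

# --------------------------------------------------------------------------
# independent reference implementation (oracle)


def ref_jaro(s: str, t: str) -> float:
    if not s and not t:
        return 1.0
    if not s or not t:
        return 0.0
    window = max(max(len(s), len(t)) // 2 - 1, 0)
    t_used = set()
    s_matches = []
    for i, c in enumerate(s):
        for j in range(max(0, i - window), min(len(t), i + window + 1)):
            if j not in t_used and t[j] == c:
                t_used.add(j)
                s_matches.append((i, j))
                break
    m = len(s_matches)
    if m == 0:
        return 0.0
    t_order = [j for _i, j in s_matches]
    t_sorted_chars = [t[j] for j in sorted(t_order)]
    s_chars = [s[i] for i, _j in s_matches]
    # mismatched matched-positions halved, rounded down — the convention
    # of the original implementation and of the common C ports
    half = sum(1 for a, b in zip(s_chars, t_sorted_chars) if a != b)
    transpositions = half // 2
    return (m / len(s) + m / len(t) + (m - transpositions) / m) / 3


def ref_jaro_winkler(s: str, t: str, p: float = 0.1, max_l: int = 4) -> float:
    j = ref_jaro(s, t)
    l = 0
    for a, b in zip(s[:max_l], t[:max_l]):
        if a != b:
            break
        l += 1
    return j + l * p * (1 - j)


# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s,t,expected",
    [
        ("abc", "abc", 1.0),
        ("fax", "fac", 0.7778),
        ("abc", "xyz", 0.0),
        ("", "", 1.0),
        ("a", "", 0.0),
    ],
)
def test_jaro_known_values(s, t, expected):
    assert jaro(s, t) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "s,t,expected",
    [
        ("MARTHA", "MARHTA", 0.9611),
        ("fax", "fac", 0.8222),
        ("identical", "identical", 1.0),
    ],
)
def test_jaro_winkler_known_values(s, t, expected):
    assert jaro_winkler(s, t) == pytest.approx(expected, abs=1e-4)


def test_jaro_metrics_match_reference_on_random_pairs():
    rng = random.Random(42)
    alphabet = string.ascii_lowercase[:8]
    for _ in range(1000):
        s = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 10)))
        t = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 10)))
        assert jaro(s, t) == pytest.approx(ref_jaro(s, t), abs=1e-12)
        assert jaro_winkler(s, t) == pytest.approx(ref_jaro_winkler(s, t), abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="abcdef", max_size=12), st.text(alphabet="abcdef", max_size=12))
def test_jaro_winkler_dominates_jaro_and_both_bounded(s, t):
    j = jaro(s, t)
    jw = jaro_winkler(s, t)
    assert 0.0 <= j <= 1.0
    assert j <= jw <= 1.0
    assert jaro(t, s) == pytest.approx(j)
    assert jaro_winkler(t, s) == pytest.approx(jw)


# --------------------------------------------------------------------------


def test_corpus_stats_counting_and_unknown_rule():
    stats = build_corpus_stats([["anti", "tag"], ["anti", "bait"]])
    assert stats.doc_count == 2
    assert stats.df["anti"] == 2
    assert stats.df["tag"] == 1
    # a token absent everywhere gets the maximum idf (df treated as 1)
    assert stats.idf("never-seen") == pytest.approx(math.log(1 + 2 / 1))
    assert stats.idf("anti") == pytest.approx(math.log(1 + 2 / 2))


def test_corpus_stats_rejects_empty_collection():
    with pytest.raises(ValueError):
        build_corpus_stats([])


def test_single_doc_corpus_gives_uniform_idf():
    stats = build_corpus_stats([["a", "b", "c"]])
    assert stats.idf("a") == stats.idf("b") == stats.idf("c")


# --------------------------------------------------------------------------


def _random_bag(rng, vocab):
    return [rng.choice(vocab) for _ in range(rng.randint(1, 6))]


def _cosine(a, b, stats):
    import collections

    ca, cb = collections.Counter(a), collections.Counter(b)
    va = {w: c * stats.idf(w) for w, c in ca.items()}
    vb = {w: c * stats.idf(w) for w, c in cb.items()}
    dot = sum(va[w] * vb.get(w, 0.0) for w in va)
    na = math.sqrt(sum(x * x for x in va.values()))
    nb = math.sqrt(sum(x * x for x in vb.values()))
    return dot / (na * nb) if na and nb else 0.0


def test_soft_tfidf_equals_cosine_at_secondary_threshold_one():
    rng = random.Random(99)
    vocab = ["anti", "tag", "pull", "down", "hybrid", "assay", "blot", "gel"]
    stats = build_corpus_stats([_random_bag(rng, vocab) for _ in range(20)])
    cfg = SimilarityConfig(secondary_threshold=1.0)
    for _ in range(100):
        a, b = _random_bag(rng, vocab), _random_bag(rng, vocab)
        assert soft_tfidf(a, b, stats, cfg) == pytest.approx(
            _cosine(a, b, stats), abs=1e-9
        )


def test_soft_tfidf_identity_symmetry_and_range():
    rng = random.Random(5)
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon"]
    stats = build_corpus_stats([_random_bag(rng, vocab) for _ in range(10)])
    for _ in range(50):
        a, b = _random_bag(rng, vocab), _random_bag(rng, vocab)
        sab = soft_tfidf(a, b, stats)
        assert 0.0 <= sab <= 1.0
        assert sab == pytest.approx(soft_tfidf(b, a, stats))
        assert soft_tfidf(a, a, stats) == pytest.approx(1.0)


def test_soft_tfidf_empty_inputs_score_zero():
    stats = build_corpus_stats([["x"]])
    assert soft_tfidf([], ["x"], stats) == 0.0
    assert soft_tfidf(["x"], [], stats) == 0.0


def test_hyphen_split_variants_are_identical():
    # "pull down" vs "pull-down" after hyphen splitting and stop-token
    # removal share the same content tokens, hence score 1
    stats = build_corpus_stats([["pull", "down"], ["two", "hybrid"]])
    assert soft_tfidf(["pull", "down"], ["pull", "down"], stats) == pytest.approx(1.0)


def test_close_but_distinct_tokens_still_contribute():
    # near-identical tokens above the 0.85 secondary threshold count
    stats = build_corpus_stats([["fax", "machine"], ["fac", "assay"]])
    score = soft_tfidf(["fax"], ["fac"], stats)
    assert score == 0.0  # jw("fax","fac")=0.822 < 0.85: no close pair
    score2 = soft_tfidf(["antibodies"], ["anti"], stats)
    assert score2 > 0.0  # jw("antibodies","anti")=0.88 >= 0.85
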