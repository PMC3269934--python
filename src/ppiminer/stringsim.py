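"""Character- and token-level string similarity.

Implements the hybrid matching stack used for grounding noun/verb-phrase
chunks to ontology method names: the Jaro and Jaro-Winkler character
metrics, corpus TF-IDF statistics, and SoftTFIDF — a token-level cosine
in TF-IDF space that lets *approximately* equal tokens (as judged by a
secondary character metric above a threshold) contribute to the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "SimilarityConfig",
    "CorpusStats",
    "jaro",
    "jaro_winkler",
    "build_corpus_stats",
    "soft_tfidf",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Knobs for the hybrid similarity.

    secondary_threshold: minimum Jaro-Winkler for two tokens to count as
        "close" inside SoftTFIDF (0.85).
    candidate_threshold: minimum SoftTFIDF for a (chunk, name) pair to be
        retained as a classification candidate (0.50).
    """

    secondary_threshold: float = 0.85
    candidate_threshold: float = 0.50
    winkler_prefix_weight: float = 0.1
    winkler_max_prefix: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.secondary_threshold <= 1.0):
            raise ValueError("secondary_threshold must be in [0, 1]")
        if not (0.0 <= self.candidate_threshold <= 1.0):
            raise ValueError("candidate_threshold must be in [0, 1]")


def jaro(s: str, t: str) -> float:
    """Jaro similarity in [0, 1].

    Match window is floor(max(|s|, |t|) / 2) - 1; transpositions are
    counted over the matched character sequences. Two empty strings are
    defined to be identical (1.0).
    """
    if not s and not t:
        return 1.0
    if not s or not t:
        return 0.0
    if s == t:
        return 1.0
    window = max(len(s), len(t)) // 2 - 1
    s_matched = [False] * len(s)
    t_matched = [False] * len(t)
    matches = 0
    for i, ch in enumerate(s):
        lo = max(0, i - window)
        hi = min(len(t), i + window + 1)
        for j in range(lo, hi):
            if not t_matched[j] and t[j] == ch:
                s_matched[i] = True
                t_matched[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    s_seq = [ch for i, ch in enumerate(s) if s_matched[i]]
    t_seq = [ch for j, ch in enumerate(t) if t_matched[j]]
    half_transpositions = sum(a != b for a, b in zip(s_seq, t_seq))
    transpositions = half_transpositions // 2
    m = float(matches)
    return (m / len(s) + m / len(t) + (m - transpositions) / m) / 3.0


def jaro_winkler(s: str, t: str, config: SimilarityConfig | None = None) -> float:
    """Jaro-Winkler: Jaro boosted by a shared prefix of up to 4 characters.

    jw = jaro + l * p * (1 - jaro), so jw >= jaro always.
    """
    cfg = config or SimilarityConfig()
    base = jaro(s, t)
    prefix = 0
    for a, b in zip(s, t):
        if a != b or prefix >= cfg.winkler_max_prefix:
            break
        prefix += 1
    return base + prefix * cfg.winkler_prefix_weight * (1.0 - base)


@dataclass
class CorpusStats:
    """Document-frequency statistics backing TF-IDF weights.

    idf(t) = log(1 + doc_count / df(t)); a token never seen in the corpus
    is treated as df = 1, i.e. it receives the maximum idf.
    """

    doc_count: int
    df: Dict[str, int] = field(default_factory=dict)

    def idf(self, token: str) -> float:
        d = self.df.get(token, 1)
        return math.log(1.0 + self.doc_count / d)


def build_corpus_stats(token_bags: Iterable[Sequence[str]]) -> CorpusStats:
    """Count document frequencies over an iterable of token multisets."""
    df: Dict[str, int] = {}
    n = 0
    for bag in token_bags:
        n += 1
        for tok in set(bag):
            df[tok] = df.get(tok, 0) + 1
    if n == 0:
        raise ValueError("cannot build corpus statistics from an empty collection")
    return CorpusStats(doc_count=n, df=df)


def _weight_vector(tokens: Sequence[str], stats: CorpusStats) -> Dict[str, float]:
    tf: Dict[str, int] = {}
    for tok in tokens:
        tf[tok] = tf.get(tok, 0) + 1
    raw = {tok: count * stats.idf(tok) for tok, count in tf.items()}
    norm = math.sqrt(sum(w * w for w in raw.values()))
    if norm == 0.0:
        return {tok: 0.0 for tok in raw}
    return {tok: w / norm for tok, w in raw.items()}


def _directed_soft_tfidf(
    v_s: Mapping[str, float],
    v_t: Mapping[str, float],
    cfg: SimilarityConfig,
) -> float:
    """Sum over tokens of s of V(w,s) * V(w',t) * jw(w,w') where w' is
    w's best close partner in t (ties broken lexicographically)."""
    t_tokens = sorted(v_t)
    total = 0.0
    for w in v_s:
        best: Tuple[float, str] | None = None
        for w2 in t_tokens:
            sim = 1.0 if w == w2 else jaro_winkler(w, w2, cfg)
            if sim >= cfg.secondary_threshold:
                if best is None or sim > best[0]:
                    best = (sim, w2)
        if best is not None:
            total += v_s[w] * v_t[best[1]] * best[0]
    return total


def soft_tfidf(
    s_tokens: Sequence[str],
    t_tokens: Sequence[str],
    stats: CorpusStats,
    config: SimilarityConfig | None = None,
) -> float:
    """SoftTFIDF similarity of two token multisets in [0, 1].

    Each token carries an L2-normalised TF-IDF weight; tokens of one
    string pair with their best Jaro-Winkler partner in the other (only
    partners at or above the secondary threshold count). The score is the
    larger of the two directed sums, which makes it symmetric and makes
    it collapse to the plain TF-IDF cosine when the secondary threshold
    is 1.0 (exact token matches only).
    """
    cfg = config or SimilarityConfig()
    if not s_tokens or not t_tokens:
        return 0.0
    v_s = _weight_vector(s_tokens, stats)
    v_t = _weight_vector(t_tokens, stats)
    fwd = _directed_soft_tfidf(v_s, v_t, cfg)
    bwd = _directed_soft_tfidf(v_t, v_s, cfg)
    return min(1.0, max(0.0, fwd, bwd))
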