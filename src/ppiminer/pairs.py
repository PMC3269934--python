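"""Binary classification of (text chunk, method name) pairs.

Rather than training one model per interaction method, this approach
reduces the multi-label problem to a single binary decision: every NP/VP
chunk that is approximately similar (SoftTFIDF >= 0.5 with a
Jaro-Winkler secondary at 0.85) to a method name or synonym forms a
candidate pair p = {c, n}; one linear classifier decides, from the
chunk's context and the properties of the method concept, whether the
pair really evidences use of that method. All MI ids of positively
classified pairs are assigned to the document.

The feature families: local context words (10-token windows with signed
position, 50-token windows as a bag), neighbouring named entities (type
and text, five per side), counts of the method's names/synonyms in a
20-token window and document-wide, definition tokens keyed by their
TF-IDF rank, the enclosing section title, a MeSH flag tying the document
to frequent methods, the chunk/id strings and the similarity score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from ._sparse import csr32
from .corpus import Chunk, Document, section_of
from .ontology import MiMeshMapping, OntologyTerm, rank_definition_tokens
from .stringsim import CorpusStats, SimilarityConfig, soft_tfidf

__all__ = [
    "CandidatePair",
    "PairModel",
    "generate_candidates",
    "extract_pair_features",
    "label_training_pairs",
    "train_pair_model",
    "predict_document_labels",
    "train_bsvm",
    "predict_bsvm",
]

FeatureVector = Dict[str, float]


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    chunk: Chunk
    matched_name: str
    mi_id: str
    similarity: float


def _chunk_tokens(doc: Document, chunk: Chunk) -> List[str]:
    return [
        t.lemma
        for t in doc.tokens[chunk.token_start : chunk.token_end]
        if not t.is_stop
    ]


def _name_tokens(name: str) -> List[str]:
    from .corpus import tokenize

    return [t.lemma for t in tokenize(name) if not t.is_stop]


def prepare_name_index(
    terms: Sequence[OntologyTerm],
) -> List[Tuple[str, str, List[str]]]:
    """(mi_id, name string, name content tokens) for every name and
    synonym."""
    index = []
    for term in terms:
        for name in term.all_names():
            toks = _name_tokens(name)
            if toks:
                index.append((term.mi_id, name, toks))
    return index


def generate_candidates(
    doc: Document,
    terms: Sequence[OntologyTerm],
    stats: CorpusStats,
    config: SimilarityConfig | None = None,
    name_index: Optional[List[Tuple[str, str, List[str]]]] = None,
) -> List[CandidatePair]:
    """Compare every NP/VP chunk against every method name and synonym;
    keep pairs at or above the candidate threshold. For a given
    (chunk, MI id) only the best-scoring name is retained; output is
    ordered by document position, then MI id."""
    cfg = config or SimilarityConfig()
    index = name_index if name_index is not None else prepare_name_index(terms)
    pairs: Dict[Tuple[int, str], CandidatePair] = {}
    for ci, chunk in enumerate(doc.chunks):
        toks = _chunk_tokens(doc, chunk)
        if not toks:
            continue
        for mi_id, name, name_toks in index:
            score = soft_tfidf(toks, name_toks, stats, cfg)
            if score < cfg.candidate_threshold:
                continue
            key = (ci, mi_id)
            existing = pairs.get(key)
            if existing is None or score > existing.similarity:
                pairs[key] = CandidatePair(
                    doc_id=doc.doc_id,
                    chunk=chunk,
                    matched_name=name,
                    mi_id=mi_id,
                    similarity=score,
                )
    return sorted(pairs.values(), key=lambda p: (p.chunk.start, p.mi_id))


def _content_context(
    doc: Document, chunk: Chunk, side_window: int
) -> Tuple[List[Tuple[int, str]], List[Tuple[int, str]]]:
    """Content (non-stop) lemmas within ``side_window`` tokens on each
    side of the chunk, with signed distances; chunk-internal tokens are
    excluded."""
    left: List[Tuple[int, str]] = []
    i = chunk.token_start - 1
    dist = 1
    while i >= 0 and dist <= side_window:
        tok = doc.tokens[i]
        if not tok.is_stop:
            left.append((-dist, tok.lemma))
            dist += 1
        i -= 1
    right: List[Tuple[int, str]] = []
    i = chunk.token_end
    dist = 1
    while i < len(doc.tokens) and dist <= side_window:
        tok = doc.tokens[i]
        if not tok.is_stop:
            right.append((dist, tok.lemma))
            dist += 1
        i += 1
    return left, right


def _count_occurrences(haystack: Sequence[str], needle: Sequence[str]) -> int:
    if not needle or len(needle) > len(haystack):
        return 0
    n = len(needle)
    return sum(
        1
        for i in range(len(haystack) - n + 1)
        if list(haystack[i : i + n]) == list(needle)
    )


def extract_pair_features(
    pair: CandidatePair,
    doc: Document,
    term: OntologyTerm,
    mapping: MiMeshMapping,
) -> FeatureVector:
    feats: FeatureVector = {}
    chunk = pair.chunk

    # (1) local context: 10 per side with signed position, 50 per side as a bag
    left10, right10 = _content_context(doc, chunk, 10)
    for dist, lemma in left10 + right10:
        feats[f"ctx10[{dist}]={lemma}"] = 1.0
    left50, right50 = _content_context(doc, chunk, 50)
    for _dist, lemma in left50 + right50:
        feats[f"ctx50={lemma}"] = 1.0

    # (2) local NER context: 5 entities on each side, type and text
    before = [e for e in doc.entities if e.end <= chunk.start]
    after = [e for e in doc.entities if e.start >= chunk.end]
    for e in before[-5:] + after[:5]:
        feats[f"ne_type={e.etype}"] = 1.0
        feats[f"ne_text={e.surface.lower()}"] = 1.0

    # (3) MI synonym match: counts in a 20-token window and document-wide
    left20, right20 = _content_context(doc, chunk, 20)
    window_lemmas = [lemma for _d, lemma in left20] + [lemma for _d, lemma in right20]
    doc_lemmas = [t.lemma for t in doc.tokens if not t.is_stop]
    syn_local = syn_global = 0
    for name in term.all_names():
        toks = _name_tokens(name)
        syn_local += _count_occurrences(window_lemmas, toks)
        syn_global += _count_occurrences(doc_lemmas, toks)
    feats["synmatch_local"] = float(syn_local)
    feats["synmatch_global"] = float(syn_global)

    # (4) MI definition match: definition tokens keyed by TF-IDF rank
    window_set = set(window_lemmas)
    doc_set = set(doc_lemmas)
    for tok, rank in term.def_token_ranks.items():
        if tok in window_set:
            feats[f"defmatch_local_rank{rank}"] = 1.0
        if tok in doc_set:
            feats[f"defmatch_global_rank{rank}"] = 1.0

    # (5) section title of the enclosing section
    title = section_of(doc, chunk.start)
    feats[f"section={title or 'none'}"] = 1.0

    # (6) MeSH: document annotated with a MeSH term mapped from a
    # frequent MI id; and whether that id is this pair's id
    doc_mesh = {m.casefold() for m in doc.mesh_ids}
    for mi_id, (_tree, mesh_name) in mapping.entries.items():
        if mesh_name.casefold() in doc_mesh:
            feats["mesh_top_mapped"] = 1.0
            if mi_id == pair.mi_id:
                feats["mesh_matches_pair_id"] = 1.0

    # (7) other: chunk string, MI id identity, similarity score
    feats[f"chunk={doc.text[chunk.start:chunk.end].lower()}"] = 1.0
    feats[f"mi={pair.mi_id}"] = 1.0
    feats["similarity"] = float(pair.similarity)
    return feats


def label_training_pairs(
    doc: Document, pairs: Sequence[CandidatePair]
) -> List[int]:
    """A pair is positive iff its MI id is among the document's gold
    labels; an unlabelled document is a hard error."""
    if doc.gold_mi_ids is None:
        raise ValueError(f"document {doc.doc_id} has no gold MI labels")
    return [1 if p.mi_id in doc.gold_mi_ids else 0 for p in pairs]


@dataclass
class PairModel:
    """Linear decision function over sparse pair features:
    sign(w . x + b)."""

    vectorizer: DictVectorizer
    clf: LinearSVC

    @property
    def weights(self) -> Dict[str, float]:
        names = self.vectorizer.get_feature_names_out()
        return {n: float(w) for n, w in zip(names, self.clf.coef_[0]) if w != 0.0}

    @property
    def bias(self) -> float:
        return float(self.clf.intercept_[0])

    def decision_values(self, feature_dicts: Sequence[FeatureVector]) -> np.ndarray:
        X = csr32(self.vectorizer.transform(feature_dicts))
        return self.clf.decision_function(X)


def train_pair_model(
    instances: Sequence[Tuple[FeatureVector, int]], C: float = 16.0
) -> PairModel:
    """Fit an L2-regularised linear large-margin classifier. Candidate
    pairs are heavily imbalanced (hundreds of chunks per document, few
    gold methods), so classes are weighted by inverse frequency."""
    if C <= 0:
        raise ValueError("C must be positive")
    labels = {lab for _f, lab in instances}
    if len(labels) < 2:
        raise ValueError("training requires at least one instance of each class")
    vec = DictVectorizer(sparse=True)
    X = csr32(vec.fit_transform([f for f, _lab in instances]))
    y = np.array([lab for _f, lab in instances])
    clf = LinearSVC(C=C, class_weight="balanced", random_state=0, max_iter=20000, tol=1e-5)
    clf.fit(X, y)
    return PairModel(vectorizer=vec, clf=clf)


def predict_document_labels(
    doc: Document,
    pairs: Sequence[CandidatePair],
    model: PairModel,
    feature_fn=None,
) -> Set[str]:
    """Union of MI ids over pairs classified positive (decision value
    strictly greater than zero); invariant to candidate order."""
    if not pairs:
        return set()
    if feature_fn is None:
        raise ValueError("feature_fn building pair feature vectors is required")
    decisions = model.decision_values([feature_fn(p) for p in pairs])
    return {p.mi_id for p, d in zip(pairs, decisions) if d > 0}


# ---------------------------------------------------------------------------
# corpus-level convenience pipeline

def _term_lookup(terms: Sequence[OntologyTerm]) -> Dict[str, OntologyTerm]:
    return {t.mi_id: t for t in terms}


def _ensure_ranks(terms: Sequence[OntologyTerm], stats: CorpusStats) -> None:
    for t in terms:
        if not t.def_token_ranks and t.definition:
            rank_definition_tokens(t, stats)


def train_bsvm(
    docs: Sequence[Document],
    terms: Sequence[OntologyTerm],
    stats: CorpusStats,
    mapping: MiMeshMapping,
    config: SimilarityConfig | None = None,
    C: float = 16.0,
) -> PairModel:
    cfg = config or SimilarityConfig()
    _ensure_ranks(terms, stats)
    lookup = _term_lookup(terms)
    index = prepare_name_index(terms)
    instances: List[Tuple[FeatureVector, int]] = []
    for doc in docs:
        pairs = generate_candidates(doc, terms, stats, cfg, name_index=index)
        labels = label_training_pairs(doc, pairs)
        for pair, label in zip(pairs, labels):
            feats = extract_pair_features(pair, doc, lookup[pair.mi_id], mapping)
            instances.append((feats, label))
    return train_pair_model(instances, C=C)


def predict_bsvm(
    docs: Sequence[Document],
    model: PairModel,
    terms: Sequence[OntologyTerm],
    stats: CorpusStats,
    mapping: MiMeshMapping,
    config: SimilarityConfig | None = None,
) -> Dict[str, Set[str]]:
    cfg = config or SimilarityConfig()
    _ensure_ranks(terms, stats)
    lookup = _term_lookup(terms)
    index = prepare_name_index(terms)
    out: Dict[str, Set[str]] = {}
    for doc in docs:
        pairs = generate_candidates(doc, terms, stats, cfg, name_index=index)
        out[doc.doc_id] = predict_document_labels(
            doc,
            pairs,
            model,
            feature_fn=lambda p: extract_pair_features(p, doc, lookup[p.mi_id], mapping),
        )
    return out
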