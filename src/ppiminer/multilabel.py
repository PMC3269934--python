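"""One-vs-all multi-label document classification with thresholding.

One binary linear model per interaction method (only methods with at
least one positive training document get a model). Document scores —
probabilities for logistic regression, raw margins for the linear SVM —
are converted to label sets by comparing against a global or per-class
threshold tuned on held-out documents (objective: accuracy or F1; the
paper-motivated floor of 0.10 applies to LR probability thresholds).
Union and intersection ensembles combine label sets across systems.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from ._sparse import csr32
from .corpus import Document, section_of
from .ontology import OntologyTerm

__all__ = [
    "LabelScore",
    "ThresholdPolicy",
    "OvaModelSet",
    "extract_doc_features",
    "train_ova",
    "tune_thresholds",
    "predict_ova",
    "ensemble_union",
    "ensemble_intersect",
]

FeatureVector = Dict[str, float]

LR_FLOOR = 0.10


@dataclass(frozen=True)
class LabelScore:
    doc_id: str
    class_id: str
    score: float


@dataclass
class ThresholdPolicy:
    """Rule converting per-class scores to label sets: a label is
    assigned when score > threshold (strictly)."""

    mode: str = "global"  # "global" | "per_class"
    objective: str = "accuracy"  # "accuracy" | "f1"
    floor: Optional[float] = None
    values: Dict[str, float] = field(default_factory=dict)
    global_value: float = 0.0

    def threshold_for(self, class_id: str) -> float:
        if self.mode == "per_class":
            return self.values.get(class_id, self.global_value)
        return self.global_value


# ---------------------------------------------------------------------------
# features

def _char_ngrams(token: str, sizes=(2, 3, 4)) -> Set[str]:
    grams: Set[str] = set()
    for n in sizes:
        for i in range(len(token) - n + 1):
            grams.add(token[i : i + n])
    return grams


@dataclass
class DocProfile:
    """Per-document feature material shared across classes (computed
    once, intersected with each class's definition material)."""

    base: FeatureVector
    unigrams: Set[str]
    ngrams: Set[str]


def build_doc_profile(doc: Document) -> DocProfile:
    base: FeatureVector = {}
    token_starts = [t.start for t in doc.tokens]
    for e in doc.entities:
        base[f"ent_type={e.etype}"] = 1.0
        base[f"ent_text={e.surface.lower()}"] = 1.0
        title = section_of(doc, e.start)
        base[f"ent_section={title or 'none'}"] = 1.0
        # position-tagged 10-token windows of content words around the entity
        import bisect

        idx = bisect.bisect_left(token_starts, e.start)
        dist = 1
        i = idx - 1
        while i >= 0 and dist <= 10:
            tok = doc.tokens[i]
            if tok.end <= e.start and not tok.is_stop:
                base[f"entctx[{-dist}]={tok.lemma}"] = 1.0
                dist += 1
            i -= 1
        dist = 1
        i = idx
        while i < len(doc.tokens) and dist <= 10:
            tok = doc.tokens[i]
            if tok.start >= e.end and not tok.is_stop:
                base[f"entctx[{dist}]={tok.lemma}"] = 1.0
                dist += 1
            i += 1
    unigrams = {t.lemma for t in doc.tokens if not t.is_stop}
    ngrams: Set[str] = set()
    for u in unigrams:
        ngrams |= _char_ngrams(u)
    return DocProfile(base=base, unigrams=unigrams, ngrams=ngrams)


@dataclass
class ClassProfile:
    unigrams: Set[str]
    ngrams: Set[str]


def build_class_profile(term: OntologyTerm) -> ClassProfile:
    from .ontology import definition_tokens

    toks: Set[str] = set(definition_tokens(term.definition))
    for name in term.synonyms:
        toks |= set(definition_tokens(name))
    ngrams: Set[str] = set()
    for tok in toks:
        ngrams |= _char_ngrams(tok)
    return ClassProfile(unigrams=toks, ngrams=ngrams)


def extract_doc_features(
    doc: Document,
    term: OntologyTerm,
    doc_profile: Optional[DocProfile] = None,
    class_profile: Optional[ClassProfile] = None,
) -> FeatureVector:
    """Class-independent entity/context/section features plus binary
    match indicators: a word unigram or character n-gram (n in {2,3,4},
    within token boundaries, lowercased) fires only if present in BOTH
    the class's definition+synonyms AND the document."""
    dp = doc_profile or build_doc_profile(doc)
    cp = class_profile or build_class_profile(term)
    feats = dict(dp.base)
    for u in cp.unigrams & dp.unigrams:
        feats[f"defuni={u}"] = 1.0
    for g in cp.ngrams & dp.ngrams:
        feats[f"defng={g}"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# training / scoring

@dataclass
class OvaModelSet:
    learner: str  # "LR" | "SVM"
    models: Dict[str, Tuple[DictVectorizer, object]] = field(default_factory=dict)
    class_profiles: Dict[str, ClassProfile] = field(default_factory=dict)
    terms: Dict[str, OntologyTerm] = field(default_factory=dict)

    @property
    def trained_classes(self) -> List[str]:
        return sorted(self.models)

    def nominal_threshold(self) -> float:
        return 0.5 if self.learner == "LR" else 0.0

    def score(self, doc: Document, class_id: str, dp: Optional[DocProfile] = None) -> float:
        vec, clf = self.models[class_id]
        feats = extract_doc_features(
            doc, self.terms[class_id], dp, self.class_profiles[class_id]
        )
        X = csr32(vec.transform([feats]))
        if self.learner == "LR":
            return float(clf.predict_proba(X)[0, 1])
        return float(clf.decision_function(X)[0])

    def score_all(self, doc: Document) -> List[LabelScore]:
        dp = build_doc_profile(doc)
        return [
            LabelScore(doc.doc_id, class_id, self.score(doc, class_id, dp))
            for class_id in self.trained_classes
        ]


def train_ova(
    docs: Sequence[Document],
    terms: Sequence[OntologyTerm],
    learner: str = "LR",
    C: float = 1.0,
) -> OvaModelSet:
    """Train one binary model per class that has at least one positive
    training document. LR is L2-regularised; the SVM is linear with
    C = 1 by default."""
    if not terms:
        raise ValueError("class list must be non-empty")
    if not docs:
        raise ValueError("no training documents")
    if learner not in ("LR", "SVM"):
        raise ValueError("learner must be LR or SVM")
    model_set = OvaModelSet(learner=learner)
    doc_profiles = [build_doc_profile(d) for d in docs]
    for term in terms:
        if any(d.gold_mi_ids is None for d in docs):
            raise ValueError("all training documents need gold labels")
        y = np.array([1 if term.mi_id in d.gold_mi_ids else 0 for d in docs])
        if y.sum() == 0:
            continue
        if y.sum() == len(y):
            continue  # degenerate: no negatives to separate against
        cp = build_class_profile(term)
        feats = [
            extract_doc_features(d, term, dp, cp)
            for d, dp in zip(docs, doc_profiles)
        ]
        vec = DictVectorizer(sparse=True)
        X = csr32(vec.fit_transform(feats))
        if learner == "LR":
            clf = LogisticRegression(C=C, l1_ratio=0, solver="liblinear", random_state=0)
        else:
            clf = LinearSVC(C=C, random_state=0, max_iter=20000)
        clf.fit(X, y)
        model_set.models[term.mi_id] = (vec, clf)
        model_set.class_profiles[term.mi_id] = cp
        model_set.terms[term.mi_id] = term
    return model_set


# ---------------------------------------------------------------------------
# thresholding

def _objective_value(
    objective: str, scores: Sequence[float], labels: Sequence[int], threshold: float
) -> float:
    pred = [s > threshold for s in scores]
    if objective == "accuracy":
        return sum(p == bool(l) for p, l in zip(pred, labels)) / len(labels)
    tp = sum(p and l for p, l in zip(pred, labels))
    fp = sum(p and not l for p, l in zip(pred, labels))
    fn = sum((not p) and l for p, l in zip(pred, labels))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def _best_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    objective: str,
    nominal: float,
    floor: Optional[float],
) -> float:
    """Scan candidate thresholds — midpoints between consecutive sorted
    scores, +/- infinity sentinels and the nominal threshold — and pick
    the one maximising the objective; ties prefer the higher threshold
    (precision-leaning). Candidates below the floor are not considered
    (the floor is a constraint on the search, and the nominal threshold
    always satisfies it)."""
    uniq = sorted(set(scores))
    if len(uniq) <= 1:
        # degenerate input: the scores cannot discriminate, keep nominal
        return max(nominal, floor) if floor is not None else nominal
    candidates = {nominal, math.inf, -math.inf}
    for a, b in zip(uniq, uniq[1:]):
        candidates.add((a + b) / 2.0)
    if uniq:
        candidates.add(uniq[0] - 1.0)
        candidates.add(uniq[-1] + 1.0)
    if floor is not None:
        candidates = {c for c in candidates if c >= floor}
        candidates.add(max(floor, nominal))
    best = max(sorted(candidates), key=lambda c: (_objective_value(objective, scores, labels, c), c))
    if math.isinf(best):
        # an infinite sentinel won: clamp to a finite equivalent
        if best > 0:
            best = (uniq[-1] + 1.0) if uniq else nominal
        else:
            best = (uniq[0] - 1.0) if uniq else nominal
        if floor is not None:
            best = max(best, floor)
    return best


def tune_thresholds(
    model_set: OvaModelSet,
    tuning_docs: Sequence[Document],
    mode: str = "per_class",
    objective: str = "accuracy",
    floor: Optional[float] = None,
) -> ThresholdPolicy:
    """Fit score thresholds on held-out documents (the caller must keep
    them disjoint from the training set). LR models default to the 0.10
    probability floor."""
    if floor is None and model_set.learner == "LR":
        floor = LR_FLOOR
    nominal = model_set.nominal_threshold()
    scored: Dict[str, Tuple[List[float], List[int]]] = {
        c: ([], []) for c in model_set.trained_classes
    }
    for doc in tuning_docs:
        if doc.gold_mi_ids is None:
            raise ValueError(f"tuning document {doc.doc_id} has no gold labels")
        dp = build_doc_profile(doc)
        for class_id in model_set.trained_classes:
            s = model_set.score(doc, class_id, dp)
            scored[class_id][0].append(s)
            scored[class_id][1].append(1 if class_id in doc.gold_mi_ids else 0)

    policy = ThresholdPolicy(mode=mode, objective=objective, floor=floor)
    if mode == "per_class":
        for class_id, (scores, labels) in scored.items():
            if not labels or len(set(labels)) < 2 and sum(labels) == 0:
                # class absent from the tuning docs: keep the nominal threshold
                print(
                    f"warning: class {class_id} has no tuning positives; "
                    f"using nominal threshold {nominal}",
                    file=sys.stderr,
                )
                policy.values[class_id] = max(nominal, floor) if floor else nominal
                continue
            policy.values[class_id] = _best_threshold(scores, labels, objective, nominal, floor)
        policy.global_value = max(nominal, floor) if floor else nominal
    elif mode == "global":
        all_scores: List[float] = []
        all_labels: List[int] = []
        for scores, labels in scored.values():
            all_scores.extend(scores)
            all_labels.extend(labels)
        policy.global_value = _best_threshold(all_scores, all_labels, objective, nominal, floor)
    else:
        raise ValueError("mode must be per_class or global")
    return policy


def nominal_policy(model_set: OvaModelSet) -> ThresholdPolicy:
    nominal = model_set.nominal_threshold()
    return ThresholdPolicy(mode="global", global_value=nominal)


def predict_ova(
    doc: Document, model_set: OvaModelSet, policy: ThresholdPolicy
) -> Tuple[Set[str], List[LabelScore]]:
    """Label set {class : score > threshold(class)} plus all raw scores
    (for ranking metrics)."""
    scores = model_set.score_all(doc)
    labels = {
        ls.class_id for ls in scores if ls.score > policy.threshold_for(ls.class_id)
    }
    return labels, scores


def ensemble_union(label_sets: Sequence[Set[str]]) -> Set[str]:
    if len(label_sets) < 2:
        raise ValueError("an ensemble needs at least two systems")
    out: Set[str] = set()
    for s in label_sets:
        out |= s
    return out


def ensemble_intersect(label_sets: Sequence[Set[str]]) -> Set[str]:
    if len(label_sets) < 2:
        raise ValueError("an ensemble needs at least two systems")
    out = set(label_sets[0])
    for s in label_sets[1:]:
        out &= s
    return out
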