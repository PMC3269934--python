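"""Binary classification of abstracts as relevant to PPI curation.

An abstract is relevant when it reports curatable protein-protein
interactions. Four feature groups are available and freely combinable:

- B: bag of words (all content lemmas; abstracts are short enough that
  no windowing is needed);
- N: named entities — type and text for the ten supported entity types;
- C: protein context — for every sentence containing at least one
  protein mention, all content lemmas position-free, plus verbs and
  nouns with signed token position relative to the protein name (capped
  at +/-10);
- M: MeSH — descriptor names as atomic ids, and/or their tree-number
  prefixes (which generalise over MeSH categories).

A feature-knockout harness measures each group's contribution by
cross-validating every requested subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import metrics
from ._sparse import csr32
from .corpus import Document, Token
from .ontology import mesh_tree_prefixes

__all__ = [
    "ActFeatureConfig",
    "ActPrediction",
    "ActModel",
    "extract_act_features",
    "train_act",
    "predict_act",
    "knockout_experiment",
]

FeatureVector = Dict[str, float]

METRIC_COLUMNS = [
    "F1 score",
    "Specificity",
    "Sensitivity",
    "Accuracy",
    "Matthews Coef",
    "AUC iP/R",
]


@dataclass(frozen=True)
class ActFeatureConfig:
    groups: FrozenSet[str] = frozenset({"B", "N", "C", "M"})
    mesh_mode: str = "id"  # "id" | "tree" | "id+tree"
    learner: str = "LR"  # "LR" | "SVM"
    regulariser: str = "L2"  # "L1" | "L2"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one feature group is required")
        if not self.groups <= {"B", "N", "C", "M"}:
            raise ValueError("groups must come from {B, N, C, M}")
        if self.mesh_mode not in ("id", "tree", "id+tree"):
            raise ValueError("mesh_mode must be id, tree or id+tree")


@dataclass(frozen=True)
class ActPrediction:
    doc_id: str
    score: float
    relevant: bool


_SENTENCE_RE = re.compile(r"[^.!?]+(?:[.!?]+|$)")


def _sentences(doc: Document) -> List[Tuple[int, int]]:
    return [(m.start(), m.end()) for m in _SENTENCE_RE.finditer(doc.text)]


def _tokens_in(doc: Document, start: int, end: int) -> List[Tuple[int, Token]]:
    return [
        (i, t) for i, t in enumerate(doc.tokens) if t.start >= start and t.end <= end
    ]


def extract_act_features(
    doc: Document,
    config: ActFeatureConfig,
    mesh_table: Optional[Mapping[str, Sequence[str]]] = None,
) -> FeatureVector:
    """Feature extraction is additive by group: adding a group never
    changes the values contributed by another."""
    feats: FeatureVector = {}

    if "B" in config.groups:
        for t in doc.tokens:
            if not t.is_stop:
                feats[f"bow={t.lemma}"] = 1.0

    if "N" in config.groups:
        for e in doc.entities:
            feats[f"ne_type={e.etype}"] = 1.0
            feats[f"ne_text={e.surface.lower()}"] = 1.0

    if "C" in config.groups:
        proteins = [e for e in doc.entities if e.etype == "protein"]
        for s_start, s_end in _sentences(doc):
            in_sentence = [p for p in proteins if p.start >= s_start and p.end <= s_end]
            if not in_sentence:
                continue
            sent_tokens = _tokens_in(doc, s_start, s_end)
            for _i, tok in sent_tokens:
                if not tok.is_stop:
                    feats[f"pctx={tok.lemma}"] = 1.0
            # verbs and nouns with signed position relative to the
            # nearest protein mention, capped at +/-10 content tokens
            anchor_idx: Set[int] = set()
            for p in in_sentence:
                for i, tok in sent_tokens:
                    if tok.start >= p.start and tok.end <= p.end:
                        anchor_idx.add(i)
            content = [(i, tok) for i, tok in sent_tokens if not tok.is_stop]
            positions = {i: rank for rank, (i, _t) in enumerate(content)}
            anchor_ranks = sorted(positions[i] for i in anchor_idx if i in positions)
            if not anchor_ranks:
                continue
            for i, tok in content:
                if tok.pos not in ("VERB", "NOUN"):
                    continue
                if i in anchor_idx:
                    continue
                rank = positions[i]
                dist = min((rank - a for a in anchor_ranks), key=abs)
                dist = max(-10, min(10, dist))
                feats[f"pctx_pos[{dist}]={tok.lemma}"] = 1.0

    if "M" in config.groups:
        for name in doc.mesh_ids:
            if config.mesh_mode in ("id", "id+tree"):
                feats[f"mesh={name}"] = 1.0
            if config.mesh_mode in ("tree", "id+tree") and mesh_table:
                for tree in mesh_table.get(name, ()):
                    for prefix in mesh_tree_prefixes(tree):
                        feats[f"meshtree={prefix}"] = 1.0
    return feats


@dataclass
class ActModel:
    config: ActFeatureConfig
    vectorizer: DictVectorizer
    clf: object
    mesh_table: Optional[Mapping[str, Sequence[str]]] = None

    def score(self, doc: Document) -> float:
        feats = extract_act_features(doc, self.config, self.mesh_table)
        X = csr32(self.vectorizer.transform([feats]))
        if self.config.learner == "LR":
            return float(self.clf.predict_proba(X)[0, 1])
        return float(self.clf.decision_function(X)[0])


def train_act(
    docs: Sequence[Document],
    config: ActFeatureConfig,
    mesh_table: Optional[Mapping[str, Sequence[str]]] = None,
    C: float = 1.0,
) -> ActModel:
    labels = [d.gold_relevant for d in docs]
    if any(l is None for l in labels):
        raise ValueError("all training documents need a relevance label")
    if len(set(labels)) < 2:
        raise ValueError("training requires both relevant and irrelevant documents")
    feats = [extract_act_features(d, config, mesh_table) for d in docs]
    vec = DictVectorizer(sparse=True)
    X = csr32(vec.fit_transform(feats))
    y = np.array([1 if l else 0 for l in labels])
    if config.learner == "LR":
        clf = LogisticRegression(
            C=C,
            l1_ratio=1 if config.regulariser == "L1" else 0,
            solver="liblinear",
            random_state=0,
        )
    else:
        clf = LinearSVC(C=C, random_state=0, max_iter=20000)
    clf.fit(X, y)
    return ActModel(config=config, vectorizer=vec, clf=clf, mesh_table=mesh_table)


def predict_act(doc: Document, model: ActModel) -> ActPrediction:
    score = model.score(doc)
    threshold = 0.5 if model.config.learner == "LR" else 0.0
    return ActPrediction(doc_id=doc.doc_id, score=score, relevant=score > threshold)


def _evaluate(model: ActModel, docs: Sequence[Document]) -> Dict[str, float]:
    counts = metrics.ConfusionCounts()
    scores: Dict[str, float] = {}
    positives = []
    for doc in docs:
        pred = predict_act(doc, model)
        scores[doc.doc_id] = pred.score
        if doc.gold_relevant:
            positives.append(doc.doc_id)
        if pred.relevant and doc.gold_relevant:
            counts.tp += 1
        elif pred.relevant:
            counts.fp += 1
        elif doc.gold_relevant:
            counts.fn += 1
        else:
            counts.tn += 1
    row = metrics.binary_metric_row(counts)
    row["AUC iP/R"] = metrics.auc_ipr(scores, positives) if positives else 0.0
    return row


def knockout_experiment(
    docs: Sequence[Document],
    group_subsets: Sequence[str],
    k: int = 10,
    seed: int = 17,
    base_config: Optional[ActFeatureConfig] = None,
    mesh_table: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Cross-validate each feature subset (e.g. ["B", "N", "C", "M",
    "BC", "BCM", "BNCM"]) and tabulate the six standard metrics per
    subset."""
    base = base_config or ActFeatureConfig()
    rows = []
    for subset in group_subsets:
        groups = frozenset(subset)
        config = ActFeatureConfig(
            groups=groups,
            mesh_mode=base.mesh_mode,
            learner=base.learner,
            regulariser=base.regulariser,
        )
        result = metrics.cross_validate(
            docs,
            k,
            seed,
            train_fn=lambda train, cfg=config: train_act(train, cfg, mesh_table),
            eval_fn=lambda model, test: _evaluate(model, test),
        )
        rows.append({"Features": subset, **{c: result.get(c, 0.0) for c in METRIC_COLUMNS}})
    return pd.DataFrame(rows, columns=["Features", *METRIC_COLUMNS])
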