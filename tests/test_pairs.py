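"""Candidate-pair generation, pair features, labelling rules and the
binary pair classifier."""

from __future__ import annotations

import pytest

from ppiminer import synth
from ppiminer.corpus import make_document
from ppiminer.ontology import MiMeshMapping, OntologyTerm, rank_definition_tokens
from ppiminer.pairs import (
    extract_pair_features,
    generate_candidates,
    label_training_pairs,
    predict_document_labels,
    train_pair_model,
)
from ppiminer.stringsim import build_corpus_stats


@pytest.fixture(scope="module")
def mini_terms():
    return [
        OntologyTerm(
            mi_id="MI:0007",
            name="anti tag coimmunoprecipitation",
            definition="antibody based chromatography capture of tagged complexes",
        ),
        OntologyTerm(mi_id="MI:0018", name="two hybrid", synonyms=["2-hybrid"]),
    ]


def _stats(terms):
    from ppiminer.corpus import tokenize

    bags = [
        [t.lemma for t in tokenize(n) if not t.is_stop]
        for term in terms
        for n in term.all_names()
    ]
    bags.append(["protein", "complex", "analysis"])
    return build_corpus_stats(bags)


def test_paper_style_chunk_is_retained(mini_terms):
    stats = _stats(mini_terms)
    doc = make_document("d", "We used anti-His tag antibodies for the assay.")
    cands = generate_candidates(doc, mini_terms, stats)
    assert any(
        c.mi_id == "MI:0007" and c.similarity >= 0.5 for c in cands
    ), [c.__dict__ for c in cands]


def test_unrelated_chunks_produce_no_candidates(mini_terms):
    stats = _stats(mini_terms)
    doc = make_document("d", "The mouse genome sequence was published.")
    assert generate_candidates(doc, mini_terms, stats) == []


def test_exact_name_chunk_scores_one(mini_terms):
    stats = _stats(mini_terms)
    doc = make_document("d", "It was confirmed by two hybrid in cells.")
    cands = generate_candidates(doc, mini_terms, stats)
    best = max(c.similarity for c in cands if c.mi_id == "MI:0018")
    assert best == pytest.approx(1.0)


def test_candidates_sorted_by_position_then_id(mini_terms, toy_terms, corpus_stats, imt_train):
    docs, _m, _t = imt_train
    for doc in docs[:5]:
        cands = generate_candidates(doc, toy_terms, corpus_stats)
        keys = [(c.chunk.start, c.mi_id) for c in cands]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)  # one candidate per (chunk, id)


# --------------------------------------------------------------------------
# labelling


def _pair_fixture(mini_terms):
    stats = _stats(mini_terms)
    doc = make_document(
        "d", "Binding was shown by anti tag coimmunoprecipitation and two hybrid."
    )
    return doc, generate_candidates(doc, mini_terms, stats)


def test_gold_membership_defines_labels(mini_terms):
    doc, cands = _pair_fixture(mini_terms)
    assert {c.mi_id for c in cands} == {"MI:0007", "MI:0018"}
    doc.gold_mi_ids = {"MI:0007"}
    labels = label_training_pairs(doc, cands)
    for c, l in zip(cands, labels):
        assert l == (1 if c.mi_id == "MI:0007" else 0)
    doc.gold_mi_ids = set()
    assert set(label_training_pairs(doc, cands)) == {0}


def test_missing_gold_labels_is_hard_error(mini_terms):
    doc, cands = _pair_fixture(mini_terms)
    doc.gold_mi_ids = None
    with pytest.raises(ValueError):
        label_training_pairs(doc, cands)


# --------------------------------------------------------------------------
# features


def test_features_fire_for_definition_and_mesh(mini_terms):
    stats = _stats(mini_terms)
    term = mini_terms[0]
    rank_definition_tokens(term, stats)
    doc = make_document(
        "d",
        "Introduction\nThe capture of complexes used anti tag coimmunoprecipitation here.",
    )
    doc.mesh_ids = ["Co-Immunoprecipitation"]
    mapping = MiMeshMapping(
        entries={"MI:0007": ("E05.196.150.639", "Co-Immunoprecipitation")}
    )
    (cand,) = [
        c for c in generate_candidates(doc, mini_terms, stats) if c.mi_id == "MI:0007"
    ]
    feats = extract_pair_features(cand, doc, term, mapping)
    assert feats["mesh_matches_pair_id"] == 1.0
    assert feats["mesh_top_mapped"] == 1.0
    assert feats["section=introduction"] == 1.0
    assert feats["mi=MI:0007"] == 1.0
    assert feats["similarity"] == pytest.approx(cand.similarity)
    rank = term.def_token_ranks["capture"]
    assert feats[f"defmatch_local_rank{rank}"] == 1.0


def test_chunk_at_document_start_has_no_left_context(mini_terms):
    stats = _stats(mini_terms)
    doc = make_document("d", "two hybrid screening confirmed the interaction later.")
    cand = [c for c in generate_candidates(doc, mini_terms, stats) if c.mi_id == "MI:0018"][0]
    feats = extract_pair_features(cand, doc, mini_terms[1], MiMeshMapping())
    assert not any(k.startswith("ctx10[-") for k in feats)
    assert any(k.startswith("ctx10[") for k in feats)  # right side exists


# --------------------------------------------------------------------------
# model


def test_separable_instances_are_separated():
    instances = [
        ({"good": 1.0}, 1),
        ({"bad": 1.0}, 0),
    ]
    model = train_pair_model(instances, C=16.0)
    d = model.decision_values([f for f, _l in instances])
    assert d[0] > 0 and d[1] <= 0


def test_training_is_deterministic():
    instances = [({"a": 1.0, "b": 0.5}, 1), ({"b": 1.0}, 0), ({"a": 0.2}, 1), ({}, 0)]
    m1 = train_pair_model(instances)
    m2 = train_pair_model(instances)
    assert m1.weights == m2.weights and m1.bias == m2.bias


def test_single_class_data_is_rejected():
    with pytest.raises(ValueError):
        train_pair_model([({"a": 1.0}, 1), ({"b": 1.0}, 1)])


def test_xor_pattern_trains_without_crashing():
    instances = [
        ({"x": 1.0}, 1),
        ({"y": 1.0}, 1),
        ({"x": 1.0, "y": 1.0}, 0),
        ({}, 0),
    ]
    model = train_pair_model(instances)
    assert model.decision_values([f for f, _l in instances]).shape == (4,)


def test_prediction_is_order_invariant(mini_terms):
    doc, cands = _pair_fixture(mini_terms)
    doc.gold_mi_ids = {"MI:0007"}
    feats = {
        id(c): extract_pair_features(c, doc, mini_terms[0 if c.mi_id == "MI:0007" else 1], MiMeshMapping())
        for c in cands
    }
    instances = list(zip([feats[id(c)] for c in cands], label_training_pairs(doc, cands)))
    # add a clearly negative synthetic instance so both classes exist
    instances.append(({"nothing": 1.0}, 0))
    model = train_pair_model(instances)
    fn = lambda p: feats[id(p)]
    forward = predict_document_labels(doc, cands, model, feature_fn=fn)
    backward = predict_document_labels(doc, list(reversed(cands)), model, feature_fn=fn)
    assert forward == backward


def test_no_candidates_means_no_labels(mini_terms):
    doc = make_document("d", "nothing relevant here")
    assert predict_document_labels(doc, [], None, feature_fn=None) == set()


def test_candidate_recall_is_total_without_surface_variation(toy_terms, corpus_stats):
    cfg = synth.SynthConfig(seed=13, n_docs=10, n_terms=8, variant_rate=0.0)
    docs, _mapping, _mesh = synth.generate_imt_corpus(cfg, toy_terms)
    for doc in docs:
        found = {c.mi_id for c in generate_candidates(doc, toy_terms, corpus_stats)}
        assert doc.gold_mi_ids <= found
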