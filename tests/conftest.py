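"""Shared fixtures: a toy ontology and seeded synthetic corpora.

Session-scoped so the heavier end-to-end tests share one corpus. The
seeds and sizes here are the study conditions for the whole suite.
"""

from __future__ import annotations

import pytest

from ppiminer import stringsim, synth
from ppiminer.corpus import tokenize


def name_bags(terms):
    return [
        [t.lemma for t in tokenize(n) if not t.is_stop]
        for term in terms
        for n in term.all_names()
    ]


@pytest.fixture(scope="session")
def toy_terms():
    return synth.generate_toy_ontology(n_terms=8, seed=7)


@pytest.fixture(scope="session")
def imt_train(toy_terms):
    cfg = synth.SynthConfig(seed=11, n_docs=60, n_terms=8, variant_rate=0.3)
    return synth.generate_imt_corpus(cfg, toy_terms)


@pytest.fixture(scope="session")
def imt_tune(toy_terms):
    cfg = synth.SynthConfig(seed=22, n_docs=20, n_terms=8, variant_rate=0.3)
    docs, _mapping, _mesh = synth.generate_imt_corpus(cfg, toy_terms)
    return docs


@pytest.fixture(scope="session")
def imt_test(toy_terms):
    cfg = synth.SynthConfig(seed=12, n_docs=20, n_terms=8, variant_rate=0.3)
    docs, _mapping, _mesh = synth.generate_imt_corpus(cfg, toy_terms)
    return docs


@pytest.fixture(scope="session")
def corpus_stats(toy_terms, imt_train):
    docs, _mapping, _mesh = imt_train
    bags = [[t.lemma for t in d.tokens if not t.is_stop] for d in docs]
    bags += name_bags(toy_terms)
    return stringsim.build_corpus_stats(bags)


@pytest.fixture(scope="session")
def act_corpus():
    cfg = synth.SynthConfig(seed=31, n_docs=60, positive_rate=0.5)
    return synth.generate_act_corpus(cfg)
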