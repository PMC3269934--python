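"""Ontology loading, definition-token ranking, MeSH tree expansion and
the MI -> MeSH mapping cascade."""

from __future__ import annotations

import random

import pytest

from ppiminer.ontology import (
    MeshDescriptor,
    MiMeshMapping,
    OntologyTerm,
    build_mi_mesh_mapping,
    load_default_mapping,
    load_psimi,
    map_mi_to_mesh,
    mesh_tree_prefixes,
    rank_definition_tokens,
)
from ppiminer.stringsim import CorpusStats, build_corpus_stats
from ppiminer.synth import generate_toy_ontology, ontology_to_obo


# --------------------------------------------------------------------------
# OBO loading

TOY_OBO = """format-version: 1.2

[Term]
id: MI:0001
name: interaction detection method

[Term]
id: MI:0019
name: coimmunoprecipitation
def: "method using antibodies" []
synonym: "coip" EXACT []
synonym: "Coimmunoprecipitation" EXACT []
is_a: MI:0001

[Term]
id: MI:0096
name: pull down
is_a: MI:0001

[Term]
id: MI:0018
name: two hybrid
synonym: "2-hybrid" EXACT []
is_a: MI:0001
"""


def test_load_filters_to_allowed_ids(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    terms = load_psimi(str(p), ["MI:0019", "MI:0018"])
    assert [t.mi_id for t in terms] == ["MI:0019", "MI:0018"]


def test_synonym_equal_to_name_is_dropped(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    (term,) = load_psimi(str(p), ["MI:0019"])
    # "Coimmunoprecipitation" duplicates the name case-insensitively
    assert term.synonyms == ["coip"]
    assert term.definition == "method using antibodies"
    assert term.parent_ids == ["MI:0001"]


def test_missing_allowed_id_is_a_hard_error(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    with pytest.raises(ValueError, match="MI:9999"):
        load_psimi(str(p), ["MI:0019", "MI:9999"])


def test_generated_obo_round_trips(tmp_path, toy_terms):
    p = tmp_path / "gen.obo"
    p.write_text(ontology_to_obo(toy_terms))
    loaded = load_psimi(str(p), [t.mi_id for t in toy_terms])
    assert len(loaded) == len(toy_terms)
    for orig, back in zip(toy_terms, loaded):
        assert back.name == orig.name
        assert back.synonyms == orig.synonyms
        assert back.definition == orig.definition


# --------------------------------------------------------------------------
# definition-token ranking


def test_ranks_match_brute_force_sort():
    stats = build_corpus_stats(
        [["affinity", "column"], ["column", "buffer"], ["resin"]]
    )
    term = OntologyTerm(
        mi_id="MI:0004",
        name="affinity chromatography",
        definition="affinity column with resin resin buffer",
    )
    rank_definition_tokens(term, stats)
    # independent oracle: full sort of (token, tf * idf)
    tf = {"affinity": 1, "column": 1, "resin": 2, "buffer": 1}
    scored = sorted(tf, key=lambda w: (-tf[w] * stats.idf(w), w))
    assert [w for w, _r in sorted(term.def_token_ranks.items(), key=lambda kv: kv[1])] == scored
    assert sorted(term.def_token_ranks.values()) == list(range(1, len(tf) + 1))


def test_equal_tfidf_breaks_ties_lexicographically():
    stats = CorpusStats(doc_count=1, df={})
    term = OntologyTerm(mi_id="MI:0001", name="x", definition="zeta alpha mid")
    rank_definition_tokens(term, stats)
    assert term.def_token_ranks == {"alpha": 1, "mid": 2, "zeta": 3}


def test_empty_definition_gives_empty_rank_map():
    term = OntologyTerm(mi_id="MI:0001", name="x", definition="")
    rank_definition_tokens(term, CorpusStats(doc_count=1, df={}))
    assert term.def_token_ranks == {}


# --------------------------------------------------------------------------
# MeSH tree numbers


@pytest.mark.parametrize(
    "tree,expected",
    [
        ("E05.196.150", ["E05", "E05.196", "E05.196.150"]),
        ("E05", ["E05"]),
        ("E05.196.150.639", ["E05", "E05.196", "E05.196.150", "E05.196.150.639"]),
    ],
)
def test_tree_prefix_expansion(tree, expected):
    assert mesh_tree_prefixes(tree) == expected


def test_prefix_count_equals_segment_count_for_random_ids():
    rng = random.Random(3)
    for _ in range(50):
        n = rng.randint(1, 6)
        tree = "E" + str(rng.randint(1, 99)) + "".join(
            f".{rng.randint(100, 999)}" for _ in range(n - 1)
        )
        assert len(mesh_tree_prefixes(tree)) == n


def test_malformed_tree_id_rejected():
    with pytest.raises(ValueError):
        mesh_tree_prefixes("5E.196")


# --------------------------------------------------------------------------
# default mapping lookups


def test_default_mapping_rows():
    mapping = load_default_mapping()
    assert map_mi_to_mesh("MI:0007", mapping) == (
        "E05.196.150.639",
        "Co-Immunoprecipitation",
    )
    assert map_mi_to_mesh("MI:0018", mapping) == (
        "E05.393.220.870",
        "Two-hybrid System Techniques",
    )
    assert map_mi_to_mesh("MI:0001", mapping) is None


# --------------------------------------------------------------------------
# mapping cascade

MESH_FIXTURE = [
    MeshDescriptor("Co-Immunoprecipitation", ("E05.196.150.639",)),
    MeshDescriptor("Affinity Chromatography", ("E05.196.181.400.170",)),
    MeshDescriptor("Two-hybrid System Techniques", ("E05.393.220.870",)),
    MeshDescriptor("X-Ray Crystallography", ("E05.196.309.742.225",)),
    MeshDescriptor("Molecular Sieve Chromatography", ("E05.196.181.400.250",)),
    MeshDescriptor("Fluorescence Microscopy", ("E01.370.350.515.458",)),
    MeshDescriptor("Protein Array Analysis", ("E05.196.630.570.700",)),
    MeshDescriptor("Surface Plasmon Resonance", ("E05.196.890",)),
    MeshDescriptor("Confocal Microscopy", ("E01.370.350.515.395",)),
]


def test_hyphen_variant_matches_at_step_three():
    terms = [OntologyTerm(mi_id="MI:0019", name="coimmunoprecipitation")]
    built = build_mi_mesh_mapping(terms, MESH_FIXTURE)
    assert built.entries["MI:0019"] == ("E05.196.150.639", "Co-Immunoprecipitation")


def test_partial_match_with_token_variants():
    terms = [OntologyTerm(mi_id="MI:0071", name="Molecular Sieving")]
    built = build_mi_mesh_mapping(terms, MESH_FIXTURE)
    assert built.entries["MI:0071"] == (
        "E05.196.181.400.250",
        "Molecular Sieve Chromatography",
    )


def test_exact_match_wins_before_approximate_steps():
    # "fluorescence microscopy" shares a token with Confocal Microscopy,
    # but the exact (step 1) match must win
    terms = [OntologyTerm(mi_id="MI:0416", name="Fluorescence Microscopy")]
    built = build_mi_mesh_mapping(terms, MESH_FIXTURE)
    assert built.entries["MI:0416"][1] == "Fluorescence Microscopy"


def _frequent_method_terms():
    rows = [
        ("MI:0007", "anti tag coimmunoprecipitation", ["MI:0019"]),
        ("MI:0006", "anti bait coimmunoprecipitation", ["MI:0019"]),
        ("MI:0096", "pull down", ["MI:0004"]),
        ("MI:0018", "two hybrid", []),
        ("MI:0114", "X-ray crystallography", []),
        ("MI:0071", "Molecular Sieving", []),
        ("MI:0416", "Fluorescence Microscopy", []),
        ("MI:0424", "Protein Kinase Assay", []),
        ("MI:0107", "Surface Plasmon Resonance", []),
        ("MI:0663", "Confocal Microscopy", []),
    ]
    terms = [
        OntologyTerm(mi_id=mi, name=name, parent_ids=parents)
        for mi, name, parents in rows
    ]
    parents = {
        "MI:0019": OntologyTerm(mi_id="MI:0019", name="coimmunoprecipitation"),
        "MI:0004": OntologyTerm(mi_id="MI:0004", name="affinity chromatography"),
    }
    return terms, parents


def test_cascade_reproduces_default_mapping_on_frequent_methods():
    terms, parents = _frequent_method_terms()
    built = build_mi_mesh_mapping(terms, MESH_FIXTURE, parents=parents)
    expected = load_default_mapping()
    assert built.entries == expected.entries


def test_adding_descriptors_never_removes_earlier_step_matches():
    terms, parents = _frequent_method_terms()
    small = [d for d in MESH_FIXTURE if d.name != "Protein Array Analysis"]
    before = build_mi_mesh_mapping(terms, small, parents=parents)
    after = build_mi_mesh_mapping(terms, MESH_FIXTURE, parents=parents)
    for mi, entry in before.entries.items():
        # exact-step matches are stable; approximate matches may only be
        # refined, never dropped
        assert mi in after.entries
        name = next(t.name for t in terms if t.mi_id == mi)
        if entry[1].casefold() == name.casefold():
            assert after.entries[mi] == entry
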