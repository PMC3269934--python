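"""Seeded synthetic corpora for the method-detection and triage tasks.

Real challenge corpora for these tasks are not redistributable, so every
pipeline stage is exercised on generated data instead: a toy ontology of
multi-word method names with synonyms (always including a hyphenated
variant) and definitions sharing tokens with the names; full-text-like
documents with Introduction / Materials and Methods / Results sections,
planted method mentions with controllable surface variation (hyphen
toggling, token drops, character typos), named entities near the
mentions, consistent MeSH rows and gold label sets; and abstracts whose
relevance signal is interaction verbs between protein mentions.

All randomness flows from a single ``random.Random(seed)`` stream per
generated artefact, with a fixed draw order, so corpora are reproducible
across runs and platforms. Distractor vocabulary is disjoint from the
method-name vocabulary, which makes exact-match recall experiments
well-posed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .corpus import (
    Chunk,
    Document,
    EntityMention,
    detect_section_titles,
    tokenize,
    write_corpus_dir,
)
from .ontology import MiMeshMapping, OntologyTerm, definition_tokens

_GENERIC_DEF_TOKENS = frozenset(
    {
        "technique", "protein", "complex", "detected", "detection",
        "using", "interaction", "sample", "assay", "signal",
    }
)


def _distinctive_defwords(term: OntologyTerm, k: int = 2) -> List[str]:
    """Definition tokens specific to this method (not name tokens, not
    generic methodology words) — what a paper would mention alongside
    the method itself."""
    name_toks = {
        t for name in term.all_names() for t in definition_tokens(name)
    }
    out: List[str] = []
    for tok in definition_tokens(term.definition):
        if tok in _GENERIC_DEF_TOKENS or tok in name_toks or tok in out:
            continue
        out.append(tok)
        if len(out) == k:
            break
    return out

__all__ = [
    "SynthConfig",
    "generate_toy_ontology",
    "ontology_to_obo",
    "generate_imt_corpus",
    "generate_act_corpus",
]

METHOD_VOCAB = [
    "affinity", "chromatography", "precipitation", "immunoblot", "hybrid",
    "fluorescence", "microscopy", "crystallography", "resonance",
    "spectrometry", "electrophoresis", "sedimentation", "filtration",
    "crosslinking", "footprinting", "calorimetry", "anisotropy",
    "interference", "polarisation", "complementation", "displacement",
    "sieving", "scattering", "ultracentrifugation", "densitometry",
    "titration", "cosedimentation", "copurification", "blotting",
    "imaging", "microarray", "spectroscopy", "cytometry", "gradient",
    "exclusion", "capture", "transfer", "luminescence", "tomography",
    "diffraction", "dichroism", "retardation", "probing", "biosensor",
    "quenching", "immunostaining", "bioluminescence", "electroporation",
]

DEF_VOCAB = [
    "reagent", "antibody", "bead", "column", "elution", "lysate",
    "substrate", "buffer", "resin", "excitation", "emission", "detector",
    "wavelength", "centrifuge", "immobilised", "epitope", "fusion",
    "reporter", "bait", "prey", "fraction", "incubation", "dilution",
    "calibration", "chamber", "membrane", "staining", "quantification",
    "velocity", "equilibrium", "refraction", "polymer",
]

DISTRACTOR_VOCAB = [
    "cell", "culture", "mouse", "tissue", "growth", "nucleus", "pathway",
    "receptor", "genome", "sequence", "plasmid", "strain", "mutant",
    "clone", "promoter", "enzyme", "cytoplasm", "organism", "vesicle",
    "chromosome", "ribosome", "transcript", "phenotype", "colony",
    "medium", "temperature", "population", "development", "morphology",
    "secretion",
]

INTERACTION_VERBS = ["interacts", "binds", "associates", "coprecipitates"]
NEUTRAL_VERBS = ["expressed", "purified", "observed", "measured"]

_FILLER = [
    "the", "of", "in", "with", "was", "were", "and", "for", "by", "a",
]


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_docs: int = 20
    n_terms: int = 8
    mentions_per_doc: Tuple[int, int] = (1, 3)
    variant_rate: float = 0.3
    typo_rate: float = 0.1
    distractor_chunks: int = 10
    positive_rate: float = 0.5
    stray_mention_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in ("variant_rate", "typo_rate", "positive_rate", "stray_mention_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")


# ---------------------------------------------------------------------------
# toy ontology

def generate_toy_ontology(n_terms: int, seed: int) -> List[OntologyTerm]:
    """Build ``n_terms`` method terms with multi-word names (tokens drawn
    without reuse from a controlled vocabulary), 1-3 synonyms each —
    always including a hyphenated variant — and 15-30-token definitions
    sharing tokens with the name."""
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = random.Random(seed)
    vocab = METHOD_VOCAB[:]
    rng.shuffle(vocab)
    defwords = DEF_VOCAB[:]
    rng.shuffle(defwords)
    if n_terms * 3 > len(vocab):
        raise ValueError(f"n_terms is limited to {len(vocab) // 3} by the vocabulary")
    terms: List[OntologyTerm] = []
    vi = 0
    for i in range(n_terms):
        n_tok = rng.choice([2, 3])
        toks = vocab[vi : vi + n_tok]
        vi += n_tok
        name = " ".join(toks)
        synonyms = [f"{toks[-2]}-{toks[-1]}" if n_tok == 2 else " ".join(toks[:-2]) + f" {toks[-2]}-{toks[-1]}"]
        if n_tok == 3 and rng.random() < 0.5:
            synonyms.append(" ".join([toks[1], toks[0], toks[2]]))
        dw = [defwords[(2 * i) % len(defwords)], defwords[(2 * i + 1) % len(defwords)]]
        body = []
        target_len = rng.randint(15, 30)
        pool = toks + dw + ["protein", "complex", "detection", "technique", "interaction", "sample", "assay", "signal"]
        while len(body) < target_len:
            if rng.random() < 0.35:
                body.append(rng.choice(_FILLER))
            else:
                body.append(rng.choice(pool))
        definition = (
            f"a technique in which the protein complex is detected by {' '.join(toks)} "
            f"using {dw[0]} and {dw[1]} " + " ".join(body)
        )
        terms.append(
            OntologyTerm(
                mi_id=f"MI:{101 + i:04d}",
                name=name,
                synonyms=synonyms,
                definition=definition,
                parent_ids=["MI:0001"],
            )
        )
    return terms


def ontology_to_obo(terms: Sequence[OntologyTerm]) -> str:
    """Serialise toy terms as an OBO 1.2 flat file (round-trips through
    the ontology loader)."""
    out = ["format-version: 1.2", ""]
    out += ["[Term]", "id: MI:0001", "name: interaction detection method", ""]
    for t in terms:
        out.append("[Term]")
        out.append(f"id: {t.mi_id}")
        out.append(f"name: {t.name}")
        out.append(f'def: "{t.definition}" [synthetic:0]')
        for syn in t.synonyms:
            out.append(f'synonym: "{syn}" EXACT []')
        for p in t.parent_ids:
            out.append(f"is_a: {p}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# mention perturbation

def _swap_chars(token: str, rng: random.Random) -> str:
    if len(token) < 4:
        return token
    i = rng.randrange(1, len(token) - 2)
    return token[:i] + token[i + 1] + token[i] + token[i + 2 :]


def _perturb_mention(mention: str, cfg: SynthConfig, rng: random.Random) -> str:
    """With probability variant_rate apply one structural perturbation:
    hyphen toggle, token drop (names of >= 3 tokens) or typo (each token
    swapped with probability typo_rate, at least one)."""
    if rng.random() >= cfg.variant_rate:
        return mention
    ops = ["hyphen", "typo"]
    space_tokens = mention.split(" ")
    if len(space_tokens) >= 3:
        ops.append("drop")
    op = rng.choice(ops)
    if op == "hyphen":
        if "-" in mention:
            return mention.replace("-", " ")
        if len(space_tokens) >= 2:
            i = rng.randrange(len(space_tokens) - 1)
            return " ".join(
                space_tokens[:i]
                + [space_tokens[i] + "-" + space_tokens[i + 1]]
                + space_tokens[i + 2 :]
            )
        op = "typo"
    if op == "drop":
        i = rng.randrange(len(space_tokens))
        return " ".join(space_tokens[:i] + space_tokens[i + 1 :])
    # typo
    out = [t for t in space_tokens]
    changed = False
    for i, tok in enumerate(out):
        if rng.random() < cfg.typo_rate:
            new = _swap_chars(tok, rng)
            changed = changed or new != tok
            out[i] = new
    if not changed:
        candidates = [i for i, t in enumerate(out) if len(t) >= 4]
        if candidates:
            i = rng.choice(candidates)
            out[i] = _swap_chars(out[i], rng)
    return " ".join(out)


# ---------------------------------------------------------------------------
# document assembly

class _TextBuilder:
    def __init__(self) -> None:
        self.parts: List[str] = []
        self.length = 0
        self.chunks: List[Tuple[int, int, str]] = []
        self.entities: List[Tuple[int, int, str]] = []

    def add(self, text: str) -> Tuple[int, int]:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start, self.length

    def mark_chunk(self, span: Tuple[int, int], kind: str = "NP") -> None:
        self.chunks.append((span[0], span[1], kind))

    def mark_entity(self, span: Tuple[int, int], etype: str) -> None:
        self.entities.append((span[0], span[1], etype))

    def build(self, doc_id: str) -> Document:
        text = "".join(self.parts)
        doc = Document(doc_id=doc_id, text=text, tokens=tokenize(text))
        bounds_first = {t.start: i for i, t in enumerate(doc.tokens)}
        bounds_last = {t.end: i for i, t in enumerate(doc.tokens)}
        for start, end, kind in self.chunks:
            if start in bounds_first and end in bounds_last:
                doc.chunks.append(
                    Chunk(start, end, kind, bounds_first[start], bounds_last[end] + 1)
                )
        for start, end, etype in self.entities:
            doc.entities.append(EntityMention(start, end, etype, text[start:end]))
        doc.sections = detect_section_titles(doc)
        return doc


def _protein_name(rng: random.Random) -> str:
    return "Prot" + "".join(rng.choice("ABCDEFGHKLMNPRSTW") for _ in range(2)) + str(rng.randrange(1, 10))


def _distractor_sentence(b: _TextBuilder, rng: random.Random, chunked: bool) -> None:
    w1, w2, w3 = (rng.choice(DISTRACTOR_VOCAB) for _ in range(3))
    b.add("The ")
    span = b.add(f"{w1} {w2}")
    if chunked:
        b.mark_chunk(span, "NP")
    b.add(f" was observed in the {w3} of the sample. ")


def toy_mi_mesh(terms: Sequence[OntologyTerm], top_k: int = 10) -> Tuple[MiMeshMapping, Dict[str, List[str]]]:
    """A consistent toy MI -> MeSH mapping (first ``top_k`` terms) and
    the matching name -> tree-number table."""
    mapping = MiMeshMapping()
    table: Dict[str, List[str]] = {}
    for i, t in enumerate(terms[:top_k]):
        mesh_name = t.name.title()
        tree = f"E05.{300 + i}.{500 + i}"
        mapping.entries[t.mi_id] = (tree, mesh_name)
        table[mesh_name] = [tree]
    table["Cell Culture Techniques"] = ["E05.200.500"]
    table["Protein Binding"] = ["G02.111.570"]
    return mapping, table


def generate_imt_corpus(
    config: SynthConfig,
    terms: Sequence[OntologyTerm],
) -> Tuple[List[Document], MiMeshMapping, Dict[str, List[str]]]:
    """Full-text-like documents with sections, planted (possibly
    perturbed) mentions of their gold methods in Materials and Methods,
    stray verbatim mentions of non-gold methods in the Introduction,
    distractor NP chunks, protein entities near planted mentions, and
    MeSH rows consistent with the toy MI -> MeSH mapping."""
    rng = random.Random(config.seed)
    mapping, mesh_table = toy_mi_mesh(terms)
    mesh_by_mi = dict(mapping.entries)
    docs: List[Document] = []
    lo, hi = config.mentions_per_doc
    for d in range(config.n_docs):
        b = _TextBuilder()
        n_mentions = rng.randint(lo, hi)
        gold_terms = rng.sample(list(terms), min(n_mentions, len(terms)))
        gold_ids = {t.mi_id for t in gold_terms}

        b.add("Introduction\n")
        for _ in range(2):
            _distractor_sentence(b, rng, chunked=True)
        if rng.random() < config.stray_mention_rate:
            non_gold = [t for t in terms if t.mi_id not in gold_ids]
            if non_gold:
                stray = rng.choice(non_gold)
                b.add("Previous studies also discussed ")
                span = b.add(stray.name)
                b.mark_chunk(span, "NP")
                b.add(" in unrelated settings. ")
        b.add("\nMaterials and Methods\n")
        defword_pool: List[str] = []
        for term in gold_terms:
            mention = rng.choice(term.all_names())
            mention = _perturb_mention(mention, config, rng)
            p1, p2 = _protein_name(rng), _protein_name(rng)
            b.add("The ")
            e1 = b.add(p1)
            b.mark_entity(e1, "protein")
            b.add(" and ")
            e2 = b.add(p2)
            b.mark_entity(e2, "protein")
            b.add(" complex was analysed by ")
            span = b.add(mention)
            b.mark_chunk(span, "NP")
            dws = _distinctive_defwords(term) or ["reagent"]
            defword_pool.extend(dws)
            b.add(" using " + " and ".join(dws) + ". ")
        for _ in range(config.distractor_chunks):
            _distractor_sentence(b, rng, chunked=True)
        b.add("\nResults\n")
        for _ in range(2):
            _distractor_sentence(b, rng, chunked=False)
        if defword_pool:
            b.add("The " + rng.choice(defword_pool) + " signal confirmed the interaction. ")

        doc = b.build(f"doc{d:04d}")
        doc.gold_mi_ids = gold_ids
        for term in gold_terms:
            if term.mi_id in mesh_by_mi and rng.random() < 0.9:
                doc.mesh_ids.append(mesh_by_mi[term.mi_id][1])
        if rng.random() < 0.5:
            doc.mesh_ids.append("Cell Culture Techniques")
        docs.append(doc)
    return docs, mapping, mesh_table


def generate_act_corpus(config: SynthConfig) -> Tuple[List[Document], Dict[str, List[str]]]:
    """Abstracts with a deterministic number of positives
    (round(positive_rate * n_docs)). Positives contain at least two
    protein mentions joined by an interaction verb and a process-type
    MeSH row; negatives contain gene entities, or proteins without
    interaction verbs."""
    rng = random.Random(config.seed)
    n_pos = round(config.positive_rate * config.n_docs)
    labels = [True] * n_pos + [False] * (config.n_docs - n_pos)
    rng.shuffle(labels)
    mesh_table = {
        "Protein Binding": ["G02.111.570"],
        "Protein Interaction Mapping": ["E05.393.420"],
        "Cell Culture Techniques": ["E05.200.500"],
        "Gene Expression Profiling": ["E05.393.332"],
    }
    docs: List[Document] = []
    for d, positive in enumerate(labels):
        b = _TextBuilder()
        _distractor_sentence(b, rng, chunked=False)
        if positive:
            p1, p2 = _protein_name(rng), _protein_name(rng)
            verb = rng.choice(INTERACTION_VERBS)
            e1 = b.add(p1)
            b.mark_entity(e1, "protein")
            b.add(f" {verb} with ")
            e2 = b.add(p2)
            b.mark_entity(e2, "protein")
            b.add(f" in the {rng.choice(DISTRACTOR_VOCAB)}. ")
            mesh = ["Protein Binding"]
            if rng.random() < 0.5:
                mesh.append("Protein Interaction Mapping")
        else:
            if rng.random() < 0.5:
                g = "gene" + str(rng.randrange(100))
                e1 = b.add(g.capitalize())
                b.mark_entity(e1, "gene")
                b.add(f" was {rng.choice(NEUTRAL_VERBS)} in the {rng.choice(DISTRACTOR_VOCAB)}. ")
            else:
                p1 = _protein_name(rng)
                e1 = b.add(p1)
                b.mark_entity(e1, "protein")
                b.add(f" was {rng.choice(NEUTRAL_VERBS)} from the {rng.choice(DISTRACTOR_VOCAB)} extract. ")
            mesh = [rng.choice(["Cell Culture Techniques", "Gene Expression Profiling"])]
        _distractor_sentence(b, rng, chunked=False)
        doc = b.build(f"abs{d:04d}")
        doc.gold_relevant = positive
        doc.mesh_ids = mesh
        docs.append(doc)
    return docs, mesh_table


# ---------------------------------------------------------------------------
# on-disk corpora

def write_imt_corpus(
    config: SynthConfig, terms: Sequence[OntologyTerm], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    docs, mapping, mesh_table = generate_imt_corpus(config, terms)
    write_corpus_dir(docs, out)
    (out / "psimi.obo").write_text(ontology_to_obo(terms), encoding="utf-8")
    (out / "allowed_ids").write_text(
        "\n".join(t.mi_id for t in terms) + "\n", encoding="utf-8"
    )
    (out / "mesh.tsv").write_text(
        "".join(f"{name}\t{';'.join(trees)}\n" for name, trees in mesh_table.items()),
        encoding="utf-8",
    )
    (out / "mi_mesh.tsv").write_text(
        "".join(
            f"{mi}\t-\t{tree}\t{name}\n" for mi, (tree, name) in mapping.entries.items()
        ),
        encoding="utf-8",
    )


def write_act_corpus(config: SynthConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    docs, mesh_table = generate_act_corpus(config)
    write_corpus_dir(docs, out)
    (out / "mesh.tsv").write_text(
        "".join(f"{name}\t{';'.join(trees)}\n" for name, trees in mesh_table.items()),
        encoding="utf-8",
    )
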