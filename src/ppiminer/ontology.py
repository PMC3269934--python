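"""PSI-MI interaction-detection-method terms and MeSH descriptors.

Loads the allowed subset of the PSI-MI ontology (the "interaction
detection method" branch supplies the label space), ranks definition
tokens by TF-IDF so that the most concept-specific words can serve as
features, expands MeSH tree numbers into hierarchical prefix features,
and builds/holds the mapping between frequent MI IDs and their MeSH
equivalents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import obonet

from .corpus import is_stopword, tokenize
from .stringsim import CorpusStats, SimilarityConfig, jaro_winkler

__all__ = [
    "OntologyTerm",
    "MeshDescriptor",
    "MiMeshMapping",
    "load_psimi",
    "rank_definition_tokens",
    "mesh_tree_prefixes",
    "map_mi_to_mesh",
    "build_mi_mesh_mapping",
    "load_default_mapping",
    "read_mesh_tsv",
]

_MI_ID_RE = re.compile(r"^MI:\d{4}$")
_TREE_ID_RE = re.compile(r"^[A-Z]\d+(\.[A-Za-z0-9]+)*$")
_QUOTED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class OntologyTerm:
    """One interaction-detection method: MI id, canonical name, synonyms,
    free-text definition and (optionally) TF-IDF ranks of its definition
    tokens (rank 1 = most concept-specific)."""

    mi_id: str
    name: str
    synonyms: List[str] = field(default_factory=list)
    definition: str = ""
    parent_ids: List[str] = field(default_factory=list)
    def_token_ranks: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _MI_ID_RE.match(self.mi_id):
            raise ValueError(f"malformed MI identifier {self.mi_id!r}")

    def all_names(self) -> List[str]:
        return [self.name, *self.synonyms]


@dataclass(frozen=True)
class MeshDescriptor:
    name: str
    tree_numbers: Tuple[str, ...]

    def __post_init__(self) -> None:
        for t in self.tree_numbers:
            if not _TREE_ID_RE.match(t):
                raise ValueError(f"malformed MeSH tree number {t!r}")


@dataclass
class MiMeshMapping:
    """MI id -> (MeSH tree number, MeSH descriptor name); at most one
    entry per MI id."""

    entries: Dict[str, Tuple[str, str]] = field(default_factory=dict)


def load_psimi(obo_source, allowed_ids: Sequence[str]) -> List[OntologyTerm]:
    """Load the terms named in ``allowed_ids`` from an OBO file.

    Synonyms are de-duplicated case-insensitively and a synonym equal to
    the canonical name is dropped. Every allowed id must be present in
    the file (hard error listing the missing ones otherwise).
    """
    if not allowed_ids:
        raise ValueError("allowed_ids must be non-empty")
    graph = obonet.read_obo(obo_source)
    missing = [mi for mi in allowed_ids if mi not in graph]
    if missing:
        raise ValueError(f"allowed MI ids absent from OBO source: {', '.join(missing)}")
    terms: List[OntologyTerm] = []
    for mi in allowed_ids:
        data = graph.nodes[mi]
        name = data.get("name", "")
        raw_synonyms = data.get("synonym", [])
        synonyms: List[str] = []
        seen = {name.casefold()}
        for line in raw_synonyms:
            m = _QUOTED_RE.search(line)
            if not m:
                continue
            syn = m.group(1).replace('\\"', '"')
            if syn.casefold() in seen:
                continue
            seen.add(syn.casefold())
            synonyms.append(syn)
        definition = ""
        if "def" in data:
            m = _QUOTED_RE.search(data["def"])
            if m:
                definition = m.group(1).replace('\\"', '"')
        parents = [p for p in graph.successors(mi)] if mi in graph else []
        terms.append(
            OntologyTerm(
                mi_id=mi,
                name=name,
                synonyms=synonyms,
                definition=definition,
                parent_ids=sorted(parents),
            )
        )
    return terms


def definition_tokens(text: str) -> List[str]:
    """Lowercased content tokens of a definition (stop words, digit-only
    and punctuation tokens removed)."""
    return [t.lemma for t in tokenize(text) if not t.is_stop]


def rank_definition_tokens(term: OntologyTerm, stats: CorpusStats) -> OntologyTerm:
    """Assign ranks 1..k to the term's definition tokens by descending
    TF-IDF (term frequency inside the definition times corpus IDF), ties
    broken lexicographically. Mutates and returns the term."""
    toks = definition_tokens(term.definition)
    tf: Dict[str, int] = {}
    for t in toks:
        tf[t] = tf.get(t, 0) + 1
    scored = sorted(tf.items(), key=lambda kv: (-kv[1] * stats.idf(kv[0]), kv[0]))
    term.def_token_ranks = {tok: rank for rank, (tok, _) in enumerate(scored, 1)}
    return term


def mesh_tree_prefixes(tree_id: str) -> List[str]:
    """All dotted prefixes of a MeSH tree number, shortest first:
    "E05.196.150" -> ["E05", "E05.196", "E05.196.150"]. These act as
    hierarchical features that generalise over MeSH categories."""
    if not _TREE_ID_RE.match(tree_id):
        raise ValueError(f"malformed MeSH tree number {tree_id!r}")
    segments = tree_id.split(".")
    return [".".join(segments[: i + 1]) for i in range(len(segments))]


def map_mi_to_mesh(mi_id: str, mapping: MiMeshMapping) -> Optional[Tuple[str, str]]:
    """Exact lookup of an MI id in the mapping; no fuzzy behaviour."""
    return mapping.entries.get(mi_id)


def load_default_mapping() -> MiMeshMapping:
    """The packaged default mapping between the ten most frequent MI ids
    and their MeSH equivalents."""
    data = resources.files("ppiminer.data").joinpath("mi_mesh_default.tsv").read_text()
    entries: Dict[str, Tuple[str, str]] = {}
    for line in data.splitlines():
        if not line.strip():
            continue
        mi_id, _mi_name, tree, mesh_name = line.split("\t")
        entries.setdefault(mi_id, (tree, mesh_name))
    return MiMeshMapping(entries=entries)


def read_mesh_tsv(path: str | Path) -> List[MeshDescriptor]:
    """Read a 2-column TSV fixture: descriptor name, semicolon-joined
    tree numbers."""
    descriptors = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        name, trees = line.split("\t")
        descriptors.append(
            MeshDescriptor(name=name, tree_numbers=tuple(t for t in trees.split(";") if t))
        )
    return descriptors


# ---------------------------------------------------------------------------
# MI -> MeSH mapping cascade

_cfg = SimilarityConfig()


def _norm(s: str) -> str:
    return " ".join(s.casefold().split())


def _dehyphen(s: str) -> str:
    return _norm(s).replace("-", "").replace(" ", "")


def _term_tokens(s: str) -> List[str]:
    return [t.lemma for t in tokenize(s) if not t.is_stop]


def _approx_score(mi_name: str, mesh_name: str) -> Optional[Tuple]:
    """Score one approximate-match candidate, or None if it does not
    qualify. Two variant classes are recognised:

    - hyphenated/unhyphenated variants: equal after hyphen deletion and
      case folding (score class 2);
    - partial matches: at least one non-stop token of either term has an
      approximate counterpart (Jaro-Winkler >= 0.85) in the other
      (score class 1, ranked by matched-token count then mean token
      similarity).
    """
    if _dehyphen(mi_name) == _dehyphen(mesh_name):
        return (2, 0, 0.0)
    a, b = _term_tokens(mi_name), _term_tokens(mesh_name)
    if not a or not b:
        return None
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    sims = []
    for tok in short:
        best = max((jaro_winkler(tok, other, _cfg) for other in long_), default=0.0)
        if best >= _cfg.secondary_threshold:
            sims.append(best)
    if not sims:
        return None
    return (1, len(sims), sum(sims) / len(sims))


def _best_approx(name: str, mesh: Sequence[MeshDescriptor]) -> Optional[MeshDescriptor]:
    best: Optional[Tuple[Tuple, str, MeshDescriptor]] = None
    for d in mesh:
        score = _approx_score(name, d.name)
        if score is None:
            continue
        # ties on the score prefer the lexicographically first descriptor
        if best is None or score > best[0] or (score == best[0] and d.name < best[1]):
            best = (score, d.name, d)
    return best[2] if best else None


def _match_term(
    name: str,
    synonyms: Sequence[str],
    mesh: Sequence[MeshDescriptor],
    by_name: Mapping[str, MeshDescriptor],
) -> Optional[MeshDescriptor]:
    # step 1: exact name match
    if _norm(name) in by_name:
        return by_name[_norm(name)]
    # step 2: exact synonym match
    for syn in synonyms:
        if _norm(syn) in by_name:
            return by_name[_norm(syn)]
    # step 3: approximate name match
    d = _best_approx(name, mesh)
    if d is not None:
        return d
    # step 4: approximate synonym match
    for syn in synonyms:
        d = _best_approx(syn, mesh)
        if d is not None:
            return d
    return None


def build_mi_mesh_mapping(
    terms: Sequence[OntologyTerm],
    mesh: Sequence[MeshDescriptor],
    parents: Optional[Mapping[str, OntologyTerm]] = None,
    max_parent_depth: int = 2,
) -> MiMeshMapping:
    """Map each MI term to a MeSH descriptor via the four-step cascade:
    exact name match, exact synonym match, approximate name match
    (hyphen variants and partial token matches), approximate synonym
    match; if all four fail, retry the cascade on the parent term (at
    most ``max_parent_depth`` levels up, to avoid mapping everything to
    the ontology root). Unmatchable terms are simply absent.

    ``parents`` supplies terms reachable by parent fallback that should
    not themselves receive entries (e.g. ancestors outside the allowed
    list); terms in ``terms`` also serve as parents of one another.
    """
    by_name = {_norm(d.name): d for d in mesh}
    lookup: Dict[str, OntologyTerm] = {t.mi_id: t for t in terms}
    if parents:
        for mi_id, t in parents.items():
            lookup.setdefault(mi_id, t)

    def resolve(term: OntologyTerm, depth: int) -> Optional[MeshDescriptor]:
        d = _match_term(term.name, term.synonyms, mesh, by_name)
        if d is not None:
            return d
        if depth >= max_parent_depth:
            return None
        for pid in term.parent_ids:
            parent = lookup.get(pid)
            if parent is None:
                continue
            d = resolve(parent, depth + 1)
            if d is not None:
                return d
        return None

    entries: Dict[str, Tuple[str, str]] = {}
    for term in terms:
        d = resolve(term, 0)
        if d is not None and d.tree_numbers:
            entries[term.mi_id] = (d.tree_numbers[0], d.name)
    return MiMeshMapping(entries=entries)
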