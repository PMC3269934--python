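"""Documents, text normalisation and annotation layers.

A :class:`Document` carries plain text plus standoff layers (tokens,
NP/VP chunks, named-entity mentions, section spans, MeSH descriptors and
gold labels). All spans are 0-based half-open character intervals in
Unicode code points, and every non-token layer must align to token
boundaries — :func:`validate_document` enforces this and is run by the
pipelines.

Full-text articles converted from PDF arrive with typographic ligatures,
exotic Unicode punctuation and stray control characters;
:func:`normalize_text` cleans these up before any linguistic processing.
Abstracts are typically clean already, but the cascade is idempotent so
it is always applied.
"""

from __future__ import annotations

import re
import sys
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "Token",
    "Chunk",
    "EntityMention",
    "SectionSpan",
    "Document",
    "ENTITY_TYPES",
    "DEFAULT_SECTION_LEXICON",
    "normalize_text",
    "tokenize",
    "is_stopword",
    "content_tokens",
    "expand_abbreviations",
    "detect_section_titles",
    "fallback_chunker",
    "make_document",
    "validate_document",
    "read_standoff",
    "write_standoff",
]

ENTITY_TYPES = frozenset(
    {
        "protein",
        "gene",
        "metabolite",
        "organ",
        "drug",
        "bacteria",
        "disease",
        "symptom",
        "diagnostic/therapeutic procedure",
        "phenomenon",
    }
)

DEFAULT_SECTION_LEXICON: Tuple[str, ...] = (
    "abstract",
    "background",
    "introduction",
    "materials and methods",
    "methods",
    "results",
    "results and discussion",
    "discussion",
    "conclusions",
    "references",
)


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str
    lemma: str
    pos: str
    is_stop: bool


@dataclass(frozen=True)
class Chunk:
    """A noun-phrase or verb-phrase span; the unit matched against
    ontology method names."""

    start: int
    end: int
    kind: str  # "NP" | "VP"
    token_start: int
    token_end: int  # half-open index range into Document.tokens

    def __post_init__(self) -> None:
        if self.kind not in ("NP", "VP"):
            raise ValueError(f"chunk kind must be NP or VP, got {self.kind!r}")


@dataclass(frozen=True)
class EntityMention:
    start: int
    end: int
    etype: str
    surface: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")


@dataclass(frozen=True)
class SectionSpan:
    start: int
    end: int
    title: str


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: List[Token] = field(default_factory=list)
    chunks: List[Chunk] = field(default_factory=list)
    entities: List[EntityMention] = field(default_factory=list)
    sections: List[SectionSpan] = field(default_factory=list)
    mesh_ids: List[str] = field(default_factory=list)
    gold_mi_ids: Optional[Set[str]] = None
    gold_relevant: Optional[bool] = None


# ---------------------------------------------------------------------------
# normalisation

_DASHES = "\u2010\u2011\u2012\u2013\u2014\u2015\u2212"
_SINGLE_QUOTES = "\u2018\u2019\u201a\u201b\u2032\u00b4\u0060"
_DOUBLE_QUOTES = "\u201c\u201d\u201e\u201f\u2033\u00ab\u00bb"
_SPACES = (
    "\u00a0\u1680\u2000\u2001\u2002\u2003\u2004\u2005\u2006\u2007"
    "\u2008\u2009\u200a\u202f\u205f\u3000\t\x0b\x0c\r"
)

_TRANSLATE = {ord(c): "-" for c in _DASHES}
_TRANSLATE.update({ord(c): "'" for c in _SINGLE_QUOTES})
_TRANSLATE.update({ord(c): '"' for c in _DOUBLE_QUOTES})
_TRANSLATE.update({ord(c): " " for c in _SPACES})

# C0 (minus newline; \t\x0b\x0c\r already map to space), C1, zero-width
# and bidi formatting characters, and the BOM.
_CONTROL_RE = re.compile(
    "[\x00-\x08\x0e-\x1f\x7f-\x9f\u200b-\u200f\u2028\u2029\ufeff]"
)


def normalize_text(raw: str) -> str:
    """Normalise ligatures, Unicode punctuation and control characters.

    Ligatures are decomposed (NFKC), dash/quote variants map to ASCII
    ``-``/``'``/``"``, all horizontal whitespace variants map to a plain
    space (newlines are kept so that heading lines survive), and C0/C1
    control characters are removed. Total and idempotent.
    """
    text = unicodedata.normalize("NFKC", raw)
    text = text.replace("\r\n", "\n")
    text = text.translate(_TRANSLATE)
    text = _CONTROL_RE.sub("", text)
    # NFKC can reintroduce mapped characters only for exotic compatibility
    # forms; a second pass keeps the function idempotent.
    text2 = unicodedata.normalize("NFKC", text).translate(_TRANSLATE)
    return _CONTROL_RE.sub("", text2)


# ---------------------------------------------------------------------------
# tokenisation and the heuristic POS tagger

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")

_VERB_LEXICON = frozenset(
    {
        "bind", "binds", "bound", "interact", "interacts", "interacted",
        "associate", "associates", "associated", "coprecipitate",
        "coprecipitates", "phosphorylate", "phosphorylates", "activate",
        "activates", "inhibit", "inhibits", "regulate", "regulates",
        "express", "expresses", "expressed", "perform", "performed",
        "use", "used", "using", "detect", "detected", "analyse",
        "analysed", "analyze", "analyzed", "measure", "measured",
        "incubate", "incubated", "purify", "purified", "observe",
        "observed", "confirm", "confirmed", "show", "showed", "shown",
        "apply", "applied", "require", "requires", "encode", "encodes",
        "localise", "localises", "localize", "localizes", "transcribe",
        "transcribes", "recruit", "recruits", "form", "forms",
    }
)

_ADJ_SUFFIXES = ("al", "ous", "ive", "ic", "ar", "ary", "able", "ible")


def _load_stopwords() -> frozenset:
    data = resources.files("ppiminer.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in data.splitlines() if w.strip())


_STOPWORDS = _load_stopwords()


def is_stopword(token: str) -> bool:
    """Function words, digit-only tokens and bare punctuation are stop
    tokens and are excluded from context features."""
    low = token.lower()
    return low in _STOPWORDS or low.isdigit() or not any(c.isalnum() for c in low)


def _heuristic_pos(surface: str) -> str:
    low = surface.lower()
    if not any(c.isalnum() for c in surface):
        return "PUNCT"
    if low.isdigit():
        return "NUM"
    if low in _STOPWORDS:
        return "FUNC"
    if low in _VERB_LEXICON:
        return "VERB"
    if low.endswith("ly"):
        return "ADV"
    if low.endswith(_ADJ_SUFFIXES):
        return "ADJ"
    return "NOUN"


def tokenize(text: str) -> List[Token]:
    """Deterministic regex tokenisation with exact offsets.

    Alphanumeric runs are single tokens; every other non-space character
    (hyphens included) is a token of its own, so "pull-down" tokenises
    as [pull, -, down] and shares its content tokens with "pull down".
    The lemma defaults to the lowercased surface.
    """
    tokens: List[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        tokens.append(
            Token(
                start=m.start(),
                end=m.end(),
                surface=surface,
                lemma=surface.lower(),
                pos=_heuristic_pos(surface),
                is_stop=is_stopword(surface),
            )
        )
    return tokens


def content_tokens(tokens: Iterable[Token]) -> List[Token]:
    return [t for t in tokens if not t.is_stop]


# ---------------------------------------------------------------------------
# abbreviation expansion (long form "(SF)" definitions)

_SHORT_FORM_RE = re.compile(r"\(([A-Za-z0-9][A-Za-z0-9-]{0,9})\)")


def _find_long_form(short: str, candidate: str) -> Optional[str]:
    """Right-to-left character alignment of the short form against the
    words preceding its parenthesis (the classic long-form heuristic):
    every short-form character must appear in order, and the first one
    must start a word."""
    s = short.lower()
    c = candidate.lower()
    si = len(s) - 1
    ci = len(c) - 1
    while si >= 0:
        ch = s[si]
        if not ch.isalnum():
            si -= 1
            continue
        while ci >= 0 and (c[ci] != ch or (si == 0 and ci > 0 and c[ci - 1].isalnum())):
            ci -= 1
        if ci < 0:
            return None
        si -= 1
        ci -= 1
    start = c.rfind(" ", 0, ci + 2) + 1 if ci >= 0 else 0
    long_form = candidate[start:].strip()
    return long_form or None


def _remap(pos: int, edits: Sequence[Tuple[int, int, int]]) -> int:
    """Map an old-text offset through a list of (start, end, new_len)
    replacement edits (non-overlapping, sorted)."""
    delta = 0
    for start, end, new_len in edits:
        if pos <= start:
            break
        if pos < end:
            pos = start + new_len  # inside a replaced region: snap to its end
            return pos + delta
        delta += new_len - (end - start)
    return pos + delta


def expand_abbreviations(doc: Document) -> Document:
    """Replace every short form defined as ``long form (SF)`` by its long
    form throughout the document, so differently named mentions of one
    entity collapse to a single string ("interleukin 2 (IL2)" makes all
    later "IL2" read "interleukin 2"). First definition wins on
    conflicts; idempotent; all annotation spans are re-aligned."""
    definitions: Dict[str, str] = {}
    for m in _SHORT_FORM_RE.finditer(doc.text):
        short = m.group(1)
        window_start = doc.text.rfind("\n", 0, m.start()) + 1
        candidate = doc.text[window_start : m.start()].strip()
        words = candidate.split()
        max_words = min(len(words), len(short) + 5, max(len(short) * 2, 2))
        candidate = " ".join(words[-max_words:]) if words else ""
        if not candidate:
            continue
        long_form = _find_long_form(short, candidate)
        if not long_form or long_form.lower() == short.lower():
            continue
        if short in definitions:
            if definitions[short] != long_form:
                print(
                    f"warning: conflicting definitions for {short!r}; keeping first",
                    file=sys.stderr,
                )
            continue
        definitions[short] = long_form

    if not definitions:
        return doc

    pattern = re.compile(
        r"\b(" + "|".join(re.escape(s) for s in sorted(definitions, key=len, reverse=True)) + r")\b"
    )
    edits: List[Tuple[int, int, int]] = []
    pieces: List[str] = []
    last = 0
    for m in pattern.finditer(doc.text):
        long_form = definitions[m.group(1)]
        if doc.text[m.start() : m.end()] == long_form:
            continue
        pieces.append(doc.text[last : m.start()])
        pieces.append(long_form)
        edits.append((m.start(), m.end(), len(long_form)))
        last = m.end()
    pieces.append(doc.text[last:])
    new_text = "".join(pieces)

    new_tokens = tokenize(new_text)
    boundaries = _token_boundaries(new_tokens)

    def snap(pos: int, up: bool) -> int:
        new = _remap(pos, edits)
        return _snap_to_boundary(new, boundaries, up)

    new_entities = []
    for e in doc.entities:
        s, t = snap(e.start, False), snap(e.end, True)
        new_entities.append(EntityMention(s, t, e.etype, new_text[s:t]))
    new_sections = [
        SectionSpan(snap(s.start, False), snap(s.end, True), s.title) for s in doc.sections
    ]
    new_doc = Document(
        doc_id=doc.doc_id,
        text=new_text,
        tokens=new_tokens,
        entities=new_entities,
        sections=new_sections,
        mesh_ids=list(doc.mesh_ids),
        gold_mi_ids=set(doc.gold_mi_ids) if doc.gold_mi_ids is not None else None,
        gold_relevant=doc.gold_relevant,
    )
    new_doc.chunks = _remap_chunks(doc.chunks, new_doc, snap)
    return new_doc


def _token_boundaries(tokens: Sequence[Token]) -> List[int]:
    bounds = set()
    for t in tokens:
        bounds.add(t.start)
        bounds.add(t.end)
    bounds.add(0)
    return sorted(bounds)


def _snap_to_boundary(pos: int, boundaries: Sequence[int], up: bool) -> int:
    import bisect

    i = bisect.bisect_left(boundaries, pos)
    if i < len(boundaries) and boundaries[i] == pos:
        return pos
    if up:
        return boundaries[i] if i < len(boundaries) else boundaries[-1]
    return boundaries[i - 1] if i > 0 else boundaries[0]


def _remap_chunks(chunks, new_doc: Document, snap) -> List[Chunk]:
    out = []
    for c in chunks:
        s, t = snap(c.start, False), snap(c.end, True)
        tr = _token_range(new_doc.tokens, s, t)
        if tr is not None:
            out.append(Chunk(s, t, c.kind, tr[0], tr[1]))
    return out


def _token_range(tokens: Sequence[Token], start: int, end: int) -> Optional[Tuple[int, int]]:
    first = last = None
    for i, t in enumerate(tokens):
        if t.start >= start and t.end <= end:
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    return first, last + 1


# ---------------------------------------------------------------------------
# section-title detection

def detect_section_titles(
    doc: Document, lexicon: Sequence[str] = DEFAULT_SECTION_LEXICON
) -> List[SectionSpan]:
    """Find heading lines whose text (case-insensitively, ignoring a
    trailing colon) is a known section name; each section span runs from
    its heading to the next heading (or end of text)."""
    if not lexicon:
        raise ValueError("section lexicon must be non-empty")
    canon = {name.lower(): name.lower() for name in lexicon}
    headings: List[Tuple[int, str]] = []
    offset = 0
    for line in doc.text.split("\n"):
        stripped = line.strip().rstrip(":").strip()
        key = stripped.lower()
        if key in canon:
            headings.append((offset, canon[key]))
        offset += len(line) + 1
    spans: List[SectionSpan] = []
    for i, (start, title) in enumerate(headings):
        end = headings[i + 1][0] if i + 1 < len(headings) else len(doc.text)
        spans.append(SectionSpan(start, min(end, len(doc.text)), title))
    return spans


def section_of(doc: Document, pos: int) -> Optional[str]:
    """Title of the nearest section heading at or before ``pos``."""
    title = None
    for s in doc.sections:
        if s.start <= pos:
            title = s.title
        else:
            break
    return title


# ---------------------------------------------------------------------------
# fallback shallow chunker

_NP_TAGS = {"NOUN", "ADJ", "NUM"}


def fallback_chunker(tokens: Sequence[Token]) -> List[Chunk]:
    """Heuristic NP/VP chunker over POS tags: maximal runs of
    adjective/noun tokens (hyphens joining two such tokens stay inside
    the run) become NPs; runs headed by a verb become VPs."""
    chunks: List[Chunk] = []
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.pos in _NP_TAGS:
            j = i + 1
            while j < n:
                t = tokens[j]
                if t.pos in _NP_TAGS:
                    j += 1
                elif (
                    t.surface == "-"
                    and j + 1 < n
                    and tokens[j + 1].pos in _NP_TAGS
                    and t.start == tokens[j - 1].end
                    and t.end == tokens[j + 1].start
                ):
                    j += 2
                else:
                    break
            chunks.append(Chunk(tok.start, tokens[j - 1].end, "NP", i, j))
            i = j
        elif tok.pos == "VERB":
            j = i + 1
            while j < n and tokens[j].pos in ("VERB", "ADV"):
                j += 1
            chunks.append(Chunk(tok.start, tokens[j - 1].end, "VP", i, j))
            i = j
        else:
            i += 1
    return chunks


# ---------------------------------------------------------------------------
# document assembly and validation

def make_document(
    doc_id: str,
    raw_text: str,
    *,
    chunk: bool = True,
    section_lexicon: Sequence[str] = DEFAULT_SECTION_LEXICON,
) -> Document:
    """Normalise, tokenise, detect sections and (optionally) chunk."""
    text = normalize_text(raw_text)
    doc = Document(doc_id=doc_id, text=text, tokens=tokenize(text))
    doc.sections = detect_section_titles(doc, section_lexicon)
    if chunk:
        doc.chunks = fallback_chunker(doc.tokens)
    return doc


def validate_document(doc: Document) -> None:
    """Check all layer invariants; raises ValueError on the first
    violation."""
    n = len(doc.text)
    prev_end = 0
    for t in doc.tokens:
        if not (0 <= t.start < t.end <= n):
            raise ValueError(f"token span ({t.start}, {t.end}) out of range")
        if t.start < prev_end:
            raise ValueError("tokens overlap or are unsorted")
        if doc.text[t.start : t.end] != t.surface:
            raise ValueError(f"token surface mismatch at {t.start}")
        prev_end = t.end
    boundaries = set(_token_boundaries(doc.tokens))
    boundaries.add(n)
    for layer, spans in (
        ("chunk", [(c.start, c.end) for c in doc.chunks]),
        ("entity", [(e.start, e.end) for e in doc.entities]),
        ("section", [(s.start, s.end) for s in doc.sections]),
    ):
        for start, end in spans:
            if not (0 <= start <= end <= n):
                raise ValueError(f"{layer} span ({start}, {end}) out of range")
            if start not in boundaries or end not in boundaries:
                raise ValueError(f"{layer} span ({start}, {end}) not on token boundaries")
    for e in doc.entities:
        if doc.text[e.start : e.end] != e.surface:
            raise ValueError(f"entity surface mismatch at {e.start}")


# ---------------------------------------------------------------------------
# standoff round-trip
#
# TSV rows: id <TAB> layer <TAB> type <TAB> start <TAB> end <TAB> value
# Layers: token (type=POS, value=lemma), chunk (type=NP|VP), entity
# (type=etype, value=surface), section (value=title), mesh (value=name),
# label (type=mi, value=MI id | type=relevance, value=pos|neg), both
# label kinds with start=end=0.

def write_standoff(doc: Document, text_path: str | Path, ann_path: str | Path) -> None:
    Path(text_path).write_text(doc.text, encoding="utf-8")
    rows: List[str] = []
    idx = 0

    def row(layer: str, typ: str, start: int, end: int, value: str) -> None:
        nonlocal idx
        idx += 1
        rows.append(f"T{idx}\t{layer}\t{typ}\t{start}\t{end}\t{value}")

    for t in doc.tokens:
        row("token", t.pos, t.start, t.end, t.lemma)
    for c in doc.chunks:
        row("chunk", c.kind, c.start, c.end, "")
    for e in doc.entities:
        row("entity", e.etype, e.start, e.end, e.surface)
    for s in doc.sections:
        row("section", "", s.start, s.end, s.title)
    for m in doc.mesh_ids:
        row("mesh", "", 0, 0, m)
    if doc.gold_mi_ids is not None:
        for mi in sorted(doc.gold_mi_ids):
            row("label", "mi", 0, 0, mi)
        if not doc.gold_mi_ids:
            row("label", "mi-none", 0, 0, "")
    if doc.gold_relevant is not None:
        row("label", "relevance", 0, 0, "pos" if doc.gold_relevant else "neg")
    Path(ann_path).write_text("\n".join(rows) + ("\n" if rows else ""), encoding="utf-8")


def read_standoff(text_path: str | Path, ann_path: str | Path) -> Document:
    """Inverse of :func:`write_standoff`; read(write(doc)) == doc.

    If the annotation file carries no token rows the text is tokenised
    with the built-in tokeniser.
    """
    text = Path(text_path).read_text(encoding="utf-8")
    doc = Document(doc_id=Path(text_path).stem, text=text)
    token_rows: List[Token] = []
    chunk_rows: List[Tuple[int, int, str]] = []
    n = len(text)
    ann_text = Path(ann_path).read_text(encoding="utf-8")
    for lineno, line in enumerate(ann_text.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{ann_path}: row {lineno}: expected 6 fields")
        _, layer, typ, start_s, end_s, value = parts
        start, end = int(start_s), int(end_s)
        if layer != "label" and not (0 <= start <= end <= n):
            raise ValueError(f"{ann_path}: row {lineno}: offsets ({start}, {end}) out of range")
        if layer == "token":
            surface = text[start:end]
            token_rows.append(
                Token(start, end, surface, value, typ, is_stopword(surface))
            )
        elif layer == "chunk":
            chunk_rows.append((start, end, typ))
        elif layer == "entity":
            doc.entities.append(EntityMention(start, end, typ, text[start:end]))
        elif layer == "section":
            doc.sections.append(SectionSpan(start, end, value))
        elif layer == "mesh":
            doc.mesh_ids.append(value)
        elif layer == "label":
            if typ == "mi":
                if doc.gold_mi_ids is None:
                    doc.gold_mi_ids = set()
                doc.gold_mi_ids.add(value)
            elif typ == "mi-none":
                if doc.gold_mi_ids is None:
                    doc.gold_mi_ids = set()
            elif typ == "relevance":
                doc.gold_relevant = value == "pos"
            else:
                raise ValueError(f"{ann_path}: row {lineno}: unknown label type {typ!r}")
        else:
            raise ValueError(f"{ann_path}: row {lineno}: unknown layer {layer!r}")
    doc.tokens = token_rows if token_rows else tokenize(text)
    for start, end, kind in chunk_rows:
        tr = _token_range(doc.tokens, start, end)
        if tr is None:
            raise ValueError(f"chunk span ({start}, {end}) covers no tokens")
        doc.chunks.append(Chunk(start, end, kind, tr[0], tr[1]))
    return doc


def read_corpus_dir(directory: str | Path) -> List[Document]:
    """Read every ``<id>.txt`` / ``<id>.ann`` pair in a directory."""
    directory = Path(directory)
    docs = []
    for text_path in sorted(directory.glob("*.txt")):
        ann_path = text_path.with_suffix(".ann")
        if ann_path.exists():
            docs.append(read_standoff(text_path, ann_path))
        else:
            docs.append(make_document(text_path.stem, text_path.read_text(encoding="utf-8")))
    return docs


def write_corpus_dir(docs: Iterable[Document], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_standoff(doc, directory / f"{doc.doc_id}.txt", directory / f"{doc.doc_id}.ann")
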