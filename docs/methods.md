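# Methods

This note documents the models and procedures implemented in
`ppiminer`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
and design choices made where the design was genuinely open.

## Document model

A document is plain UTF-8 text plus standoff layers: tokens, NP/VP
chunks, named-entity mentions (a closed set of ten biomedical types),
section spans, MeSH descriptors, and gold labels. All spans are
0-based, half-open character intervals counted in Unicode code points,
and every non-token layer must start and end on token boundaries; a
validator enforces this and runs in every pipeline.

Text normalisation targets the artefacts of PDF-converted full text:
NFKC decomposition for typographic ligatures, mapping of Unicode dash /
quote / space variants to their ASCII equivalents, and removal of
C0/C1 control characters. Newlines are preserved deliberately — section
headings are detected as standalone lines, so collapsing vertical
whitespace would destroy the section layer. The cascade is idempotent,
so it is also safe to run on abstracts that are already clean.

The tokeniser is a deterministic regex: alphanumeric runs are tokens
and every other non-space character is a token of its own. Splitting
hyphens into separate tokens is a deliberate choice: it makes
`pull-down` and `pull down` share the same content-token multiset,
which is exactly the behaviour the hybrid string similarity needs.
Lemmas default to the lowercased surface (a heuristic suffix/lexicon
part-of-speech tagger supports the fallback chunker and the verb/noun
context features; externally produced token layers can be ingested via
the standoff reader). Stop tokens are a packaged function-word list
plus digit-only and punctuation-only tokens; third-person pronouns are
excluded from the list because strings like `anti-His tag` carry a
content-bearing "His" in this domain.

Abbreviation expansion uses the classic long-form / parenthesised
short-form heuristic: a short form's characters must appear in order in
the preceding words, with the first character starting a word. All
occurrences of the short form in the same document are replaced by the
long form (document-local only; no global dictionary), all annotation
spans are re-aligned, and the operation is idempotent. On conflicting
definitions the first wins, with a warning.

## String similarity

`jaro` and `jaro_winkler` follow the standard definitions (match window
`floor(max(|s|,|t|)/2) - 1`; transpositions are half the number of
mismatched matched positions, rounded down, as in the original
implementation and its common ports; Winkler prefix boost `l·p·(1−jaro)`
with `p = 0.1` capped at 4 characters).

`soft_tfidf` scores two token multisets. Each token carries an
L2-normalised TF·IDF weight with `idf(t) = log(1 + N/df(t))`; tokens
never seen in the corpus get the maximum idf (df treated as 1). In one
direction, every token of the source string pairs with its best
Jaro-Winkler partner in the target provided the similarity reaches the
secondary threshold (default 0.85; ties broken lexicographically), and
the products `V(w,s)·V(w',t)·jw(w,w')` are summed. The reported score
is the **maximum of the two directed sums**. This choice keeps the
function symmetric, makes it collapse exactly to the TF-IDF cosine when
the secondary threshold is 1.0, and preserves the retention behaviour
that motivates the method (the worked anti-His-tag example scores ~0.8
against `anti tag coimmunoprecipitation`, comfortably above the 0.5
candidate threshold). Averaging the two directions instead would let
one direction's unmatched high-idf token veto a pair that the method is
designed to keep.

The IDF source corpus is the training document collection plus all
ontology method names and synonyms, so method-name tokens are
well-estimated even on tiny corpora.

## Ontology handling

The allowed subset of PSI-MI interaction-detection methods is loaded
from OBO (via `obonet`); synonyms are de-duplicated case-insensitively
and a synonym equal to the canonical name is dropped. Definition tokens
are ranked 1..k by descending TF·IDF within the definition (ties
lexicographic); the rank — not the token weight — is what the pair
classifier uses, making the feature robust to corpus-scale changes.

MeSH descriptors live in a 2-column TSV fixture (name, semicolon-joined
tree numbers); no live MeSH access is required. Tree numbers expand
into all dotted prefixes, shortest first, giving hierarchical features
that generalise over MeSH categories.

The MI→MeSH mapping cascade tries, in order: (1) exact name match,
(2) exact synonym match, (3) approximate name match, (4) approximate
synonym match, then retries on parent terms up to depth 2 (a deeper
fallback would map everything to the ontology root). Approximate
matching recognises two variant classes: hyphenated/unhyphenated
variants (equal after hyphen deletion and case folding) and partial
matches. A partial match requires at least one non-stop token of the
shorter term to have an approximate counterpart (Jaro-Winkler ≥ 0.85)
in the other; candidates are ranked by variant class, matched-token
count and mean token similarity, with lexicographic tie-breaks. The
one-matched-token minimum is deliberately permissive: the mapping this
cascade reproduces was originally curated by hand, and a manual curator
accepts pairs like *protein kinase assay* → *Protein Array Analysis*
that share only one informative token. The packaged default mapping
covers the ten most frequent methods and is shipped as data.

## Pair classification

Candidate generation compares every NP/VP chunk with every method name
and synonym and keeps pairs with SoftTFIDF ≥ 0.50 (both thresholds as
fixed above); for a given (chunk, MI id) only the best-scoring name is
retained, and output order (document position, then MI id) is
deterministic.

Feature families, extracted per pair: signed-position context lemmas
within 10 content tokens per side of the chunk; a position-free bag
within 50 per side (window sizes count content tokens after stop-word
removal, and chunk-internal tokens are excluded); type and text of up
to 5 named entities per side; counts of the concept's names/synonyms in
a 20-token window and document-wide; binary definition-token indicators
keyed by TF-IDF rank (local and global); the enclosing section title;
MeSH evidence (document annotated with a mapped descriptor, and whether
that descriptor's MI id is the pair's id); and the chunk string, the MI
id, and the similarity score as a real-valued feature.

A training pair is positive iff its MI id is among the document's gold
labels. The classifier is an L2-regularised linear SVM (scikit-learn
liblinear) with `C = 16` — the smaller of the two equally good values
found for this task family — and inverse-class-frequency instance
weighting, because candidate pairs are heavily imbalanced (hundreds of
chunks per full-text document, very few gold methods). Document labels
are the union of MI ids over positively classified pairs; the decision
is the sign of the margin, with no extra thresholding.

## One-vs-all classification and thresholding

One binary model per class with at least one positive training
document: logistic regression (L2) or linear SVM (`C = 1`). Features:
entity types/surfaces, signed-position 10-token content windows around
entities (lemmas, for consistency with the pair classifier), the
section containing each entity, and binary match indicators for word
unigrams and within-token character n-grams (n ∈ {2,3,4}, lowercased)
present in both the class's definition+synonyms and the document.

Thresholding is score-based only (rank-based and class-proportion
strategies select fixed label counts and are unsuitable for online
classification). Candidates are midpoints between consecutive sorted
tuning scores plus the nominal threshold and sentinels beyond the score
range; the scan maximises per-class accuracy (default) or F1, ties
preferring the higher threshold (precision-leaning). For logistic
models the 0.10 probability floor is a *constraint on the scan* —
candidates below it are never considered — rather than a post-hoc
clamp, so the tuned threshold provably does at least as well on the
tuning fold as the nominal 0.5. Classes absent from the tuning
documents, or with degenerate constant scores, keep the nominal
threshold with a warning. Label assignment is strict (`score >
threshold`). Union and intersection ensembles are plain set algebra per
document, which is what makes "union improves recall, intersection
improves precision" provable at the containment level.

## Triage

Feature groups are strictly additive: B (bag of content lemmas — whole
abstracts, no windowing), N (entity type and text), C (for each
sentence containing a protein mention: all content lemmas
position-free, plus verbs and nouns with signed content-token distance
to the nearest protein mention, capped at ±10 to match the other
windows), M (MeSH descriptor names, tree-number prefixes, or both;
`id+tree` is exactly the concatenation of the two). Sentences are split
on terminal punctuation; position-free C words cover the whole
sentence while positioned verbs/nouns are window-capped. Learners as
above (LR with an L1 option for comparison experiments); the relevance
decision uses the nominal threshold (probability 0.5, margin 0). The
knockout harness cross-validates any list of group subsets and reports
F1, specificity, sensitivity, accuracy, Matthews correlation and AUC
iP/R per subset.

## Metrics

Micro-averaging pools all (document, label) decisions and is the
headline aggregate; per-class counts are available for macro views.
P/R/F1 use the 0-when-undefined convention; MCC is 0 when any marginal
is empty. AUC iP/R ranks all decisions by descending score — ties keep
stable input order, a documented caveat since other scorers may break
ties differently — records (recall, precision) at every gold positive,
interpolates precision at recall r as the maximum precision at any
recall ≥ r, and integrates the resulting step function. Cross-validation
folds are a seeded random partition; learning-curve subsets are seeded
and nested (each larger fraction contains the smaller) to reduce
sampling noise between points.

## Synthetic corpora

The generator emulates the structure that the pipelines rely on, at
desk scale: a toy ontology (default 8 terms) whose multi-word names
draw tokens without reuse from a controlled methodology vocabulary,
each with a hyphenated-variant synonym and a 15–30-token definition
sharing tokens with the name; full-text-like documents (default 20)
with Introduction / Materials and Methods / Results sections, 1–3
planted gold-method mentions in the methods section flanked by protein
entities and method-specific definition words, stray verbatim mentions
of non-gold methods in the introduction (rate 0.5/document — these
become the classifier's negative pairs), 10 distractor noun phrases per
document from a vocabulary disjoint from method-name tokens, and MeSH
rows consistent with the toy MI→MeSH mapping. Surface variation is
controlled by `variant_rate` (probability a planted mention is
perturbed by hyphen toggling, token dropping, or character swaps) and
`typo_rate` (per-token swap probability within the typo perturbation);
at `variant_rate = 0` every mention is string-equal to a name or
synonym, so candidate recall is exactly 1. Triage abstracts plant an
interaction verb between two protein mentions plus a process-type MeSH
descriptor in positives (count fixed at `round(positive_rate·n_docs)`),
and gene mentions or proteins with neutral verbs in negatives. One
`random.Random(seed)` stream per corpus with a fixed draw order makes
every artefact bit-reproducible.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: the long-tailed class distribution
of real method annotations and its drift between splits, annotation
inconsistency, coreference and discourse phenomena (e.g. methods
mentioned in failed-attempt contexts), noisy PDF text beyond what the
normaliser repairs, and realistic named-entity recognition errors
(entities are planted, not recognised). End-to-end scores on these
corpora (the suite requires micro-F1 ≥ 0.90 for the pair pipeline on a
60/20 split with 30 % surface variation) characterise correctness of
the machinery, not expected performance on real articles.

## Numerical choices and degenerate inputs

- Empty token lists score 0 under SoftTFIDF; two empty strings have
  Jaro similarity 1 by convention.
- Scores are clamped to [0, 1] against floating-point drift.
- Training requires both classes; single-class inputs are hard errors
  rather than silent degenerate models. All learners run with fixed
  random state and tightened iteration limits, so retraining on
  identical data reproduces identical models.
- Duplicate (chunk, MI id) candidates arising through multiple synonyms
  collapse to the maximum similarity.
- AUC iP/R requires at least one gold positive (hard error otherwise).

## Problem sizes

The default experiment sizes used throughout the suite and examples —
8-term ontologies, 60-document training corpora, 20-document held-out
splits, 5-fold knockout cross-validation on 60 abstracts — were chosen
so that every end-to-end property runs comfortably on a single CPU
while still containing enough signal for the classifiers to recover the
planted structure; they are the package's reference study conditions.

## Known limitations

- The heuristic POS tagger and chunker are intentionally simple; real
  deployments should ingest external token/chunk layers through the
  standoff format.
- The MI→MeSH cascade's permissive partial match can over-map in large
  descriptor inventories; it is tuned for the frequent-method use case.
- No PPI relation extraction precedes method detection, so methods
  mentioned outside an established-interaction context are
  indistinguishable from evidential mentions.
- SVM scores are uncalibrated margins; cross-system score comparison
  should use the logistic models.
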