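# ppiminer

Text-mining toolkit for two linked biocuration problems around
protein-protein interactions (PPI):

- **Interaction-method detection** — given a full-text article, decide
  which experimental techniques (PSI-MI *interaction detection method*
  concepts, identified by MI ids such as `MI:0007`) were used to
  establish the reported interactions. Zero or more labels per
  document.
- **Curation triage** — given an abstract, decide whether the paper
  reports curatable protein-protein interactions at all.

It is aimed at curators and text-mining researchers who need a
self-contained, testable implementation of the classic
candidate-matching + classification pipeline for these tasks.

## The methods

**Pair classification (b-SVM).** Instead of one classifier per
technique, the multi-label problem is reduced to a single binary
decision. Every noun/verb-phrase chunk *c* is compared against every
ontology method name or synonym *n* with **SoftTFIDF**: tokens carry
L2-normalised TF-IDF weights and two tokens may match approximately
when their **Jaro-Winkler** similarity reaches 0.85, so that
`pull down` ~ `pull-down` and `antibodies` ~ `anti` still contribute.
Pairs *p* = {*c*, *n*} scoring above 0.5 become candidates; a linear
classifier then decides from the chunk's context (context windows,
neighbouring named entities, matches against the concept's synonyms and
TF-IDF-ranked definition tokens, section titles, MeSH evidence) whether
the pair really evidences use of the method. MI ids of positive pairs
are assigned to the document.

**One-vs-all document classification (m-LR / m-SVM).** One
L2-regularised logistic-regression or linear-SVM model per method with
at least one positive training document, over entity/context features
plus word-unigram and character n-gram (n ∈ {2,3,4}) matches between
each concept's definition+synonyms and the document. Scores are turned
into label sets by per-class or global thresholds tuned on held-out
documents (objective: accuracy or F1; logistic probabilities keep a
0.10 floor). Union/intersection ensembles combine systems.

**Triage (ACT).** A binary linear model over feature groups B (bag of
words), N (named entities), C (protein-sentence context: words, plus
verbs/nouns with signed position relative to the protein mention) and M
(MeSH descriptors, optionally expanded into hierarchical tree-number
prefixes: `E05.196.150` → `E05`, `E05.196`, `E05.196.150`), with a
feature-knockout harness.

Evaluation uses the tasks' standard metrics: micro precision/recall/F1,
specificity, sensitivity, accuracy, Matthews correlation, and AUC iP/R
(area under the interpolated precision-recall curve). A seeded
synthetic-corpus generator produces toy ontologies, sectioned full-text
documents with planted (optionally perturbed) method mentions, and
triage abstracts, so the whole pipeline is testable without any
external corpus.

## Worked example

```python
from ppiminer.corpus import tokenize
from ppiminer.ontology import mesh_tree_prefixes
from ppiminer.stringsim import SimilarityConfig, build_corpus_stats, soft_tfidf

names = ["anti tag coimmunoprecipitation", "anti bait coimmunoprecipitation",
         "pull down", "two hybrid", "X-ray crystallography"]
bag = lambda s: [t.lemma for t in tokenize(s) if not t.is_stop]
stats = build_corpus_stats([bag(n) for n in names])

score = soft_tfidf(bag("anti-His tag antibodies"),
                   bag("anti tag coimmunoprecipitation"),
                   stats, SimilarityConfig())
print(f"{score:.3f}")                      # 0.801
print(mesh_tree_prefixes("E05.196.150"))   # ['E05', 'E05.196', 'E05.196.150']
```

The chunk `anti-His tag antibodies` scores 0.801 against the method
name `anti tag coimmunoprecipitation` — well above the 0.5 retention
threshold, so the pair is kept for classification even though the two
strings share only part of their tokens. The MeSH tree number expands
into three hierarchical features, one per dotted prefix.

An end-to-end run on a synthetic corpus:

```bash
ppiminer synth imt --seed 3 --n-docs 20 --out /tmp/corpus
ppiminer corpus validate /tmp/corpus      # ok: 20 documents valid
ppiminer imt train-bsvm --corpus /tmp/corpus --out /tmp/model.pkl
ppiminer imt predict-bsvm --corpus /tmp/corpus --model /tmp/model.pkl --out /tmp/pred.tsv
```

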