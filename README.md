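# ontotriage

A toolkit for literature-curation support in molecular-interaction databases,
with two independent pipelines:

* **Triage (`act-*`)** — binary classification of articles (title + abstract)
  as interaction-relevant or not: n-gram features over a normalization
  pipeline (lowercase, punctuation removal, Porter stemming, number removal),
  feature selection by mutual information or chi-square, and either a naive
  Bayes model with add-one smoothing on binary indicators or a
  polynomial-kernel SVM with calibrated confidences.
* **Ontology mapping (`imt-*`)** — assignment of ontology nodes (e.g. the
  PSI-MI interaction-detection-methods vocabulary in OBO format) to full-text
  articles, cast as article–node pair classification over 21 lexicon-match
  features (perfect match, unigram/bigram matches and ratios, matched-term
  MI/chi-square sums, node popularity, regex-annotator hook, keyword
  presence), trained with tree-based learners (random forest, random
  committee, naive-Bayes tree, decision tree) after chi-square feature
  selection, plus evidence-sentence extraction by concept-unigram chi-square
  scoring.

A shared evaluation module provides confusion counts, precision/recall/F1,
accuracy, sensitivity, specificity, Matthews correlation, and interpolated
AUC iP/R over ranked predictions. A synthetic-fixture module generates
seeded corpora/ontologies/annotations with planted signal so every stage is
testable offline.

## Layout

```
src/ontotriage/
  corpus_io.py           TSV/plain-text corpora, OBO parsing, supplements,
                         annotations, prediction files
  textnorm.py            normalization, n-grams, sentence splitting
  _porter.py             Porter stemmer (original algorithm)
  feature_scoring.py     2x2 tables, MI, chi-square, top-K selection
  act_pipeline.py        triage vectorization, training, ranked prediction
  imt_features.py        node lexicons, term statistics, the 21 pair features
  imt_pipeline.py        pair instances, feature selection, classifiers,
                         evidence sentences
  evaluation.py          all metrics
  synthetic_fixtures.py  seeded synthetic data generators
  presets.py + presets/  the 10 triage and 10 mapping run presets
  cli.py                 command-line interface
```

## CLI

All commands are subcommands of a single entry point:

```bash
# generate a synthetic, ready-to-train fixture tree
ontotriage fixtures --task act --out-dir fx-act --seed 1 --n-docs 200
ontotriage fixtures --task imt --out-dir fx-imt --seed 1 --n-docs 100 --n-nodes 20

# triage: train / predict / evaluate
ontotriage act-train --corpus fx-act/corpus.tsv --preset SVM-1-400-td \
    --model-out model.bin --seed 1
ontotriage act-predict --model model.bin --corpus fx-act/corpus.tsv --out preds.tsv
ontotriage act-eval --gold fx-act/corpus.tsv --predictions preds.tsv

# ontology mapping: train / predict / evaluate
ontotriage imt-train --corpus-dir fx-imt/fulltext --annotations fx-imt/annotations.tsv \
    --obo fx-imt/ontology.obo --supplement fx-imt/supplement.tsv \
    --preset rf-12 --model-out imt.bin --seed 1
ontotriage imt-predict --model imt.bin --corpus-dir fx-imt/fulltext --out imt-preds.tsv
ontotriage imt-eval --gold fx-imt/annotations.tsv --predictions imt-preds.tsv \
    --corpus-dir fx-imt/fulltext --obo fx-imt/ontology.obo
```

Run presets are named config files shipped with the package (triage:
`NBM-12-1k-td` … `SVM-1-400-td`; mapping: `j48-21` … `rf-15`). Any preset
field can be overridden via `--config file.yaml` (a `preset:` key seeds the
defaults); `--dump-config` prints the resolved configuration.

### File formats

* Triage corpus: TSV with header `doc_id  label  title  abstract`
  (label empty for unlabeled documents).
* Full-text corpus: a directory of UTF-8 `.txt` files, filename stem =
  document ID (subdirectories ignored).
* Ontology: OBO 1.2 flat file; obsolete terms excluded; all synonym scopes
  ingested by default.
* Lexicon supplement: TSV `node_id  kind  value` with kind in
  `{synonym, keyword}`.
* Annotations (gold or predicted): TSV `doc_id  node_id`.
* Term statistics / scored vocabulary: TSV `term  mi  chi2`.

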