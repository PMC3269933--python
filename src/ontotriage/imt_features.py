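"""Per-node lexicons and the 21 article-node pair features used by the
ontology-mapping classifier.

Feature groups (21 values total):
  * perfect match of the concept name / any synonym (2, binary)
  * unigram/bigram term match for concept / synonyms (4, binary)
  * unigram/bigram term-match ratio for concept / synonyms (4, in [0,1])
  * matched-term mutual-information sums (4, >= 0)
  * matched-term chi-square sums (4, >= 0)
  * node popularity (training annotation count)
  * regex-annotator hit (pluggable, default 0)
  * keyword presence (binary)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .corpus_io import AnnotationSet, DocumentRecord, LabeledCorpus, OntologyNode
from .feature_scoring import (ContingencyTable2x2, FeatureScore,
                              ScoredVocabulary, chi_square,
                              mutual_information, read_term_scores,
                              write_term_scores)
from .textnorm import (NORMALIZATION_VERSION, extract_ngrams,
                       normalize_and_tokenize)

__all__ = [
    "FEATURE_NAMES",
    "NodeLexicon",
    "TermStatistics",
    "DocumentView",
    "build_node_lexicon",
    "compute_term_statistics",
    "compute_node_popularity",
    "extract_pair_features",
    "PairFeatureVector",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "perfect_match_concept",
    "perfect_match_synonym",
    "term_match_uni_concept",
    "term_match_bi_concept",
    "term_match_uni_synonym",
    "term_match_bi_synonym",
    "term_match_ratio_uni_concept",
    "term_match_ratio_bi_concept",
    "term_match_ratio_uni_synonym",
    "term_match_ratio_bi_synonym",
    "mi_sum_uni_concept",
    "mi_sum_bi_concept",
    "mi_sum_uni_synonym",
    "mi_sum_bi_synonym",
    "chi2_sum_uni_concept",
    "chi2_sum_bi_concept",
    "chi2_sum_uni_synonym",
    "chi2_sum_bi_synonym",
    "node_popularity",
    "regex_annotation",
    "keyword_presence",
)


@dataclass(frozen=True)
class NodeLexicon:
    """Normalized matching material derived from one ontology node."""

    node_id: str
    name_tokens: Tuple[str, ...]
    raw_token_sequences: Tuple[Tuple[str, ...], ...]  # name + synonyms, for perfect match
    synonym_token_sequences: Tuple[Tuple[str, ...], ...]
    concept_unigrams: FrozenSet[str]
    concept_bigrams: FrozenSet[str]
    synonym_unigrams: FrozenSet[str]
    synonym_bigrams: FrozenSet[str]
    keyword: Optional[str] = None
    normalization_version: str = NORMALIZATION_VERSION


class TermStatistics:
    """Normalized n-gram -> (mi, chi2); unknown terms score (0, 0)."""

    def __init__(self, scores: Mapping[str, Tuple[float, float]],
                 label_definition: str = "annotated_with_term_node",
                 normalization_version: str = NORMALIZATION_VERSION) -> None:
        for term, (mi, chi2) in scores.items():
            if mi < 0 or chi2 < 0:
                raise ValueError(f"negative score for term {term!r}")
        self._scores = dict(scores)
        self.label_definition = label_definition
        self.normalization_version = normalization_version

    def get(self, term: str) -> Tuple[float, float]:
        return self._scores.get(term, (0.0, 0.0))

    def mi(self, term: str) -> float:
        return self.get(term)[0]

    def chi2(self, term: str) -> float:
        return self.get(term)[1]

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, term: str) -> bool:
        return term in self._scores

    def to_tsv(self, path) -> None:
        entries = [FeatureScore(t, mi, chi2)
                   for t, (mi, chi2) in sorted(self._scores.items())]
        write_term_scores(ScoredVocabulary(entries), path)

    @classmethod
    def from_tsv(cls, path) -> "TermStatistics":
        vocab = read_term_scores(path)
        return cls(vocab.as_dict())


def _ngram_sets(token_seqs: Sequence[Tuple[str, ...]]) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    unis: Set[str] = set()
    bis: Set[str] = set()
    for seq in token_seqs:
        unis.update(seq)
        bis.update(f"{a} {b}" for a, b in zip(seq, seq[1:]))
    return frozenset(unis), frozenset(bis)


def build_node_lexicon(node: OntologyNode) -> NodeLexicon:
    """Normalize a node's name, synonyms and keyword into matching sets."""
    name_tokens = tuple(normalize_and_tokenize(node.name))
    syn_seqs = tuple(
        seq for seq in (tuple(normalize_and_tokenize(s)) for s in node.synonyms) if seq
    )
    concept_uni, concept_bi = _ngram_sets([name_tokens] if name_tokens else [])
    syn_uni, syn_bi = _ngram_sets(syn_seqs)
    keyword = None
    if node.keyword is not None:
        kw_tokens = normalize_and_tokenize(node.keyword)
        if len(kw_tokens) != 1:
            raise ValueError(
                f"node {node.node_id!r}: keyword {node.keyword!r} must normalize "
                f"to a single token, got {kw_tokens}"
            )
        keyword = kw_tokens[0]
    raw_seqs = tuple(s for s in ((name_tokens,) + syn_seqs) if s)
    return NodeLexicon(
        node_id=node.node_id,
        name_tokens=name_tokens,
        raw_token_sequences=raw_seqs,
        synonym_token_sequences=syn_seqs,
        concept_unigrams=concept_uni,
        concept_bigrams=concept_bi,
        synonym_unigrams=syn_uni,
        synonym_bigrams=syn_bi,
        keyword=keyword,
    )


def compute_term_statistics(
    corpus: LabeledCorpus,
    annotations: AnnotationSet,
    lexicons: Sequence[NodeLexicon],
) -> TermStatistics:
    """Score every node-derived n-gram against the training corpus.

    For a term t, a document counts as positive iff it is annotated with at
    least one node whose lexicon contains t; presence is document-level
    binary occurrence of t in the document's n-grams.
    """
    if len(annotations) == 0:
        raise ValueError("annotation set must be non-empty")
    term_nodes: Dict[str, Set[str]] = {}
    for lex in lexicons:
        for term in (lex.concept_unigrams | lex.concept_bigrams
                     | lex.synonym_unigrams | lex.synonym_bigrams):
            term_nodes.setdefault(term, set()).add(lex.node_id)

    doc_grams: Dict[str, Set[str]] = {}
    for doc in corpus:
        doc_grams[doc.doc_id] = set(
            extract_ngrams(normalize_and_tokenize(doc.text), (1, 2))
        )

    scores: Dict[str, Tuple[float, float]] = {}
    n_docs = len(corpus)
    for term in sorted(term_nodes):
        nodes = term_nodes[term]
        a = b = c = d = 0
        for doc in corpus:
            present = term in doc_grams[doc.doc_id]
            positive = bool(annotations.nodes_for(doc.doc_id) & nodes)
            if present and positive:
                a += 1
            elif present:
                b += 1
            elif positive:
                c += 1
            else:
                d += 1
        t = ContingencyTable2x2(a, b, c, d)
        scores[term] = (mutual_information(t), chi_square(t))
    return TermStatistics(scores)


def compute_node_popularity(annotations: AnnotationSet) -> Dict[str, int]:
    """Training-annotation count per node (set semantics per document)."""
    counts: Dict[str, int] = {}
    for nodes in annotations.pairs.values():
        for n in nodes:
            counts[n] = counts.get(n, 0) + 1
    return counts


class DocumentView:
    """Precomputed normalized token/n-gram view of one document, so that
    feature extraction against many nodes scans the text only once."""

    def __init__(self, doc: DocumentRecord) -> None:
        self.doc_id = doc.doc_id
        self.tokens: Tuple[str, ...] = tuple(normalize_and_tokenize(doc.text))
        self.unigrams: FrozenSet[str] = frozenset(self.tokens)
        self.bigrams: FrozenSet[str] = frozenset(
            f"{a} {b}" for a, b in zip(self.tokens, self.tokens[1:])
        )

    def contains_sequence(self, seq: Tuple[str, ...]) -> bool:
        if not seq:
            return False
        if len(seq) == 1:
            return seq[0] in self.unigrams
        first = seq[0]
        toks = self.tokens
        n, m = len(toks), len(seq)
        for i in range(n - m + 1):
            if toks[i] == first and toks[i : i + m] == seq:
                return True
        return False


@dataclass(frozen=True)
class PairFeatureVector:
    doc_id: str
    node_id: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values, got {len(self.values)}")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]


def _group_features(grams: FrozenSet[str], doc_grams: FrozenSet[str],
                    stats: TermStatistics) -> Tuple[float, float, float, float]:
    """(match, ratio, mi_sum, chi2_sum) for one lexicon n-gram group.

    Sums count each distinct matched n-gram once; empty groups give ratios
    of 0 rather than a division error.
    """
    if not grams:
        return 0.0, 0.0, 0.0, 0.0
    matched = grams & doc_grams
    ratio = len(matched) / len(grams)
    mi_sum = sum(stats.mi(t) for t in matched)
    chi2_sum = sum(stats.chi2(t) for t in matched)
    return (1.0 if matched else 0.0), ratio, mi_sum, chi2_sum


def extract_pair_features(
    doc: "DocumentRecord | DocumentView",
    lex: NodeLexicon,
    stats: TermStatistics,
    popularity: Mapping[str, int],
    regex_hit: bool = False,
) -> PairFeatureVector:
    """Compute the 21 named features for one article-node pair.

    Matching is on normalized (stemmed) tokens. Perfect match requires the
    node's full normalized name (or any synonym's) token sequence to occur
    contiguously in the document token sequence.
    """
    if lex.normalization_version != stats.normalization_version:
        raise ValueError("lexicon and term statistics normalization versions differ")
    view = doc if isinstance(doc, DocumentView) else DocumentView(doc)

    pm_concept = 1.0 if view.contains_sequence(lex.name_tokens) else 0.0
    pm_synonym = 1.0 if any(view.contains_sequence(s) for s in lex.synonym_token_sequences) else 0.0

    uc = _group_features(lex.concept_unigrams, view.unigrams, stats)
    bc = _group_features(lex.concept_bigrams, view.bigrams, stats)
    us = _group_features(lex.synonym_unigrams, view.unigrams, stats)
    bs = _group_features(lex.synonym_bigrams, view.bigrams, stats)

    values = (
        pm_concept,
        pm_synonym,
        uc[0], bc[0], us[0], bs[0],
        uc[1], bc[1], us[1], bs[1],
        uc[2], bc[2], us[2], bs[2],
        uc[3], bc[3], us[3], bs[3],
        float(popularity.get(lex.node_id, 0)),
        1.0 if regex_hit else 0.0,
        1.0 if (lex.keyword is not None and lex.keyword in view.unigrams) else 0.0,
    )
    return PairFeatureVector(doc_id=view.doc_id, node_id=lex.node_id, values=values)
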