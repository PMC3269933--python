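"""Seeded synthetic corpora, ontologies and annotations with planted signal.

Background text is sampled from a Zipf-like distribution over a vocabulary
of tokens that are fixed points of the normalization pipeline, so planted
discriminative terms are recoverable by feature scoring without stemming
collisions. Fixture trees are written in the exact external formats (TSV
corpus, plain-text directory, OBO) to exercise the real readers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .corpus_io import (AnnotationSet, DocumentRecord, LabeledCorpus,
                        OntologyNode, write_act_corpus, write_annotations,
                        write_fulltext_corpus, write_obo)
from .textnorm import normalize_and_tokenize

__all__ = [
    "ActFixtureSpec", "ImtFixtureSpec",
    "make_act_fixture", "make_imt_fixture",
    "write_act_fixture_tree", "write_imt_fixture_tree",
]

# Letters chosen so generated words avoid Porter-active suffixes
# (no s/e/d/y endings -> stems are the words themselves).
_ALPHABET = "bcfgjklmnpqrtvwxz"


def _stable_words(count: int, prefix: str = "") -> List[str]:
    """Generate `count` distinct tokens invariant under normalization."""
    words: List[str] = []
    seen = set()
    for size in itertools.count(2):
        for combo in itertools.product(_ALPHABET, repeat=size):
            w = prefix + "".join(combo)
            stemmed = normalize_and_tokenize(w)
            if len(stemmed) == 1 and stemmed[0] == w and w not in seen:
                words.append(w)
                seen.add(w)
                if len(words) == count:
                    return words
    raise AssertionError("unreachable")


def _zipf_probs(size: int) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = 1.0 / ranks
    return p / p.sum()


@dataclass(frozen=True)
class ActFixtureSpec:
    """Parameters of a labeled triage corpus with planted signal terms."""

    n_pos: int = 100
    n_neg: int = 100
    n_signal_terms: int = 5
    vocab_size: int = 200
    doc_length: int = 40
    noise_rate: float = 0.0
    max_planted_per_doc: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one document")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.n_signal_terms < 1 or self.vocab_size < 2 or self.doc_length < 2:
            raise ValueError("invalid fixture dimensions")
        if self.max_planted_per_doc < 1:
            raise ValueError("max_planted_per_doc must be >= 1")


def make_act_fixture(spec: ActFixtureSpec) -> Tuple[LabeledCorpus, List[str]]:
    """Generate a labeled corpus; every positive contains at least one
    signal term, negatives contain each signal term with probability
    ``noise_rate``. Pure function of the spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    signal = _stable_words(spec.n_signal_terms, prefix="zz")
    background = _stable_words(spec.vocab_size, prefix="q")
    probs = _zipf_probs(spec.vocab_size)

    docs: List[DocumentRecord] = []
    width = len(str(spec.n_pos + spec.n_neg))
    for i in range(spec.n_pos + spec.n_neg):
        positive = i < spec.n_pos
        words = list(rng.choice(background, size=spec.doc_length, p=probs))
        if positive:
            # few signal terms per positive keeps a clean margin without
            # saturating per-term presence rates
            planted = rng.integers(1, min(spec.n_signal_terms, spec.max_planted_per_doc) + 1)
            idx = rng.choice(spec.n_signal_terms, size=planted, replace=False)
            words.extend(signal[j] for j in sorted(idx))
        else:
            for term in signal:
                if rng.random() < spec.noise_rate:
                    words.append(term)
        rng.shuffle(words)
        docs.append(
            DocumentRecord(
                doc_id=f"D{i:0{width}d}",
                title=f"Synthetic document {i}",
                body=" ".join(words),
                gold_label=int(positive),
            )
        )
    return LabeledCorpus(docs), signal


@dataclass(frozen=True)
class ImtFixtureSpec:
    """Parameters of a synthetic full-text corpus + ontology + gold pairs."""

    n_nodes: int = 20
    synonyms_per_node: int = 1
    n_docs: int = 100
    annotations_per_doc: float = 2.14
    mention_rate: float = 1.0
    distractor_rate: float = 0.0
    doc_length: int = 60
    vocab_size: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annotations_per_doc <= 0:
            raise ValueError("annotations_per_doc must be positive")
        if not 0.0 <= self.mention_rate <= 1.0 or not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if self.n_nodes < 2 or self.n_docs < 1:
            raise ValueError("need at least 2 nodes and 1 document")


def _make_nodes(spec: ImtFixtureSpec) -> List[OntologyNode]:
    # 2 unique name tokens + 2 unique tokens per synonym keep node
    # vocabularies pairwise disjoint.
    per_node = 2 + 2 * spec.synonyms_per_node
    words = _stable_words(spec.n_nodes * per_node, prefix="m")
    nodes = []
    for i in range(spec.n_nodes):
        chunk = words[i * per_node : (i + 1) * per_node]
        name = f"{chunk[0]} {chunk[1]}"
        synonyms = [
            f"{chunk[2 + 2 * j]} {chunk[3 + 2 * j]}"
            for j in range(spec.synonyms_per_node)
        ]
        nodes.append(
            OntologyNode(
                node_id=f"FX:{i:04d}", name=name, synonyms=synonyms,
                keyword=chunk[0],
            )
        )
    return nodes


def make_imt_fixture(
    spec: ImtFixtureSpec,
) -> Tuple[LabeledCorpus, List[OntologyNode], AnnotationSet]:
    """Generate full-text documents mentioning their gold nodes' names.

    Gold node counts per document are Poisson around the target mean
    (capped at n_nodes); each gold node's name is inserted verbatim with
    probability ``mention_rate`` and non-gold names leak in with
    probability ``distractor_rate``. Text is split into sentences so the
    sentence splitter and evidence scorer see realistic structure.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = _make_nodes(spec)
    background = _stable_words(spec.vocab_size, prefix="b")
    probs = _zipf_probs(spec.vocab_size)

    docs: List[DocumentRecord] = []
    annotations = AnnotationSet()
    width = len(str(spec.n_docs))
    for i in range(spec.n_docs):
        doc_id = f"F{i:0{width}d}"
        n_gold = min(int(rng.poisson(spec.annotations_per_doc)), spec.n_nodes)
        gold_idx = sorted(rng.choice(spec.n_nodes, size=n_gold, replace=False))
        phrases: List[str] = []
        for j in gold_idx:
            annotations.add(doc_id, nodes[j].node_id)
            if rng.random() < spec.mention_rate:
                phrases.append(nodes[j].name)
        for j in range(spec.n_nodes):
            if j not in gold_idx and rng.random() < spec.distractor_rate:
                phrases.append(nodes[j].name)
        words = list(rng.choice(background, size=spec.doc_length, p=probs))
        # distribute phrases over sentence-sized chunks of background text
        sentence_len = 10
        chunks = [words[k : k + sentence_len] for k in range(0, len(words), sentence_len)]
        for p, phrase in enumerate(phrases):
            chunks[p % len(chunks)].append(phrase)
        sentences = [" ".join(c).capitalize() + "." for c in chunks if c]
        docs.append(DocumentRecord(doc_id=doc_id, body=" ".join(sentences)))
    return LabeledCorpus(docs), nodes, annotations


def write_act_fixture_tree(spec: ActFixtureSpec, directory) -> Dict[str, Path]:
    """Emit a ready-to-train triage fixture: corpus TSV + signal-term list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    corpus, signal = make_act_fixture(spec)
    paths = {
        "corpus": directory / "corpus.tsv",
        "signal_terms": directory / "signal_terms.txt",
    }
    write_act_corpus(corpus, paths["corpus"])
    paths["signal_terms"].write_text("\n".join(signal) + "\n", encoding="utf-8")
    return paths


def write_imt_fixture_tree(spec: ImtFixtureSpec, directory) -> Dict[str, Path]:
    """Emit a ready-to-train ontology-mapping fixture: full-text directory,
    OBO ontology, gold annotations, and a keyword supplement."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    corpus, nodes, annotations = make_imt_fixture(spec)
    paths = {
        "fulltext": directory / "fulltext",
        "obo": directory / "ontology.obo",
        "annotations": directory / "annotations.tsv",
        "supplement": directory / "supplement.tsv",
    }
    write_fulltext_corpus(corpus, paths["fulltext"])
    write_obo(nodes, paths["obo"])
    write_annotations(annotations, paths["annotations"])
    supplement_lines = [
        f"{n.node_id}\tkeyword\t{n.keyword}" for n in nodes if n.keyword
    ]
    paths["supplement"].write_text(
        "\n".join(supplement_lines) + "\n", encoding="utf-8"
    )
    return paths
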