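"""Contingency tables, mutual information and chi-square feature scoring,
and top-K selection — the statistical core shared by both tasks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .corpus_io import LabeledCorpus
from .textnorm import extract_ngrams, normalize_and_tokenize

__all__ = [
    "ContingencyTable2x2",
    "FeatureScore",
    "ScoredVocabulary",
    "build_contingency",
    "mutual_information",
    "chi_square",
    "score_vocabulary",
    "select_top_k",
    "write_term_scores",
    "read_term_scores",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Term-presence x class counts.

    a: present & positive, b: present & negative,
    c: absent & positive,  d: absent & negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table must have n > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FeatureScore:
    term: str
    mi: float
    chi2: float


@dataclass
class ScoredVocabulary:
    """All corpus n-grams with their MI (bits) and chi-square scores."""

    entries: List[FeatureScore]
    source_label_definition: str = "gold_label"

    def __post_init__(self) -> None:
        terms = [e.term for e in self.entries]
        if len(terms) != len(set(terms)):
            raise ValueError("vocabulary terms must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> Dict[str, Tuple[float, float]]:
        return {e.term: (e.mi, e.chi2) for e in self.entries}


def build_contingency(
    term: str,
    corpus: LabeledCorpus,
    labels: Mapping[str, int],
    orders: Iterable[int] = (1, 2),
) -> ContingencyTable2x2:
    """Document-level binary presence of ``term`` cross-tabulated with class."""
    if not term:
        raise ValueError("term must be non-empty")
    a = b = c = d = 0
    for doc in corpus:
        if doc.doc_id not in labels:
            raise ValueError(f"document {doc.doc_id!r} has no label")
        present = term in set(extract_ngrams(normalize_and_tokenize(doc.text), orders))
        positive = bool(labels[doc.doc_id])
        if present and positive:
            a += 1
        elif present:
            b += 1
        elif positive:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def mutual_information(t: ContingencyTable2x2) -> float:
    """MI(F;C) in bits over the four joint cells, with 0*log(0) = 0."""
    n = t.n
    joint = ((t.a, t.a + t.b, t.a + t.c), (t.b, t.a + t.b, t.b + t.d),
             (t.c, t.c + t.d, t.a + t.c), (t.d, t.c + t.d, t.b + t.d))
    mi = 0.0
    for cell, row, col in joint:
        if cell == 0:
            continue
        mi += (cell / n) * math.log2(cell * n / (row * col))
    return max(mi, 0.0)


def chi_square(t: ContingencyTable2x2) -> float:
    """Pearson statistic, 2x2 closed form, no continuity correction.

    Any zero margin returns 0 by convention.
    """
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    if 0 in (row1, row2, col1, col2):
        return 0.0
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    return num / (row1 * row2 * col1 * col2)


def score_vocabulary(
    corpus: LabeledCorpus,
    labels: Mapping[str, int],
    orders: Iterable[int] = (1, 2),
) -> ScoredVocabulary:
    """Score the union of all corpus n-grams with MI and chi-square."""
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    doc_grams: List[Tuple[Set[str], bool]] = []
    for doc in corpus:
        if doc.doc_id not in labels:
            raise ValueError(f"document {doc.doc_id!r} has no label")
        grams = set(extract_ngrams(normalize_and_tokenize(doc.text), orders))
        doc_grams.append((grams, bool(labels[doc.doc_id])))
    n_pos = sum(1 for _, p in doc_grams if p)
    n_neg = len(doc_grams) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to score features")

    counts: Dict[str, List[int]] = {}
    for grams, positive in doc_grams:
        for g in grams:
            cell = counts.setdefault(g, [0, 0])
            cell[0 if positive else 1] += 1

    entries = []
    for term in sorted(counts):
        a, b = counts[term]
        t = ContingencyTable2x2(a, b, n_pos - a, n_neg - b)
        entries.append(FeatureScore(term, mutual_information(t), chi_square(t)))
    return ScoredVocabulary(entries)


def select_top_k(vocab: ScoredVocabulary, k: int, method: str) -> List[str]:
    """Top-k terms by the chosen score, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if method not in ("mi", "chi2"):
        raise ValueError(f"method must be 'mi' or 'chi2', got {method!r}")
    key = (lambda e: (-e.mi, e.term)) if method == "mi" else (lambda e: (-e.chi2, e.term))
    ranked = sorted(vocab.entries, key=key)
    return [e.term for e in ranked[:k]]


def write_term_scores(vocab: ScoredVocabulary, path) -> None:
    """Serialize as TSV ``term  mi  chi2`` — also the term-statistics format
    consumed by the ontology-mapping feature extractor."""
    lines = ["term\tmi\tchi2"]
    for e in vocab.entries:
        lines.append(f"{e.term}\t{e.mi!r}\t{e.chi2!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_term_scores(path) -> ScoredVocabulary:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != "term\tmi\tchi2":
        raise ValueError(f"{path}: expected header 'term\\tmi\\tchi2'")
    entries = []
    for line in lines[1:]:
        if not line:
            continue
        term, mi, chi2 = line.split("\t")
        entries.append(FeatureScore(term, float(mi), float(chi2)))
    return ScoredVocabulary(entries)
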