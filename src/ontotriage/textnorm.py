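"""Text normalization, n-gram extraction and sentence splitting.

The normalization pipeline is shared by the triage and ontology-mapping
tasks: lowercase, replace punctuation with spaces, split on whitespace,
drop purely numeric tokens, Porter-stem the survivors.
"""

from __future__ import annotations

import re
import string
import unicodedata
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

from ._porter import porter_stem

__all__ = [
    "NORMALIZATION_VERSION",
    "Sentence",
    "normalize_and_tokenize",
    "extract_ngrams",
    "ngram_set",
    "split_sentences",
]

#: Bump when the pipeline changes; serialized alongside models/statistics so
#: that mismatched artifacts are rejected instead of silently mis-matching.
NORMALIZATION_VERSION = "1"

# Purely numeric tokens, optionally with . or , separators (e.g. "10,000").
_NUMERIC_RE = re.compile(r"^[0-9]+([.,][0-9]+)*[.,]?$")

_ASCII_PUNCT = set(string.punctuation)


def _is_punct(ch: str) -> bool:
    return ch in _ASCII_PUNCT or unicodedata.category(ch).startswith("P")


_PUNCT_CACHE: dict = {}


def _strip_punct(text: str) -> str:
    out = []
    for ch in text:
        repl = _PUNCT_CACHE.get(ch)
        if repl is None:
            repl = " " if _is_punct(ch) else ch
            _PUNCT_CACHE[ch] = repl
        out.append(repl)
    return "".join(out)


def normalize_and_tokenize(text: str) -> List[str]:
    """Run the full normalization pipeline on raw text.

    Order is fixed: lowercase -> punctuation to spaces -> whitespace split
    -> drop purely numeric tokens -> Porter stem. Alphanumeric tokens such
    as ``gal4`` are kept.
    """
    tokens = _strip_punct(text.lower()).split()
    return [porter_stem(t) for t in tokens if not _NUMERIC_RE.match(t)]


def extract_ngrams(tokens: Sequence[str], orders: Iterable[int] = (1, 2)) -> List[str]:
    """Unigrams in token order, then bigrams of consecutive tokens.

    ``orders`` must be a non-empty subset of {1, 2}.
    """
    orders = set(orders)
    if not orders or not orders <= {1, 2}:
        raise ValueError(f"orders must be a non-empty subset of {{1, 2}}, got {sorted(orders)}")
    out: List[str] = []
    if 1 in orders:
        out.extend(tokens)
    if 2 in orders:
        out.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return out


def ngram_set(text: str, orders: Iterable[int] = (1, 2)) -> Set[str]:
    """Convenience: the set of normalized n-grams of a text."""
    return set(extract_ngrams(normalize_and_tokenize(text), orders))


@dataclass(frozen=True)
class Sentence:
    """A raw-text sentence with character offsets into the source text."""

    text: str
    start: int
    end: int


#: Tokens that end with '.' but do not terminate a sentence.
ABBREVIATIONS = (
    "fig.", "figs.", "al.", "e.g.", "i.e.", "etc.", "vs.", "cf.", "no.",
    "dr.", "prof.", "st.", "ref.", "refs.", "eq.", "eqs.", "approx.",
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")


def _ends_with_abbreviation(prefix: str) -> bool:
    tail = prefix.lower().rstrip()
    return any(tail.endswith(abbr) for abbr in ABBREVIATIONS)


def split_sentences(text: str) -> List[Sentence]:
    """Rule-based sentence splitter preserving character offsets.

    Splits after sentence-final punctuation followed by whitespace and an
    uppercase letter or digit, guarded by a small abbreviation list.
    The original substring is recoverable as ``text[s.start:s.end]``.
    """
    if not text.strip():
        return []
    boundaries = []
    for m in _BOUNDARY_RE.finditer(text):
        if _ends_with_abbreviation(text[: m.end()]):
            continue
        boundaries.append(m.end())
    sentences: List[Sentence] = []
    prev = 0
    for b in boundaries + [len(text)]:
        chunk = text[prev:b]
        if chunk.strip():
            start = prev + (len(chunk) - len(chunk.lstrip()))
            end = prev + len(chunk.rstrip())
            sentences.append(Sentence(text[start:end], start, end))
        prev = b
    return sentences
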