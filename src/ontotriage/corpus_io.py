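"""I/O for corpora, OBO ontologies, lexicon supplements, annotations and
predictions.

All files are UTF-8 TSV except full-text corpora (one plain-text file per
document) and ontologies (OBO 1.2 flat files). Writers are bit-stable:
identical inputs produce identical bytes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "DocumentRecord",
    "LabeledCorpus",
    "OntologyNode",
    "AnnotationSet",
    "CorpusFormatError",
    "read_act_corpus",
    "write_act_corpus",
    "read_fulltext_corpus",
    "write_fulltext_corpus",
    "parse_obo",
    "write_obo",
    "read_lexicon_supplement",
    "apply_supplement",
    "read_annotations",
    "write_annotations",
    "write_predictions",
    "read_count_summary",
    "annotations_per_article",
]


class CorpusFormatError(ValueError):
    """Raised for malformed or invariant-violating input files."""


@dataclass(frozen=True)
class DocumentRecord:
    """One article: identifier, title/body text, optional binary gold label."""

    doc_id: str
    title: str = ""
    body: str = ""
    gold_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusFormatError("doc_id must be non-empty")
        if not self.title and not self.body:
            raise CorpusFormatError(f"document {self.doc_id!r}: title and body both empty")
        if self.gold_label is not None and self.gold_label not in (0, 1):
            raise CorpusFormatError(f"document {self.doc_id!r}: gold_label must be 0 or 1")

    @property
    def text(self) -> str:
        """Title and body concatenated (the classification input)."""
        return f"{self.title}\n{self.body}" if self.title else self.body


@dataclass
class LabeledCorpus:
    """An ordered document collection with per-label counts."""

    documents: List[DocumentRecord]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def label_counts(self) -> Dict[int, int]:
        return dict(Counter(d.gold_label for d in self.documents if d.gold_label is not None))

    @property
    def doc_ids(self) -> List[str]:
        return [d.doc_id for d in self.documents]


@dataclass
class OntologyNode:
    """An ontology concept: accession, canonical name, synonyms, keyword."""

    node_id: str
    name: str
    synonyms: List[str] = field(default_factory=list)
    keyword: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.node_id:
            raise CorpusFormatError("node_id must be non-empty")
        if not self.name:
            raise CorpusFormatError(f"node {self.node_id!r}: name must be non-empty")


@dataclass
class AnnotationSet:
    """Gold or predicted document-to-node assignments (set semantics)."""

    pairs: Dict[str, Set[str]] = field(default_factory=dict)

    def add(self, doc_id: str, node_id: str) -> None:
        self.pairs.setdefault(doc_id, set()).add(node_id)

    def nodes_for(self, doc_id: str) -> Set[str]:
        return self.pairs.get(doc_id, set())

    def as_pairs(self) -> Set[Tuple[str, str]]:
        return {(d, n) for d, nodes in self.pairs.items() for n in nodes}

    def __len__(self) -> int:
        return sum(len(v) for v in self.pairs.values())


# ---------------------------------------------------------------------------
# Triage (title+abstract) corpora
# ---------------------------------------------------------------------------

_ACT_HEADER = ["doc_id", "label", "title", "abstract"]


def read_act_corpus(path) -> LabeledCorpus:
    """Read a TSV corpus with header ``doc_id  label  title  abstract``.

    An empty label column yields an unlabeled record (test data).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CorpusFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != _ACT_HEADER:
        raise CorpusFormatError(f"{path}: expected header {_ACT_HEADER}, got {header}")
    docs: List[DocumentRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise CorpusFormatError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        doc_id, label, title, abstract = cols
        if label not in ("", "0", "1"):
            raise CorpusFormatError(f"{path}:{lineno}: label must be 0, 1 or empty, got {label!r}")
        try:
            docs.append(
                DocumentRecord(
                    doc_id=doc_id,
                    title=title,
                    body=abstract,
                    gold_label=int(label) if label else None,
                )
            )
        except CorpusFormatError as exc:
            raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    return LabeledCorpus(docs)


def _clean_field(text: str) -> str:
    return text.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def write_act_corpus(corpus: LabeledCorpus, path) -> None:
    lines = ["\t".join(_ACT_HEADER)]
    for d in corpus:
        label = "" if d.gold_label is None else str(d.gold_label)
        lines.append("\t".join([d.doc_id, label, _clean_field(d.title), _clean_field(d.body)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Full-text corpora (one plain-text file per document)
# ---------------------------------------------------------------------------

def read_fulltext_corpus(directory) -> LabeledCorpus:
    """Read every regular file in ``directory`` (non-recursive) as one
    document; the filename stem is the doc_id. Subdirectories are ignored."""
    directory = Path(directory)
    if not directory.is_dir():
        raise CorpusFormatError(f"{directory}: not a directory")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise CorpusFormatError(f"{directory}: no document files found")
    docs = []
    for p in files:
        try:
            body = p.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise CorpusFormatError(f"{p}: not valid UTF-8") from exc
        if not body.strip():
            raise CorpusFormatError(f"{p}: empty document")
        docs.append(DocumentRecord(doc_id=p.stem, body=body))
    return LabeledCorpus(docs)


def write_fulltext_corpus(corpus: LabeledCorpus, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for d in corpus:
        (directory / f"{d.doc_id}.txt").write_text(d.body, encoding="utf-8")


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

_SYNONYM_SCOPES = ("EXACT", "RELATED", "NARROW", "BROAD")


def _parse_synonym_line(value: str, term_id: str) -> Tuple[str, str]:
    # synonym: "text" SCOPE [xrefs]
    if not value.startswith('"'):
        raise CorpusFormatError(f"term {term_id}: malformed synonym line {value!r}")
    end = value.find('"', 1)
    while end != -1 and value[end - 1] == "\\":
        end = value.find('"', end + 1)
    if end == -1:
        raise CorpusFormatError(f"term {term_id}: unterminated synonym string {value!r}")
    text = value[1:end].replace('\\"', '"')
    rest = value[end + 1 :].strip()
    scope = rest.split()[0] if rest and rest.split()[0] in _SYNONYM_SCOPES else "RELATED"
    return text, scope


def parse_obo(
    path,
    allowed_ids: Optional[Iterable[str]] = None,
    synonym_scopes: Optional[Iterable[str]] = None,
) -> List[OntologyNode]:
    """Parse ``[Term]`` stanzas of an OBO 1.2 flat file.

    Obsolete terms are excluded. All synonym scopes are ingested unless
    ``synonym_scopes`` restricts them. With ``allowed_ids``, output is
    restricted to (and ordered by) that list; IDs absent from the file are
    reported via ``warnings.warn``.
    """
    path = Path(path)
    scopes = set(synonym_scopes) if synonym_scopes is not None else None
    nodes: Dict[str, OntologyNode] = {}
    in_term = False
    term_id: Optional[str] = None
    name: Optional[str] = None
    synonyms: List[str] = []
    obsolete = False

    def flush() -> None:
        nonlocal term_id, name, synonyms, obsolete
        if in_term and not obsolete:
            if term_id is None or name is None:
                raise CorpusFormatError(
                    f"{path}: [Term] stanza missing id or name (id={term_id!r}, name={name!r})"
                )
            nodes[term_id] = OntologyNode(node_id=term_id, name=name, synonyms=list(synonyms))
        term_id, name, synonyms, obsolete = None, None, [], False

    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("!")[0].strip() if not raw.lstrip().startswith("synonym:") else raw.strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term:
            continue
        if ":" not in line:
            raise CorpusFormatError(f"{path}: malformed line in term {term_id!r}: {raw!r}")
        tag, _, value = line.partition(":")
        value = value.strip()
        if tag == "id":
            term_id = value
        elif tag == "name":
            name = value
        elif tag == "synonym":
            text, scope = _parse_synonym_line(value, term_id or "?")
            if scopes is None or scope in scopes:
                synonyms.append(text)
        elif tag == "is_obsolete" and value.lower().startswith("true"):
            obsolete = True
    flush()

    if allowed_ids is None:
        return list(nodes.values())
    allowed = list(allowed_ids)
    missing = [i for i in allowed if i not in nodes]
    if missing:
        warnings.warn(f"{len(missing)} allowed IDs absent from {path}: {missing}", stacklevel=2)
    return [nodes[i] for i in allowed if i in nodes]


def write_obo(nodes: Sequence[OntologyNode], path) -> None:
    """Serialize nodes as a minimal OBO 1.2 file (round-trips via parse_obo)."""
    chunks = ["format-version: 1.2", ""]
    for n in nodes:
        chunks.append("[Term]")
        chunks.append(f"id: {n.node_id}")
        chunks.append(f"name: {n.name}")
        for s in n.synonyms:
            escaped = s.replace('"', '\\"')
            chunks.append(f'synonym: "{escaped}" EXACT []')
        chunks.append("")
    Path(path).write_text("\n".join(chunks), encoding="utf-8")


# ---------------------------------------------------------------------------
# Lexicon supplements (manually added synonyms / keywords)
# ---------------------------------------------------------------------------

def read_lexicon_supplement(path) -> Dict[str, Tuple[List[str], Optional[str]]]:
    """Read TSV rows ``node_id  kind  value`` with kind in {synonym, keyword}.

    Returns node_id -> (extra synonyms, keyword or None). A later keyword
    row overwrites an earlier one; duplicate synonyms are dropped.
    """
    path = Path(path)
    out: Dict[str, Tuple[List[str], Optional[str]]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise CorpusFormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        node_id, kind, value = cols
        syns, kw = out.get(node_id, ([], None))
        if kind == "synonym":
            if value not in syns:
                syns.append(value)
        elif kind == "keyword":
            if len(value.split()) != 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: keyword {value!r} must be a single token"
                )
            kw = value
        else:
            raise CorpusFormatError(f"{path}:{lineno}: unknown kind {kind!r}")
        out[node_id] = (syns, kw)
    return out


def apply_supplement(
    nodes: Sequence[OntologyNode],
    supplement: Dict[str, Tuple[List[str], Optional[str]]],
) -> List[OntologyNode]:
    """Merge a supplement into ontology nodes; idempotent."""
    out = []
    for n in nodes:
        syns, kw = supplement.get(n.node_id, ([], None))
        merged = list(n.synonyms)
        for s in syns:
            if s not in merged:
                merged.append(s)
        out.append(
            OntologyNode(
                node_id=n.node_id,
                name=n.name,
                synonyms=merged,
                keyword=kw if kw is not None else n.keyword,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path, allowed_node_ids: Optional[Iterable[str]] = None) -> AnnotationSet:
    """Read ``doc_id TAB node_id`` lines into an AnnotationSet."""
    path = Path(path)
    allowed = set(allowed_node_ids) if allowed_node_ids is not None else None
    ann = AnnotationSet()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise CorpusFormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        doc_id, node_id = cols
        if allowed is not None and node_id not in allowed:
            raise CorpusFormatError(f"{path}:{lineno}: node {node_id!r} not in allowed node list")
        ann.add(doc_id, node_id)
    return ann


def write_annotations(ann: AnnotationSet, path) -> None:
    lines = [f"{d}\t{n}" for d, n in sorted(ann.as_pairs())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(records: Sequence, path, task: str) -> None:
    """Write ranked predictions as TSV.

    act rows: (doc_id, label, confidence, rank); imt rows:
    (doc_id, node_id, confidence, evidence sentence). Tabs/newlines inside
    evidence sentences are replaced by spaces.
    """
    if task == "act":
        lines = ["doc_id\tlabel\tconfidence\trank"]
        prev_rank = 0
        for doc_id, label, conf, rank in records:
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0, 1] for {doc_id!r}")
            if rank <= prev_rank:
                raise ValueError(f"ranks must be strictly increasing, got {rank} after {prev_rank}")
            prev_rank = rank
            lines.append(f"{doc_id}\t{label}\t{conf:.6f}\t{rank}")
    elif task == "imt":
        lines = ["doc_id\tnode_id\tconfidence\tevidence"]
        for doc_id, node_id, conf, evidence in records:
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0, 1] for {doc_id!r}/{node_id!r}")
            lines.append(f"{doc_id}\t{node_id}\t{conf:.6f}\t{_clean_field(evidence)}")
    else:
        raise ValueError(f"unknown task {task!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Corpus summary statistics
# ---------------------------------------------------------------------------

def read_count_summary(path) -> List[Tuple[str, int, int]]:
    """Read TSV rows ``set_name  n_articles  n_annotations``."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise CorpusFormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        rows.append((cols[0], int(cols[1]), int(cols[2])))
    return rows


def annotations_per_article(n_annotations: int, n_articles: int) -> float:
    """Mean annotations per article, rounded to two decimals."""
    if n_articles <= 0:
        raise ValueError("n_articles must be positive")
    return round(n_annotations / n_articles, 2)
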