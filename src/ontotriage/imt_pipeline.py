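"""Article-node pair classification: instance generation, chi-square
feature selection (with supervised discretization of continuous features),
tree-based learners, and evidence-sentence extraction."""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .corpus_io import AnnotationSet, DocumentRecord, LabeledCorpus
from .evaluation import ConfusionCounts
from .feature_scoring import ContingencyTable2x2, chi_square
from .imt_features import (FEATURE_NAMES, DocumentView, NodeLexicon,
                           PairFeatureVector, TermStatistics,
                           extract_pair_features)
from .textnorm import (NORMALIZATION_VERSION, Sentence, normalize_and_tokenize,
                       split_sentences)

__all__ = [
    "ImtConfig", "PairInstance", "ImtPrediction", "TrainedPairClassifier",
    "generate_pair_instances", "select_pair_features", "train_imt",
    "predict_imt", "extract_evidence_sentence", "pair_confusion",
    "save_model", "load_model",
]

_ALGORITHMS = ("random_forest", "random_committee", "nb_tree", "j48")


@dataclass(frozen=True)
class ImtConfig:
    algorithm: str = "random_forest"
    n_features: int = 21
    negative_sampling: str = "all"   # "all" or "ratio"
    sampling_ratio: float = 2.0      # negatives per positive (ratio mode)
    seed: int = 0
    evidence_use_synonyms: bool = False
    evidence_per_occurrence: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {_ALGORITHMS}")
        if not 1 <= self.n_features <= len(FEATURE_NAMES):
            raise ValueError(f"n_features must be in [1, {len(FEATURE_NAMES)}]")
        if self.negative_sampling not in ("all", "ratio"):
            raise ValueError(f"negative_sampling must be 'all' or 'ratio'")


@dataclass(frozen=True)
class PairInstance:
    features: PairFeatureVector
    label: Optional[int] = None


@dataclass(frozen=True)
class ImtPrediction:
    doc_id: str
    node_id: str
    confidence: float
    evidence_sentence: str
    evidence_score: float


class _RandomCommittee:
    """Committee of randomized decision trees trained on the full data with
    different seeds; confidence is the averaged class probability."""

    def __init__(self, n_members: int = 10, seed: int = 0) -> None:
        self.n_members = n_members
        self.seed = seed
        self.members: List[DecisionTreeClassifier] = []
        self.classes_: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_RandomCommittee":
        self.members = []
        for i in range(self.n_members):
            tree = DecisionTreeClassifier(splitter="random", random_state=self.seed + i)
            tree.fit(x, y)
            self.members.append(tree)
        self.classes_ = self.members[0].classes_
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(x) for m in self.members], axis=0)


class _NaiveBayesTree:
    """A shallow decision tree with a Gaussian naive Bayes model at each
    leaf; leaves with a single class fall back to that class's frequency."""

    def __init__(self, max_depth: int = 3, seed: int = 0) -> None:
        self.max_depth = max_depth
        self.seed = seed
        self.tree: Optional[DecisionTreeClassifier] = None
        self.leaf_models: Dict[int, object] = {}
        self.classes_: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_NaiveBayesTree":
        self.tree = DecisionTreeClassifier(
            max_depth=self.max_depth, min_samples_leaf=5, random_state=self.seed
        )
        self.tree.fit(x, y)
        self.classes_ = self.tree.classes_
        self.leaf_models = {}
        leaves = self.tree.apply(x)
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            y_leaf = y[mask]
            if len(np.unique(y_leaf)) < 2:
                self.leaf_models[int(leaf)] = int(y_leaf[0])
            else:
                nb = GaussianNB()
                nb.fit(x[mask], y_leaf)
                self.leaf_models[int(leaf)] = nb
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        assert self.tree is not None and self.classes_ is not None
        leaves = self.tree.apply(x)
        out = np.zeros((len(x), len(self.classes_)))
        for i, leaf in enumerate(leaves):
            model = self.leaf_models[int(leaf)]
            if isinstance(model, int):
                out[i, list(self.classes_).index(model)] = 1.0
            else:
                probs = model.predict_proba(x[i : i + 1])[0]
                for cls, p in zip(model.classes_, probs):
                    out[i, list(self.classes_).index(cls)] = p
        return out


@dataclass
class TrainedPairClassifier:
    config: ImtConfig
    feature_names: List[str]           # selected subset, in rank order
    model: object
    normalization_version: str = NORMALIZATION_VERSION

    @property
    def feature_indices(self) -> List[int]:
        return [FEATURE_NAMES.index(n) for n in self.feature_names]


def generate_pair_instances(
    corpus: LabeledCorpus,
    annotations: AnnotationSet,
    lexicons: Sequence[NodeLexicon],
    stats: TermStatistics,
    popularity: Mapping[str, int],
    config: ImtConfig,
    regex_hits: Optional[Set[Tuple[str, str]]] = None,
) -> List[PairInstance]:
    """Positives are gold (doc, node) pairs; negatives are all remaining
    (doc x allowed node) pairs, optionally down-sampled per document to
    ``sampling_ratio`` negatives per positive (seeded)."""
    if not lexicons:
        raise ValueError("allowed node list must be non-empty")
    regex_hits = regex_hits or set()
    rng = np.random.default_rng(config.seed)
    instances: List[PairInstance] = []
    for doc in corpus:
        view = DocumentView(doc)
        gold = annotations.nodes_for(doc.doc_id)
        neg_ids = [l.node_id for l in lexicons if l.node_id not in gold]
        if config.negative_sampling == "ratio":
            n_keep = min(len(neg_ids), int(round(config.sampling_ratio * max(len(gold), 1))))
            idx = rng.choice(len(neg_ids), size=n_keep, replace=False)
            neg_ids = [neg_ids[i] for i in sorted(idx)]
        keep_neg = set(neg_ids)
        for lex in lexicons:
            if lex.node_id not in gold and lex.node_id not in keep_neg:
                continue
            fv = extract_pair_features(
                view, lex, stats, popularity,
                regex_hit=(doc.doc_id, lex.node_id) in regex_hits,
            )
            instances.append(PairInstance(fv, label=int(lex.node_id in gold)))
    return instances


def _best_split_chi2(values: np.ndarray, y: np.ndarray) -> float:
    """Chi-square of the best supervised binary split of a feature.

    Each candidate threshold (midpoint between consecutive distinct values)
    binarizes the feature; the maximum 2x2 chi-square over thresholds is
    returned. Constant features score 0.
    """
    distinct = np.unique(values)
    if len(distinct) < 2:
        return 0.0
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best = 0.0
    order = np.argsort(values, kind="stable")
    sv, sy = values[order], y[order]
    # cumulative positives below each threshold position
    cum_pos = np.cumsum(sy)
    for i in range(len(sv) - 1):
        if sv[i] == sv[i + 1]:
            continue
        # "high" side = values above the midpoint
        below = i + 1
        pos_below = int(cum_pos[i])
        a = n_pos - pos_below            # high & positive
        b = (len(sv) - below) - a        # high & negative
        c = pos_below
        d = n_neg - b
        best = max(best, chi_square(ContingencyTable2x2(a, b, c, d)))
    return best


def select_pair_features(instances: Sequence[PairInstance], n: int) -> List[str]:
    """Rank the 21 features by discretized chi-square against the pair label
    and return the top n (ties broken by feature name)."""
    if not 1 <= n <= len(FEATURE_NAMES):
        raise ValueError(f"n must be in [1, {len(FEATURE_NAMES)}]")
    labels = [inst.label for inst in instances]
    if any(l is None for l in labels):
        raise ValueError("all instances must be labeled")
    y = np.array(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    x = np.array([inst.features.values for inst in instances], dtype=float)
    scored = [
        (-_best_split_chi2(x[:, j], y), name)
        for j, name in enumerate(FEATURE_NAMES)
    ]
    scored.sort()
    return [name for _, name in scored[:n]]


def _make_model(config: ImtConfig):
    if config.algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=config.seed)
    if config.algorithm == "random_committee":
        return _RandomCommittee(n_members=10, seed=config.seed)
    if config.algorithm == "nb_tree":
        return _NaiveBayesTree(max_depth=3, seed=config.seed)
    return DecisionTreeClassifier(random_state=config.seed)  # j48


def train_imt(instances: Sequence[PairInstance], config: ImtConfig) -> TrainedPairClassifier:
    """Select features and fit the configured tree-based learner."""
    labels = [inst.label for inst in instances]
    if any(l is None for l in labels):
        raise ValueError("all training instances must be labeled")
    y = np.array(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training instances must contain both classes")
    selected = select_pair_features(instances, config.n_features)
    idx = [FEATURE_NAMES.index(n) for n in selected]
    x = np.array([inst.features.values for inst in instances], dtype=float)[:, idx]
    model = _make_model(config)
    model.fit(x, y)
    return TrainedPairClassifier(config=config, feature_names=selected, model=model)


def _positive_proba(model, x: np.ndarray) -> np.ndarray:
    probs = model.predict_proba(x)
    classes = list(model.classes_)
    return probs[:, classes.index(1)] if 1 in classes else np.zeros(len(x))


def extract_evidence_sentence(
    sentences: Sequence[Sentence],
    lex: NodeLexicon,
    stats: TermStatistics,
    use_synonyms: bool = False,
    per_occurrence: bool = False,
) -> Tuple[str, float]:
    """Pick the sentence best supporting a node assignment.

    Each sentence scores the sum of chi-square values of the node's concept
    unigrams it contains (distinct unigrams by default). Ties go to the
    longest sentence (characters), then the earliest offset. An empty
    sentence list yields ("", 0.0).
    """
    if not sentences:
        return "", 0.0
    unigrams = set(lex.concept_unigrams)
    if use_synonyms:
        unigrams |= set(lex.synonym_unigrams)
    best: Optional[Tuple[float, int, int]] = None  # (score, length, -index) maximized
    best_sentence = sentences[0]
    for i, sent in enumerate(sentences):
        tokens = normalize_and_tokenize(sent.text)
        if per_occurrence:
            score = sum(stats.chi2(t) for t in tokens if t in unigrams)
        else:
            score = sum(stats.chi2(u) for u in unigrams if u in set(tokens))
        key = (score, len(sent.text), -i)
        if best is None or key > best:
            best = key
            best_sentence = sent
    assert best is not None
    return best_sentence.text, best[0]


def predict_imt(
    clf: TrainedPairClassifier,
    doc: DocumentRecord,
    lexicons: Sequence[NodeLexicon],
    stats: TermStatistics,
    popularity: Mapping[str, int],
    regex_hits: Optional[Set[Tuple[str, str]]] = None,
) -> List[ImtPrediction]:
    """Confidence for every (doc, node) pair; pairs with confidence >= 0.5
    are emitted with an evidence sentence, sorted by confidence descending
    then node_id. A document may legitimately yield no predictions."""
    if clf.normalization_version != NORMALIZATION_VERSION:
        raise ValueError("model normalization version mismatch")
    regex_hits = regex_hits or set()
    view = DocumentView(doc)
    fvs = [
        extract_pair_features(view, lex, stats, popularity,
                              regex_hit=(doc.doc_id, lex.node_id) in regex_hits)
        for lex in lexicons
    ]
    x = np.array([fv.values for fv in fvs], dtype=float)[:, clf.feature_indices]
    confs = _positive_proba(clf.model, x)
    sentences = split_sentences(doc.text)
    out: List[ImtPrediction] = []
    for lex, conf in zip(lexicons, confs):
        if conf >= 0.5:
            evidence, score = extract_evidence_sentence(
                sentences, lex, stats,
                use_synonyms=clf.config.evidence_use_synonyms,
                per_occurrence=clf.config.evidence_per_occurrence,
            )
            out.append(ImtPrediction(doc.doc_id, lex.node_id, float(conf), evidence, score))
    out.sort(key=lambda p: (-p.confidence, p.node_id))
    return out


def pair_confusion(
    gold: AnnotationSet,
    predicted: AnnotationSet,
    doc_ids: Sequence[str],
    node_ids: Sequence[str],
) -> ConfusionCounts:
    """Micro-averaged confusion over the full (doc x node) pair universe."""
    universe = {(d, n) for d in doc_ids for n in node_ids}
    gold_pairs = gold.as_pairs()
    pred_pairs = predicted.as_pairs()
    from .evaluation import confusion

    return confusion(gold_pairs, pred_pairs, universe)


def save_model(clf: TrainedPairClassifier, path) -> None:
    Path(path).write_bytes(pickle.dumps(clf))


def load_model(path) -> TrainedPairClassifier:
    clf = pickle.loads(Path(path).read_bytes())
    if clf.normalization_version != NORMALIZATION_VERSION:
        raise ValueError("model normalization version mismatch")
    return clf
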