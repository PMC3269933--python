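"""The document-triage classifier: binary n-gram vectors over a selected
vocabulary, trained with multinomial naive Bayes or a polynomial-kernel SVM.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.naive_bayes import BernoulliNB, MultinomialNB
from sklearn.svm import SVC

from .corpus_io import DocumentRecord, LabeledCorpus
from .feature_scoring import score_vocabulary, select_top_k
from .textnorm import NORMALIZATION_VERSION, ngram_set

__all__ = ["ActConfig", "ActPrediction", "TrainedTextClassifier",
           "vectorize", "train_act", "predict_act", "save_model", "load_model"]


@dataclass(frozen=True)
class ActConfig:
    """Training configuration for the triage classifier."""

    algorithm: str = "nbm"            # nbm | svm_poly
    selection_method: str = "mi"      # mi | chi2
    k: int = 400
    orders: FrozenSet[int] = frozenset({1, 2})
    training_split: str = "train_plus_dev"  # train_plus_dev | dev_only
    seed: int = 0
    svm_degree: int = 1
    svm_cost: float = 1.0
    calibrate_svm: bool = True        # logistic mapping of decision values
    binary_features: bool = True      # presence/absence (default) vs counts

    def __post_init__(self) -> None:
        if self.algorithm not in ("nbm", "svm_poly"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.selection_method not in ("mi", "chi2"):
            raise ValueError(f"unknown selection method {self.selection_method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not set(self.orders) or not set(self.orders) <= {1, 2}:
            raise ValueError("orders must be a non-empty subset of {1, 2}")


@dataclass(frozen=True)
class ActPrediction:
    doc_id: str
    label: int
    confidence: float


@dataclass
class TrainedTextClassifier:
    config: ActConfig
    vocabulary: List[str]
    model: object
    normalization_version: str = NORMALIZATION_VERSION


def vectorize(doc: DocumentRecord, vocabulary: Sequence[str],
              orders=(1, 2)) -> np.ndarray:
    """Binary indicator vector: component i is 1 iff vocabulary term i
    occurs in the document's normalized n-gram set."""
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    grams = ngram_set(doc.text, orders)
    return np.fromiter((1.0 if t in grams else 0.0 for t in vocabulary),
                       dtype=np.float64, count=len(vocabulary))


def _count_vector(doc: DocumentRecord, vocabulary, orders) -> np.ndarray:
    from collections import Counter

    from .textnorm import extract_ngrams, normalize_and_tokenize

    counts = Counter(extract_ngrams(normalize_and_tokenize(doc.text), orders))
    return np.fromiter((float(counts[t]) for t in vocabulary),
                       dtype=np.float64, count=len(vocabulary))


def _design_matrix(corpus: LabeledCorpus, vocabulary, orders,
                   binary: bool = True) -> np.ndarray:
    rows = [
        vectorize(d, vocabulary, orders) if binary else _count_vector(d, vocabulary, orders)
        for d in corpus
    ]
    return np.vstack(rows)


def train_act(corpus: LabeledCorpus, config: ActConfig) -> TrainedTextClassifier:
    """Select the vocabulary on the training corpus and fit the classifier.

    Feature selection uses training documents only. NBM applies add-one
    smoothing on the binary indicators; the SVM uses a polynomial kernel
    (degree/cost from the config, defaults 1/1).
    """
    labels = {d.doc_id: d.gold_label for d in corpus}
    if any(v is None for v in labels.values()):
        raise ValueError("all training documents must be labeled")
    if len(set(labels.values())) < 2:
        raise ValueError("training corpus must contain both classes")

    vocab_scores = score_vocabulary(corpus, labels, config.orders)
    k = config.k
    if k > len(vocab_scores):
        import warnings

        warnings.warn(
            f"k={k} exceeds vocabulary size {len(vocab_scores)}; clamping",
            stacklevel=2,
        )
        k = len(vocab_scores)
    vocabulary = select_top_k(vocab_scores, k, config.selection_method)

    x = _design_matrix(corpus, vocabulary, config.orders, config.binary_features)
    y = np.array([labels[d.doc_id] for d in corpus], dtype=int)
    if config.algorithm == "nbm":
        # add-one smoothing on binary indicators (presence AND absence are
        # modeled); frequency mode switches to a multinomial event model
        model = BernoulliNB(alpha=1.0) if config.binary_features else MultinomialNB(alpha=1.0)
    else:
        model = SVC(
            kernel="poly", degree=config.svm_degree, C=config.svm_cost,
            gamma=1.0, coef0=0.0, random_state=config.seed,
        )
    model.fit(x, y)
    return TrainedTextClassifier(config=config, vocabulary=vocabulary, model=model)


def _confidences(clf: TrainedTextClassifier, x: np.ndarray) -> np.ndarray:
    cfg = clf.config
    if cfg.algorithm == "nbm":
        return clf.model.predict_proba(x)[:, list(clf.model.classes_).index(1)]
    decision = clf.model.decision_function(x)
    if clf.model.classes_[1] != 1:
        decision = -decision
    if cfg.calibrate_svm:
        return 1.0 / (1.0 + np.exp(-decision))
    return (decision > 0).astype(float)


def predict_act(clf: TrainedTextClassifier, docs: LabeledCorpus) -> List[ActPrediction]:
    """One prediction per document, sorted by confidence descending then
    doc_id ascending; label = confidence >= 0.5."""
    if len(docs) == 0:
        return []
    x = _design_matrix(docs, clf.vocabulary, clf.config.orders,
                       clf.config.binary_features)
    confs = _confidences(clf, x)
    preds = [
        ActPrediction(doc_id=d.doc_id, label=int(c >= 0.5), confidence=float(c))
        for d, c in zip(docs, confs)
    ]
    preds.sort(key=lambda p: (-p.confidence, p.doc_id))
    return preds


def save_model(clf: TrainedTextClassifier, path) -> None:
    Path(path).write_bytes(pickle.dumps(clf))


def load_model(path) -> TrainedTextClassifier:
    clf = pickle.loads(Path(path).read_bytes())
    if clf.normalization_version != NORMALIZATION_VERSION:
        raise ValueError(
            f"model normalization version {clf.normalization_version!r} does not "
            f"match runtime version {NORMALIZATION_VERSION!r}"
        )
    return clf
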