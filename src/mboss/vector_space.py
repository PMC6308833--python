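"""Vector-space classification of word histograms (BOSS VS adapted to MBOSS).

Each class is summarized by one sparse tf-idf vector over the training
vocabulary: tf(p, C) = 1 + ln(sum of counts of word p over the class's
histograms) and idf(p) = ln(|CLASSES| / number of classes containing p).
An unlabeled histogram is represented by its own tf vector
(tf(p, Q) = 1 + ln count, no idf on the query side) and assigned the label of
the class maximizing cosine similarity, where the query norm runs over the
query's words only and the model norm over the class's full vector — exactly
the asymmetric form the method defines.  Natural logarithms throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .boss import WordHistogram
from .sfa import MCBTable, SFAParams


def term_frequency(hist: WordHistogram, word: str) -> float:
    """tf of a word in one histogram: 1 + ln(count) if present, else 0."""
    count = hist.counts.get(word, 0)
    return 1.0 + math.log(count) if count > 0 else 0.0


def query_tf_vector(hist: WordHistogram) -> dict[str, float]:
    """Sparse tf vector of a query histogram."""
    return {w: 1.0 + math.log(c) for w, c in hist.counts.items() if c > 0}


def class_term_frequency(
    class_hists: Sequence[WordHistogram], word: str
) -> float:
    """Class-level tf: 1 + ln of the summed counts over the class's training
    histograms; 0 when the word is absent from the class."""
    total = sum(h.counts.get(word, 0) for h in class_hists)
    return 1.0 + math.log(total) if total > 0 else 0.0


def inverse_document_frequency(
    word: str, class_hists_by_class: Mapping[str, Sequence[WordHistogram]]
) -> float:
    """idf: ln(number of classes / number of classes containing the word)."""
    n_classes = len(class_hists_by_class)
    containing = sum(
        1
        for hists in class_hists_by_class.values()
        if any(h.counts.get(word, 0) > 0 for h in hists)
    )
    if containing == 0:
        raise ValueError(f"word {word!r} occurs in no class")
    return math.log(n_classes / containing)


@dataclass(frozen=True)
class ClassModel:
    """One class's sparse tf-idf weight vector and its Euclidean norm."""

    class_label: str
    tfidf: dict[str, float]
    norm: float

    @classmethod
    def from_weights(cls, label: str, weights: dict[str, float]) -> "ClassModel":
        weights = {w: v for w, v in weights.items() if v > 0.0}
        norm = math.sqrt(sum(v * v for v in weights.values()))
        return cls(class_label=label, tfidf=weights, norm=norm)


@dataclass(frozen=True)
class Prediction:
    label: str
    scores: dict[str, float]
    degenerate: bool = False  # all-zero similarity; label is the tie-rule default


@dataclass
class FittedClassifier:
    """Per-class tf-idf models plus the fitted transform (params and MCBs)."""

    class_models: list[ClassModel]
    params: SFAParams
    mcbs: list[MCBTable]
    class_order: list[str]

    def __post_init__(self) -> None:
        if len(self.class_order) < 2:
            raise ValueError("need at least 2 classes")
        by_label = {m.class_label for m in self.class_models}
        if by_label != set(self.class_order):
            raise ValueError("class_models and class_order disagree")

    def model_for(self, label: str) -> ClassModel:
        for m in self.class_models:
            if m.class_label == label:
                return m
        raise KeyError(label)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "params": {
                "window_size": self.params.window_size,
                "word_length": self.params.word_length,
                "alphabet_size": self.params.alphabet_size,
                "drop_first_coeff": self.params.drop_first_coeff,
                "normalize_windows": self.params.normalize_windows,
                "normalize_series": self.params.normalize_series,
            },
            "mcbs": [json.loads(m.to_json()) for m in self.mcbs],
            "class_order": self.class_order,
            "class_models": {
                m.class_label: m.tfidf for m in self.class_models
            },
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedClassifier":
        obj = json.loads(text)
        params = SFAParams(**obj["params"])
        mcbs = [MCBTable.from_json(json.dumps(m)) for m in obj["mcbs"]]
        models = [
            ClassModel.from_weights(label, {w: float(v) for w, v in wt.items()})
            for label, wt in obj["class_models"].items()
        ]
        return cls(
            class_models=models,
            params=params,
            mcbs=mcbs,
            class_order=list(obj["class_order"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FittedClassifier":
        return cls.from_json(Path(path).read_text())


def build_class_models(
    hists: Sequence[WordHistogram],
    labels: Sequence[str],
    params: SFAParams | None = None,
    mcbs: Sequence[MCBTable] | None = None,
) -> FittedClassifier:
    """Build per-class tf-idf vectors from labeled training histograms.

    The weight of word p in class C is class_term_frequency(p, C) times
    inverse_document_frequency(p); the vocabulary is the union over training
    histograms.  Class order is lexicographic, which fixes tie-breaking and
    makes confusion matrices reproducible.
    """
    if len(hists) != len(labels):
        raise ValueError("one label per histogram required")
    by_class: dict[str, list[WordHistogram]] = {}
    for h, y in zip(hists, labels):
        by_class.setdefault(y, []).append(h)
    if len(by_class) < 2:
        raise ValueError("need at least 2 classes")
    for label, class_hists in by_class.items():
        if not class_hists:
            raise ValueError(f"class {label!r} has no histograms")
    class_order = sorted(by_class)
    n_classes = len(class_order)

    # Summed counts and document frequency per word, in one pass.
    class_sums: dict[str, dict[str, int]] = {y: {} for y in class_order}
    for y, class_hists in by_class.items():
        sums = class_sums[y]
        for h in class_hists:
            for w, c in h.counts.items():
                sums[w] = sums.get(w, 0) + c
    df: dict[str, int] = {}
    for sums in class_sums.values():
        for w in sums:
            df[w] = df.get(w, 0) + 1

    models = []
    for y in class_order:
        weights = {
            w: (1.0 + math.log(total)) * math.log(n_classes / df[w])
            for w, total in class_sums[y].items()
        }
        models.append(ClassModel.from_weights(y, weights))
    return FittedClassifier(
        class_models=models,
        params=params if params is not None else _DEFAULT_PARAMS,
        mcbs=list(mcbs) if mcbs is not None else [],
        class_order=class_order,
    )


_DEFAULT_PARAMS = SFAParams(window_size=32)


def cosine_similarity(query_tf: Mapping[str, float], model: ClassModel) -> float:
    """Asymmetric cosine: dot over the query's words / (query norm x model norm).

    The query norm is computed over the query's own tf components only.  A
    zero query vector has similarity 0 by definition; a zero model norm is a
    contract violation.
    """
    if not model.norm > 0:
        raise ValueError("model norm must be positive")
    qnorm = math.sqrt(sum(v * v for v in query_tf.values()))
    if qnorm == 0.0:
        return 0.0
    dot = sum(v * model.tfidf.get(w, 0.0) for w, v in query_tf.items())
    return dot / (qnorm * model.norm)


def predict(hist: WordHistogram, clf: FittedClassifier) -> Prediction:
    """Label of the class maximizing cosine similarity to the query tf vector.

    Ties are broken by class order (first wins).  An empty histogram (or one
    sharing no vocabulary with any class) yields the first class with an
    all-zero score vector, flagged as degenerate.
    """
    q = query_tf_vector(hist)
    scores: dict[str, float] = {}
    for label in clf.class_order:
        model = clf.model_for(label)
        if model.norm > 0:
            scores[label] = cosine_similarity(q, model)
        else:
            scores[label] = 0.0
    best = clf.class_order[0]
    best_score = scores[best]
    for label in clf.class_order[1:]:
        if scores[label] > best_score:
            best, best_score = label, scores[label]
    return Prediction(label=best, scores=scores, degenerate=best_score == 0.0)


def predict_instance(instance, clf: FittedClassifier) -> Prediction:
    """Transform an instance with the classifier's fitted params/MCBs, then
    classify its fused histogram."""
    from .boss import mboss_transform

    if not clf.mcbs:
        raise ValueError("classifier carries no fitted MCB tables")
    hist = mboss_transform(instance, clf.params, clf.mcbs)
    return predict(hist, clf)
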