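"""Grid-search fitting of (w, l) with cross-validation, and the two
evaluation protocols (personalized 10-fold, generalized leave-one-subject-out).

The fit procedure follows the method's training algorithm: window sizes are
taken from an arithmetic progression of roughly sqrt(n) candidates between 10
and the instance length; for each candidate w the instances are transformed
once at the maximum word length, each smaller word length in the grid is
derived by word truncation, and a stratified k-fold cross-validation score
selects the best (w, l).  The final models are refit on the entire training
set at the chosen parameters.

Inside the grid search, histograms are held as integer word codes in sparse
count matrices so the per-fold tf-idf/cosine arithmetic is vectorized; the
result is identical to the dictionary-level route in
:mod:`mboss.vector_space` (asserted by the test suite), which is used for the
final refit and for prediction.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .boss import fit_axis_mcbs, mboss_transform
from .segmentation import FLAT_STD_EPS, Instance
from .sfa import SFAParams, fit_mcb, symbol_indices
from .vector_space import FittedClassifier, build_class_models, predict_instance

logger = logging.getLogger("mboss")


@dataclass(frozen=True)
class FitConfig:
    """Grid-search configuration.

    Defaults follow the method's standard settings: alphabet size 4, maximum
    word length 16, word-length grid {4, 6, ..., 16}, 10-fold
    cross-validation.  Ties in the CV score are broken toward the smaller
    word length, then the smaller window (cheaper models).
    """

    alphabet_size: int = 4
    max_word_length: int = 16
    word_length_grid: tuple[int, ...] = (4, 6, 8, 10, 12, 14, 16)
    folds: int = 10
    seed: int = 0
    tie_rule: str = "smaller-l-then-smaller-w"
    drop_first_coeff: bool = True
    normalize_windows: bool = True
    normalize_series: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for l in self.word_length_grid:
            if l % 2 != 0 or l > self.max_word_length:
                raise ValueError("grid word lengths must be even and <= max")

    def params(self, window_size: int, word_length: int | None = None) -> SFAParams:
        return SFAParams(
            window_size=window_size,
            word_length=word_length or self.max_word_length,
            alphabet_size=self.alphabet_size,
            drop_first_coeff=self.drop_first_coeff,
            normalize_windows=self.normalize_windows,
            normalize_series=self.normalize_series,
        )


def window_grid(n: int, min_w: int | None = None) -> list[int]:
    """Candidate window sizes: an arithmetic progression from 10 up to n with
    step ~ sqrt(n - 10), giving about sqrt(n) candidates.

    ``min_w`` filters out windows too small for the configured maximum word
    length.
    """
    if n < 10:
        warnings.warn(f"instance length {n} < 10; single window candidate")
        return [min(n, min_w)] if min_w is not None else [n]
    step = max(1, round(math.sqrt(n - 10)))
    grid = list(range(10, n + 1, step))
    if min_w is not None:
        grid = [w for w in grid if w >= min_w]
        if not grid:
            if min_w <= n:
                grid = [min_w]
            else:
                raise ValueError(
                    f"instances of length {n} cannot host a window of {min_w}"
                )
    return grid


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------


def assign_folds(
    labels: Sequence[str], folds: int, seed: int
) -> tuple[np.ndarray, int]:
    """Stratified, seeded fold ids; -1 marks always-in-training instances.

    If some class has fewer instances than requested folds, the fold count is
    reduced to the smallest class size (never below 2); classes with a single
    instance are pinned to the training side of every fold.
    """
    labels = np.asarray(labels, dtype=object)
    counts = Counter(labels.tolist())
    singles = {y for y, c in counts.items() if c == 1}
    if singles:
        warnings.warn(
            f"classes with a single instance are never held out: {sorted(singles)}"
        )
    eligible = np.array([y not in singles for y in labels])
    multi_counts = [c for y, c in counts.items() if y not in singles]
    if not multi_counts:
        raise ValueError("every class has a single instance; cannot cross-validate")
    folds_eff = min(folds, min(multi_counts))
    if folds_eff < folds:
        logger.info("folds reduced from %d to %d", folds, folds_eff)
    folds_eff = max(2, folds_eff)
    fold_ids = np.full(len(labels), -1, dtype=int)
    idx = np.nonzero(eligible)[0]
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(idx)), labels[idx])):
        fold_ids[idx[test]] = f
    return fold_ids, folds_eff


# ---------------------------------------------------------------------------
# vectorized transform + CV fast path
# ---------------------------------------------------------------------------


def _stacked_segments(instances: Sequence[Instance]) -> np.ndarray:
    """Stack equal-length instances into an (N, n, v) array."""
    if not instances:
        raise ValueError("empty training set")
    shapes = {inst.segment.shape for inst in instances}
    if len(shapes) != 1:
        raise ValueError("all instances must share the same length and axis count")
    return np.stack([inst.segment for inst in instances])


def _axis_symbols(data: np.ndarray, params: SFAParams):
    """Symbols of every sliding window of every instance for one axis.

    ``data`` is (N, n); returns ((N, n_win, l) uint8 symbol indices, MCBTable)
    with the MCB fitted on all windows of all instances.
    """
    w = params.window_size
    if params.normalize_series:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        data = np.where(sd < FLAT_STD_EPS, 0.0, (data - mu) / np.maximum(sd, FLAT_STD_EPS))
    wins = np.lib.stride_tricks.sliding_window_view(data, w, axis=1)
    n_inst, n_win, _ = wins.shape
    flat = wins.reshape(-1, w).astype(float)
    if params.normalize_windows:
        mu = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, keepdims=True)
        flat = np.where(sd < FLAT_STD_EPS, 0.0, (flat - mu) / np.maximum(sd, FLAT_STD_EPS))
    elif params.drop_first_coeff:
        flat = flat - flat.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(flat, axis=1) / w
    start = 1 if params.drop_first_coeff else 0
    sel = spectrum[:, start : start + params.n_coeffs]
    coeffs = np.empty((flat.shape[0], params.word_length), dtype=float)
    coeffs[:, 0::2] = sel.real
    coeffs[:, 1::2] = sel.imag
    mcb = fit_mcb(coeffs, params.alphabet_size)
    syms = symbol_indices(coeffs, mcb)
    return syms.reshape(n_inst, n_win, params.word_length), mcb


def _count_matrix(
    symbols_by_axis: Sequence[np.ndarray], l: int, c: int
) -> sp.csr_matrix:
    """Numerosity-reduced fused histograms as a sparse (N, vocab) count matrix.

    Word codes are base-c integers of the first l symbols, offset by an
    axis-specific block so fused vocabularies stay disjoint — the integer
    analogue of the axis-character prefix.
    """
    n_inst = symbols_by_axis[0].shape[0]
    weights = (c ** np.arange(l - 1, -1, -1)).astype(np.int64)
    block = np.int64(c) ** np.int64(l)
    inst_parts, code_parts = [], []
    for axis_idx, syms in enumerate(symbols_by_axis, start=1):
        codes = syms[:, :, :l].astype(np.int64) @ weights  # (N, n_win)
        codes += np.int64(axis_idx) * block
        keep = np.ones(codes.shape, dtype=bool)
        keep[:, 1:] = codes[:, 1:] != codes[:, :-1]  # numerosity reduction
        rows, _ = np.nonzero(keep)
        inst_parts.append(rows)
        code_parts.append(codes[keep])
    inst = np.concatenate(inst_parts)
    code = np.concatenate(code_parts)
    vocab, inv = np.unique(code, return_counts=False, return_inverse=True)
    v_size = len(vocab)
    key = inst.astype(np.int64) * v_size + inv
    uniq, counts = np.unique(key, return_counts=True)
    return sp.csr_matrix(
        (counts.astype(float), (uniq // v_size, uniq % v_size)),
        shape=(n_inst, v_size),
    )


def _cv_score(
    X: sp.csr_matrix, y: np.ndarray, fold_ids: np.ndarray, n_classes: int
) -> int:
    """Total correct held-out predictions over all folds.

    Per fold, class tf-idf vectors are built from the training rows
    (tf = 1 + ln of the class-summed counts, idf = ln(K / document frequency))
    and each test row's tf vector is scored by the asymmetric cosine; the
    argmax over the class order wins, ties going to the earlier class.
    """
    Q = X.copy()
    Q.data = 1.0 + np.log(Q.data)
    qnorm = np.sqrt(np.asarray(Q.multiply(Q).sum(axis=1)).ravel())
    correct = 0
    for f in range(fold_ids.max() + 1):
        train = fold_ids != f
        test = fold_ids == f
        if not test.any():
            continue
        S = np.zeros((n_classes, X.shape[1]))
        for k in range(n_classes):
            rows = train & (y == k)
            if rows.any():
                S[k] = np.asarray(X[rows].sum(axis=0)).ravel()
        tf = np.where(S > 0, 1.0 + np.log(np.maximum(S, 1.0)), 0.0)
        df = (S > 0).sum(axis=0)
        idf = np.where(df > 0, np.log(n_classes / np.maximum(df, 1)), 0.0)
        W = tf * idf[None, :]
        wnorm = np.sqrt((W * W).sum(axis=1))
        scores = Q[test] @ W.T  # (n_test, K)
        denom = qnorm[test][:, None] * wnorm[None, :]
        with np.errstate(invalid="ignore"):
            scores = np.where(denom > 0, scores / np.maximum(denom, 1e-300), 0.0)
        pred = np.argmax(scores, axis=1)
        correct += int((pred == y[test]).sum())
    return correct


def _labels_as_indices(
    instances: Sequence[Instance],
) -> tuple[np.ndarray, list[str]]:
    class_order = sorted({inst.label for inst in instances})
    index = {y: k for k, y in enumerate(class_order)}
    y = np.array([index[inst.label] for inst in instances], dtype=int)
    return y, class_order


def cross_validate(
    train_set: Sequence[Instance], w: int, l: int, config: FitConfig
) -> int:
    """Stratified k-fold CV score (total correct predictions) at fixed (w, l).

    The MCB is fitted once on the full training set (as the training algorithm
    prescribes: the transform precedes the fold loop); tf-idf models are built
    on the training folds only.
    """
    data = _stacked_segments(train_set)
    y, class_order = _labels_as_indices(train_set)
    params = config.params(w, l)
    symbols = [
        _axis_symbols(data[:, :, i], params)[0] for i in range(data.shape[2])
    ]
    X = _count_matrix(symbols, l, config.alphabet_size)
    fold_ids, _ = assign_folds([inst.label for inst in train_set], config.folds, config.seed)
    return _cv_score(X, y, fold_ids, len(class_order))


@dataclass
class FitResult:
    classifier: FittedClassifier
    window_size: int
    word_length: int
    score: int
    grid_scores: dict[tuple[int, int], int] = field(default_factory=dict)


def fit(train_set: Sequence[Instance], config: FitConfig | None = None) -> FitResult:
    """Grid-search (w, l) by cross-validation, then refit on everything.

    For each candidate window size the instances are transformed once at the
    maximum word length; smaller word lengths reuse those symbols by
    truncation.  The (w, l) with the highest summed CV score wins, ties going
    to the smaller l and then the smaller w.  The returned classifier is
    refit on the entire training set at the chosen parameters.
    """
    config = config or FitConfig()
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty training set")
    y, class_order = _labels_as_indices(train_set)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    data = _stacked_segments(train_set)
    n = data.shape[1]
    v = data.shape[2]
    min_w = 2 * (config.max_word_length // 2 + int(config.drop_first_coeff))
    grid_w = window_grid(n, min_w=min_w)
    fold_ids, _ = assign_folds(
        [inst.label for inst in train_set], config.folds, config.seed
    )

    best_key: tuple[int, int, int] | None = None  # (score, -l, -w)
    best_wl: tuple[int, int] | None = None
    grid_scores: dict[tuple[int, int], int] = {}
    for w in grid_w:
        params_max = config.params(w)
        symbols = [_axis_symbols(data[:, :, i], params_max)[0] for i in range(v)]
        for l in sorted(config.word_length_grid):
            X = _count_matrix(symbols, l, config.alphabet_size)
            score = _cv_score(X, y, fold_ids, len(class_order))
            grid_scores[(w, l)] = score
            key = (score, -l, -w)
            if best_key is None or key > best_key:
                best_key, best_wl = key, (w, l)
            logger.debug("w=%d l=%d score=%d", w, l, score)
    assert best_wl is not None
    w_best, l_best = best_wl
    logger.info(
        "selected w=%d l=%d (score %d/%d)", w_best, l_best, best_key[0], len(train_set)
    )

    params = config.params(w_best, l_best)
    mcbs = fit_axis_mcbs(train_set, params)
    hists = [mboss_transform(inst, params, mcbs) for inst in train_set]
    clf = build_class_models(
        hists, [inst.label for inst in train_set], params=params, mcbs=mcbs
    )
    return FitResult(
        classifier=clf,
        window_size=w_best,
        word_length=l_best,
        score=best_key[0],
        grid_scores=grid_scores,
    )


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], class_order: Sequence[str]
) -> np.ndarray:
    """Entry (i, j) counts instances of true class i predicted as class j."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    known = set(class_order)
    for lab in list(truth) + list(predicted):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class_order")
    return _sk_confusion(truth, predicted, labels=list(class_order))


@dataclass
class EvaluationReport:
    """Accuracies, confusion matrix and chosen parameters for one protocol."""

    strategy: str
    class_order: list[str]
    per_unit_accuracy: dict[str, float]
    overall_accuracy: float
    mean_accuracy: float
    median_accuracy: float
    confusion: np.ndarray
    chosen_params: dict[str, list[int]]
    n_instances: int

    def to_jsonable(self) -> dict:
        return {
            "strategy": self.strategy,
            "class_order": self.class_order,
            "per_unit_accuracy": self.per_unit_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "median_accuracy": self.median_accuracy,
            "confusion": self.confusion.tolist(),
            "chosen_params": self.chosen_params,
            "n_instances": self.n_instances,
        }

    def to_text(self) -> str:
        lines = [
            f"strategy: {self.strategy}",
            f"instances: {self.n_instances}",
            f"overall accuracy: {self.overall_accuracy:.4f}",
            f"mean accuracy:    {self.mean_accuracy:.4f}",
            f"median accuracy:  {self.median_accuracy:.4f}",
            "",
            "confusion matrix (rows = truth, cols = predicted):",
            "," + ",".join(self.class_order),
        ]
        for label, row in zip(self.class_order, self.confusion):
            lines.append(label + "," + ",".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"

    def confusion_to_csv(self, path) -> None:
        from pathlib import Path

        lines = ["," + ",".join(self.class_order)]
        for label, row in zip(self.class_order, self.confusion):
            lines.append(label + "," + ",".join(str(int(x)) for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _report(
    strategy: str,
    class_order: list[str],
    truth: list[str],
    predicted: list[str],
    per_unit: dict[str, float],
    chosen: dict[str, list[int]],
) -> EvaluationReport:
    conf = confusion_matrix(truth, predicted, class_order)
    total = conf.sum()
    overall = float(np.trace(conf) / total) if total else 0.0
    accs = list(per_unit.values())
    return EvaluationReport(
        strategy=strategy,
        class_order=class_order,
        per_unit_accuracy=per_unit,
        overall_accuracy=overall,
        mean_accuracy=float(np.mean(accs)) if accs else 0.0,
        median_accuracy=float(np.median(accs)) if accs else 0.0,
        confusion=conf,
        chosen_params=chosen,
        n_instances=int(total),
    )


def evaluate_generalized(dataset, config: FitConfig | None = None) -> EvaluationReport:
    """Leave-one-subject-out evaluation (generalized / user-independent model).

    One fold per subject: the classifier (including parameter selection) is
    fit on all other subjects and scored on the held-out subject.
    """
    config = config or FitConfig()
    instances = list(dataset.instances)
    subjects = sorted({inst.subject for inst in instances})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    class_order = sorted({inst.label for inst in instances})
    truth: list[str] = []
    predicted: list[str] = []
    per_subject: dict[str, float] = {}
    chosen: dict[str, list[int]] = {}
    for subject in subjects:
        train = [i for i in instances if i.subject != subject]
        test = [i for i in instances if i.subject == subject]
        result = fit(train, config)
        chosen[subject] = [result.window_size, result.word_length, result.score]
        correct = 0
        for inst in test:
            pred = predict_instance(inst, result.classifier)
            truth.append(inst.label)
            predicted.append(pred.label)
            correct += int(pred.label == inst.label)
        per_subject[subject] = correct / len(test)
        logger.info("LOSO subject %s: accuracy %.4f", subject, per_subject[subject])
    return _report("loso", class_order, truth, predicted, per_subject, chosen)


def evaluate_personalized(dataset, config: FitConfig | None = None) -> EvaluationReport:
    """Per-subject stratified k-fold evaluation (personalized model).

    For each subject, each test fold is predicted by a classifier fit —
    including parameter selection — on the subject's other folds.  Subjects
    with a single class are skipped with a warning.
    """
    config = config or FitConfig()
    instances = list(dataset.instances)
    class_order = sorted({inst.label for inst in instances})
    subjects = sorted({inst.subject for inst in instances})
    truth: list[str] = []
    predicted: list[str] = []
    per_subject: dict[str, float] = {}
    chosen: dict[str, list[int]] = {}
    for subject in subjects:
        mine = [i for i in instances if i.subject == subject]
        if len({i.label for i in mine}) < 2:
            warnings.warn(f"subject {subject} has a single class; skipped")
            continue
        fold_ids, folds_eff = assign_folds(
            [i.label for i in mine], config.folds, config.seed
        )
        correct = tested = 0
        for f in range(folds_eff):
            train = [i for i, fid in zip(mine, fold_ids) if fid != f]
            test = [i for i, fid in zip(mine, fold_ids) if fid == f]
            if not test:
                continue
            result = fit(train, config)
            chosen[f"{subject}/fold{f}"] = [
                result.window_size,
                result.word_length,
                result.score,
            ]
            for inst in test:
                pred = predict_instance(inst, result.classifier)
                truth.append(inst.label)
                predicted.append(pred.label)
                correct += int(pred.label == inst.label)
                tested += 1
        per_subject[subject] = correct / tested if tested else 0.0
        logger.info(
            "personalized subject %s: accuracy %.4f", subject, per_subject[subject]
        )
    if not per_subject:
        raise ValueError("no subject had at least 2 classes")
    return _report(
        "personalized", class_order, truth, predicted, per_subject, chosen
    )
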