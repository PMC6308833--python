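import dataclasses
import math

import numpy as np
import pytest
import scipy.stats

from mboss import (
    FitConfig,
    Instance,
    assign_folds,
    confusion_matrix,
    cross_validate,
    evaluate_generalized,
    fit,
    window_grid,
)
from mboss.boss import fit_axis_mcbs, mboss_transform
from mboss.model_selection import _count_matrix, _cv_score, _axis_symbols
from mboss.vector_space import build_class_models, predict


class TestWindowGrid:
    def test_progression_for_128(self):
        # step round(sqrt(118)) = 11
        assert window_grid(128) == [10, 21, 32, 43, 54, 65, 76, 87, 98, 109, 120]

    def test_degenerate_minimum(self):
        assert window_grid(10) == [10]

    def test_size_is_about_sqrt_n(self):
        for n in (64, 128, 256, 512):
            g = window_grid(n)
            assert len(g) <= math.isqrt(n) + 2
            assert g[0] == 10 and g[-1] <= n

    def test_min_w_filter(self):
        g = window_grid(128, min_w=18)
        assert g[0] == 21
        assert all(w >= 18 for w in g)

    def test_short_instance_warns(self):
        with pytest.warns(UserWarning):
            assert window_grid(8) == [8]


class TestFolds:
    def test_deterministic_assignment(self):
        labels = ["a"] * 12 + ["b"] * 12
        f1, k1 = assign_folds(labels, 10, seed=3)
        f2, k2 = assign_folds(labels, 10, seed=3)
        assert (f1 == f2).all() and k1 == k2

    def test_fold_count_reduced_to_min_class_size(self):
        labels = ["a"] * 3 + ["b"] * 20
        _, k = assign_folds(labels, 10, seed=0)
        assert k == 3

    def test_singleton_class_pinned_to_training(self):
        labels = ["a"] * 8 + ["lonely"]
        with pytest.warns(UserWarning):
            fold_ids, _ = assign_folds(labels, 4, seed=0)
        assert fold_ids[-1] == -1
        assert (fold_ids[:-1] >= 0).all()


def _make_disjoint_instances(rng, n_per_class=12):
    """Three classes separable by construction: distinct strong tones."""
    insts = []
    t = np.arange(128) / 50.0
    for k, f in enumerate((1.0, 3.0, 6.0)):
        for i in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            seg = np.column_stack(
                [np.sin(2 * np.pi * f * t + phase) + 0.01 * rng.normal(size=128)]
                * 3
            )
            insts.append(Instance(seg, label=f"c{k}", subject=f"s{i % 4}"))
    return insts


class TestCrossValidate:
    def test_separable_classes_score_total(self):
        rng = np.random.default_rng(0)
        insts = _make_disjoint_instances(rng)
        score = cross_validate(insts, w=32, l=8, config=FitConfig(seed=0, folds=4))
        assert score == len(insts)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        insts = _make_disjoint_instances(rng, n_per_class=8)
        cfg = FitConfig(seed=5, folds=4)
        assert cross_validate(insts, 32, 8, cfg) == cross_validate(insts, 32, 8, cfg)

    def test_permuted_labels_score_chance(self):
        """With labels permuted, the CV score falls inside the 99% binomial
        band around 1/K."""
        rng = np.random.default_rng(2)
        insts = _make_disjoint_instances(rng, n_per_class=16)
        labels = [i.label for i in insts]
        perm = rng.permutation(len(labels))
        shuffled = [
            dataclasses.replace(i, label=labels[j]) for i, j in zip(insts, perm)
        ]
        score = cross_validate(shuffled, 32, 8, FitConfig(seed=2, folds=4))
        n, p = len(shuffled), 1.0 / 3.0
        lo = scipy.stats.binom.ppf(0.005, n, p)
        hi = scipy.stats.binom.ppf(0.995, n, p)
        assert lo <= score <= hi


class TestFastPathEquivalence:
    def test_cv_fast_path_matches_dict_route(self):
        """The sparse-matrix CV scorer and the dictionary-level
        build_class_models/predict route agree fold by fold."""
        rng = np.random.default_rng(3)
        insts = _make_disjoint_instances(rng, n_per_class=6)
        # add label noise so the score is not trivially saturated
        labels = [i.label for i in insts]
        perm = rng.permutation(len(labels))
        insts = [
            dataclasses.replace(i, label=labels[j] if k % 3 else labels[k])
            for k, (i, j) in enumerate(zip(insts, perm))
        ]
        config = FitConfig(seed=9, folds=3)
        w, l = 32, 8
        params = config.params(w, l)
        data = np.stack([i.segment for i in insts])
        symbols = [
            _axis_symbols(data[:, :, a], params)[0] for a in range(data.shape[2])
        ]
        X = _count_matrix(symbols, l, config.alphabet_size)
        class_order = sorted({i.label for i in insts})
        y = np.array([class_order.index(i.label) for i in insts])
        fold_ids, folds_eff = assign_folds(
            [i.label for i in insts], config.folds, config.seed
        )
        fast = _cv_score(X, y, fold_ids, len(class_order))

        # independent dict-level route
        mcbs = fit_axis_mcbs(insts, params)
        hists = [mboss_transform(i, params, mcbs) for i in insts]
        slow = 0
        for f in range(folds_eff):
            train = [k for k in range(len(insts)) if fold_ids[k] != f]
            test = [k for k in range(len(insts)) if fold_ids[k] == f]
            clf = build_class_models(
                [hists[k] for k in train], [insts[k].label for k in train]
            )
            for k in test:
                if predict(hists[k], clf).label == insts[k].label:
                    slow += 1
        assert fast == slow


class TestFit:
    def test_separable_problem_perfect_score_and_determinism(self):
        rng = np.random.default_rng(4)
        insts = _make_disjoint_instances(rng, n_per_class=8)
        cfg = FitConfig(seed=1, folds=4)
        res1 = fit(insts, cfg)
        assert res1.score == len(insts)
        # shuffle instances: same stratified folds seed -> same selection
        order = rng.permutation(len(insts))
        res2 = fit([insts[k] for k in order], cfg)
        assert (res1.window_size, res1.word_length) == (
            res2.window_size,
            res2.word_length,
        )

    def test_tie_rule_prefers_smaller_l_then_w(self):
        rng = np.random.default_rng(5)
        insts = _make_disjoint_instances(rng, n_per_class=8)
        res = fit(insts, FitConfig(seed=1, folds=4))
        best = res.score
        ties = [k for k, v in res.grid_scores.items() if v == best]
        expected = min(ties, key=lambda wl: (wl[1], wl[0]))
        assert (res.window_size, res.word_length) == expected

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], FitConfig())


class TestConfusion:
    def test_diagonal_when_perfect(self):
        m = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        np.testing.assert_array_equal(m, [[2, 0], [0, 1]])

    def test_systematic_error_row(self):
        m = confusion_matrix(
            ["A", "A", "A"], ["B", "B", "B"], ["A", "B", "C"]
        )
        np.testing.assert_array_equal(m[0], [0, 3, 0])

    def test_row_sums_count_classes(self):
        rng = np.random.default_rng(6)
        classes = ["x", "y", "z"]
        truth = rng.choice(classes, size=60).tolist()
        pred = rng.choice(classes, size=60).tolist()
        m = confusion_matrix(truth, pred, classes)
        for k, c in enumerate(classes):
            assert m[k].sum() == truth.count(c)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["q"], ["a", "b"])


class TestReports:
    def test_accuracy_equals_trace_over_total(self, small_dataset, small_fit_config):
        rep = evaluate_generalized(small_dataset, small_fit_config)
        assert rep.overall_accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )
        # row sums = per-class instance counts
        for k, label in enumerate(rep.class_order):
            expected = sum(1 for i in small_dataset.instances if i.label == label)
            assert rep.confusion[k].sum() == expected

    def test_end_to_end_determinism(self, small_dataset, small_fit_config):
        r1 = evaluate_generalized(small_dataset, small_fit_config)
        r2 = evaluate_generalized(small_dataset, small_fit_config)
        assert r1.to_jsonable() == r2.to_jsonable()
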