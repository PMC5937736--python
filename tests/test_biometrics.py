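import itertools
import math

import numpy as np
import pytest

from blinkkin import (
    BetaMeanConfig,
    FeatureDataset,
    build_beta_mean_set,
    evaluate_classifier,
    forward_select,
    selection_rates,
)
from blinkkin.errors import InfeasibleUniquenessError, InvalidParameterError


def _ds(X, subjects, names=None):
    X = np.asarray(X, float)
    return FeatureDataset(
        X=X,
        subjects=np.asarray(subjects),
        trials=np.array([f"t{k}" for k in range(len(X))]),
        feature_names=names or [f"f{j + 1}" for j in range(X.shape[1])],
    )


def _gaussian_classes(n_classes, per_class, n_features, separation, seed):
    rng = np.random.default_rng(seed)
    centers = separation * rng.normal(size=(n_classes, n_features))
    X = np.vstack([
        centers[c] + rng.normal(size=(per_class, n_features))
        for c in range(n_classes)
    ])
    subjects = np.repeat([f"s{c}" for c in range(n_classes)], per_class)
    return _ds(X, subjects)


class TestBetaMeanSet:
    def test_beta_one_is_a_permutation_of_original_rows(self):
        rng = np.random.default_rng(0)
        ds = _ds(rng.normal(size=(12, 3)), np.repeat(["a", "b"], 6))
        out = build_beta_mean_set(ds, BetaMeanConfig(beta=1, n_boot=6, seed=1))
        for subj in ("a", "b"):
            orig = ds.X[ds.rows_of(subj)]
            boot = out.X[out.rows_of(subj)]
            orig_sorted = orig[np.lexsort(orig.T)]
            boot_sorted = boot[np.lexsort(boot.T)]
            assert np.array_equal(orig_sorted, boot_sorted)

    def test_beta_equals_b_with_multiple_boots_infeasible(self):
        ds = _ds(np.arange(24.0).reshape(8, 3), np.repeat(["a", "b"], 4))
        with pytest.raises(InfeasibleUniquenessError):
            build_beta_mean_set(ds, BetaMeanConfig(beta=4, n_boot=2))
        # beta = b with a single construction is the subject mean
        out = build_beta_mean_set(ds, BetaMeanConfig(beta=4, n_boot=1))
        assert np.allclose(out.X[out.rows_of("a")][0],
                           ds.X[ds.rows_of("a")].mean(axis=0))

    def test_requesting_more_than_comb_b_beta_rejected(self):
        ds = _ds(np.arange(12.0).reshape(6, 2), ["a"] * 6)
        assert math.comb(6, 2) == 15
        with pytest.raises(InfeasibleUniquenessError):
            build_beta_mean_set(ds, BetaMeanConfig(beta=2, n_boot=16))

    def test_exhausting_all_subsets_yields_every_combination(self):
        """Drawing exactly C(b, beta) unique subsets must enumerate them all:
        the constructed means equal the full enumeration as a multiset."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        ds = _ds(X, ["a"] * 6)
        out = build_beta_mean_set(ds, BetaMeanConfig(beta=2, n_boot=15, seed=3))
        expected = np.array([X[list(c)].mean(axis=0)
                             for c in itertools.combinations(range(6), 2)])
        got = out.X[np.lexsort(out.X.T)]
        want = expected[np.lexsort(expected.T)]
        assert np.allclose(got, want)

    def test_seed_reproducibility_and_mean_preservation(self):
        rng = np.random.default_rng(9)
        ds = _ds(rng.normal(size=(40, 4)), np.repeat(["a", "b"], 20))
        cfg = BetaMeanConfig(beta=5, n_boot=30, seed=11)
        out1 = build_beta_mean_set(ds, cfg)
        out2 = build_beta_mean_set(ds, cfg)
        assert np.array_equal(out1.X, out2.X)
        out3 = build_beta_mean_set(ds, BetaMeanConfig(beta=5, n_boot=30, seed=12))
        assert not np.array_equal(out1.X, out3.X)
        # constructed rows are unbiased for the subject mean: the Monte-Carlo
        # standard error of the mean of n_boot beta-averages bounds the gap
        for subj in ("a", "b"):
            mu = ds.X[ds.rows_of(subj)].mean(axis=0)
            sd = ds.X[ds.rows_of(subj)].std(axis=0, ddof=1)
            boot_mu = out1.X[out1.rows_of(subj)].mean(axis=0)
            se = sd / np.sqrt(5 * 30)
            assert np.all(np.abs(boot_mu - mu) < 5 * se)

    def test_average_of_waveforms_mode(self, small_dataset):
        from blinkkin import make_feature_dataset

        ds, _, segs = make_feature_dataset(n_subjects=2, trials=8, seed=7,
                                           return_segments=True)
        cfg = BetaMeanConfig(beta=3, n_boot=5, seed=2,
                             mode="average-of-waveforms")
        out = build_beta_mean_set(ds, cfg, segments_by_subject=segs)
        assert out.B == 10 and out.F == ds.F
        # averaged windows are still valid blinks with ordered landmarks
        t_cols = [out.feature_names.index(n) for n in ("t2P", "t4P", "t8P")]
        assert np.all(np.diff(out.X[:, t_cols], axis=1) > 0)


class TestEvaluateClassifier:
    def test_separable_subjects_reach_perfect_cir(self):
        ds = _gaussian_classes(2, 30, 4, separation=10.0, seed=0)
        for clf in ("lda", "qda", "knn", "ct"):
            report = evaluate_classifier(ds, classifier=clf, seed=1)
            assert report.cir == 100.0

    def test_cir_consistent_with_confusion_matrix(self):
        ds = _gaussian_classes(4, 20, 3, separation=1.0, seed=2)
        report = evaluate_classifier(ds, classifier="lda", seed=3)
        assert report.cir == pytest.approx(
            100.0 * np.trace(report.confusion) / report.confusion.sum()
        )
        assert report.confusion.sum() == ds.B

    def test_stratified_folds_balance_subjects(self):
        ds = _gaussian_classes(5, 20, 3, separation=2.0, seed=4)
        report = evaluate_classifier(ds, classifier="lda", seed=5)
        for subj in ds.subject_labels:
            per_fold = np.bincount(report.fold_assignment[ds.rows_of(subj)],
                                   minlength=10)
            assert per_fold.max() - per_fold.min() <= 1

    def test_deterministic_given_seed(self):
        ds = _gaussian_classes(3, 20, 4, separation=1.5, seed=6)
        r1 = evaluate_classifier(ds, classifier="knn", seed=7)
        r2 = evaluate_classifier(ds, classifier="knn", seed=7)
        assert r1.cir == r2.cir
        assert np.array_equal(r1.confusion, r2.confusion)
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)

    def test_loo_agrees_with_kfold_for_lda(self):
        ds = _gaussian_classes(6, 30, 5, separation=1.2, seed=8)
        kfold = evaluate_classifier(ds, "lda", "kfold", seed=9)
        loo = evaluate_classifier(ds, "lda", "loo", seed=9)
        assert abs(kfold.cir - loo.cir) <= 2.0

    def test_unknown_classifier_rejected(self):
        ds = _gaussian_classes(2, 10, 2, separation=1.0, seed=10)
        with pytest.raises(InvalidParameterError, match="svm"):
            evaluate_classifier(ds, classifier="svm")


class TestForwardSelection:
    @staticmethod
    def _one_informative(seed=0, n_noise=7):
        rng = np.random.default_rng(seed)
        n_classes, per_class = 4, 25
        informative = np.repeat(np.arange(n_classes, dtype=float) * 10,
                                per_class)
        informative += 0.1 * rng.normal(size=informative.size)
        noise = rng.normal(size=(informative.size, n_noise))
        X = np.column_stack([informative, noise])
        subjects = np.repeat([f"s{c}" for c in range(n_classes)], per_class)
        return _ds(X, subjects)

    def test_separating_feature_selected_first_then_stop(self):
        ds = self._one_informative()
        selected = forward_select(ds, classifier="lda", seed=1)
        assert selected[0] == 0
        assert len(selected) == 1  # zero loss cannot strictly decrease

    def test_first_pick_matches_exhaustive_enumeration(self):
        """Greedy step one equals the brute-force best single feature by
        10-fold misclassification count."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import StratifiedKFold

        ds = self._one_informative(seed=3)
        y = ds.subjects.astype(str)
        splits = list(StratifiedKFold(10, shuffle=True,
                                      random_state=1).split(ds.X, y))
        losses = []
        for f in range(ds.F):
            loss = 0
            for train, test in splits:
                clf = LinearDiscriminantAnalysis()
                clf.fit(ds.X[train][:, [f]], y[train])
                loss += int(np.sum(clf.predict(ds.X[test][:, [f]]) != y[test]))
            losses.append(loss)
        assert forward_select(ds, classifier="lda", seed=1)[0] == int(
            np.argmin(losses)
        )

    def test_identical_noise_features_select_at_most_one(self):
        # every column is the same noise: adding a second can never strictly
        # decrease the loss, so the stopping rule fires immediately
        rng = np.random.default_rng(12)
        col = rng.normal(size=80)
        X = np.tile(col[:, None], (1, 6))
        subjects = np.repeat([f"s{c}" for c in range(4)], 20)
        selected = forward_select(_ds(X, subjects), classifier="lda", seed=2)
        assert len(selected) <= 1

    def test_ties_break_to_lowest_index(self):
        ds = self._one_informative(seed=5)
        # duplicate the informative feature at a higher column index
        X = np.column_stack([ds.X, ds.X[:, 0]])
        dup = _ds(X, ds.subjects)
        assert forward_select(dup, classifier="lda", seed=1)[0] == 0


class TestSelectionRates:
    def test_hand_tally_on_five_runs(self):
        runs = [[0, 2], [0], [1, 2], [0, 2], [2]]
        profile = selection_rates(runs, n_features=4)
        assert profile.counts.tolist() == [3, 1, 4, 0]
        assert profile.rate.tolist() == [60.0, 20.0, 80.0, 0.0]

    def test_always_and_never_selected(self):
        profile = selection_rates([[0], [0], [0]], n_features=2)
        assert profile.rate[0] == 100.0
        assert profile.rate[1] == 0.0

    def test_empty_runs_rejected(self):
        with pytest.raises(InvalidParameterError):
            selection_rates([], n_features=3)
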