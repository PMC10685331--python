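"""Imputation scoring, paired statistics, classifiers, coherence and
impute-then-classify."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointomics import likelihoods as lk
from jointomics.data import ModalitySpec
from jointomics.evaluation import (
    ClassifierConfig,
    bootstrap_mcc_ci,
    coherence_eval,
    compare_to_baseline,
    downstream_classify,
    holm_adjust,
    imputation_eval,
    impute_then_classify,
    mcc,
    outlier_flags,
    paired_test,
    train_modality_classifier,
)
from jointomics.linear import MeanImputer, pca_fit_transform
from jointomics.models import encoder_input
from tests.conftest import two_modality_dataset


class _OracleImputer:
    """Returns the true held-out categorical profiles as one-hot params."""

    def __init__(self, dataset, K):
        self.dataset = dataset
        self.K = K

    def impute(self, Xs, source, target):
        X = Xs[int(target)]
        probs = np.eye(self.K)[X.astype(int)]
        return lk.CategoricalParams(probs=probs)


class TestImputationEval:
    def test_oracle_categorical_gives_zero(self, rng):
        from jointomics.data import MultiOmicsDataset, make_split

        X1 = rng.normal(size=(30, 3))
        X2 = rng.integers(0, 5, size=(30, 4)).astype(float)
        ds = MultiOmicsDataset(
            modalities=[(ModalitySpec("g", 3, "gaussian"), X1),
                        (ModalitySpec("c", 4, "categorical"), X2)],
            split=make_split(None, 30, (0.6, 0.2, 0.2), 0).assignment)
        r = imputation_eval(_OracleImputer(ds, 5), ds, [0], 1)
        assert np.allclose(r.ll, 0.0) and r.median == 0.0

    def test_constant_gaussian_closed_form(self, rng):
        ds = two_modality_dataset(n=50, seed=1)
        mi = MeanImputer.fit(ds)
        r = imputation_eval(mi, ds, [0], 1)
        te = ds.split_subset("test")
        c = ds.split_subset("train").matrix(1).mean(axis=0)
        oracle = np.mean(-0.5 * (np.log(2 * np.pi) + (te.matrix(1) - c) ** 2), axis=1)
        assert np.allclose(r.ll, oracle)

    def test_outlier_rule(self):
        flags = outlier_flags(np.array([0.0, 0.0, 0.0, 0.0, -100.0]))
        assert list(flags) == [False, False, False, False, True]

    def test_sample_order_invariance(self, rng):
        ds = two_modality_dataset(n=60, seed=4)
        mi = MeanImputer.fit(ds)
        r = imputation_eval(mi, ds, [0], 1)
        assert r.median == np.median(r.ll)


class TestPairedTest:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            assert paired_test(np.ones(10), np.ones(10)) == 1.0

    def test_uniform_shift_tiny_p(self):
        a = np.random.default_rng(0).normal(size=50)
        assert paired_test(a + 1.0, a) < 1e-8

    def test_exact_enumeration_n6(self, rng):
        """Exact Wilcoxon null: enumerate all 2^6 sign assignments."""
        d = np.array([0.3, -1.2, 0.7, 2.1, -0.4, 1.5])
        a = d
        b = np.zeros(6)
        p = paired_test(a, b)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        n = 6
        total = ranks.sum()
        stats_null = []
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            stats_null.append(w)
        stats_null = np.array(stats_null)
        # two-sided: distance from the mean of the null
        center = total / 2
        p_exact = np.mean(np.abs(stats_null - center) >= abs(w_obs - center) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_test(np.ones(3), np.ones(4))


class TestHolm:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12))
    def test_monotone_and_not_below_raw(self, ps):
        raw = np.array(ps)
        adj = holm_adjust(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_compare_to_baseline_frame(self, rng):
        base = rng.normal(size=40)
        lls = {"m1": base + 1.0, "m2": base + rng.normal(0, 0.01, 40)}
        out = compare_to_baseline(lls, base)
        assert set(out["method"]) == {"m1", "m2"}
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()


class TestMCC:
    def test_perfect_and_constant(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert mcc(y, y) == 1.0
        assert mcc(y, np.zeros(6, dtype=int)) == 0.0

    def test_matches_direct_covariance_formula(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        C = np.zeros((3, 3))
        for t, p in zip(y_true, y_pred):
            C[t, p] += 1
        n = C.sum()
        tk = C.sum(axis=1)
        pk = C.sum(axis=0)
        cov_tp = np.trace(C) * n - tk @ pk
        cov_tt = n ** 2 - tk @ tk
        cov_pp = n ** 2 - pk @ pk
        direct = cov_tp / np.sqrt(cov_tt * cov_pp)
        assert mcc(y_true, y_pred) == pytest.approx(direct, abs=1e-12)

    def test_label_permutation_symmetry(self, rng):
        y_true = rng.integers(0, 4, 80)
        y_pred = rng.integers(0, 4, 80)
        perm = rng.permutation(4)
        assert mcc(perm[y_true], perm[y_pred]) == pytest.approx(
            mcc(y_true, y_pred), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mcc([], [])


class TestModalityClassifier:
    def test_separable_blobs_high_accuracy(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5)) + 6.0 * labels[:, None]
        from jointomics.data import make_split

        split = make_split(labels, n, (0.6, 0.2, 0.2), 0).assignment
        clf = train_modality_classifier(
            X, labels, split, config=ClassifierConfig(hidden=[16], epochs=30,
                                                      learning_rate=1e-2, seed=0))
        assert clf.test_accuracy_ >= 0.95

    def test_shuffled_labels_chance_level(self, rng):
        n = 400
        K = 4
        labels = rng.integers(0, K, n)
        X = rng.normal(size=(n, 5))  # no signal at all
        from jointomics.data import make_split

        split = make_split(labels, n, (0.6, 0.2, 0.2), 0).assignment
        clf = train_modality_classifier(
            X, labels, split, config=ClassifierConfig(hidden=[16], epochs=20,
                                                      learning_rate=1e-2, seed=0))
        n_test = (split == "test").sum()
        band = 3 * np.sqrt(0.25 / n_test)
        assert clf.test_accuracy_ < 1.0 / K + band + 0.1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        labels = np.zeros(20, dtype=int)
        from jointomics.data import make_split

        split = make_split(None, 20, (0.6, 0.2, 0.2), 0).assignment
        with pytest.raises(ValueError):
            train_modality_classifier(X, labels, split)


class _FixedClassifier:
    def __init__(self, labels):
        self.labels = np.asarray(labels)
        self.spec_ = None

    def predict(self, X):
        return self.labels[: len(X)]


class _UniformClassifier:
    def __init__(self, K, seed):
        self.K = K
        self.rng = np.random.default_rng(seed)
        self.spec_ = None

    def predict(self, X):
        return self.rng.integers(0, self.K, len(X))


class TestCoherence:
    def test_prototype_decoders_perfect_agreement(self, tiny_trained_models):
        res = tiny_trained_models["cgvae"]
        labels = np.arange(2000) % 3
        clfs = [_FixedClassifier(labels), _FixedClassifier(labels)]
        assert coherence_eval(res, clfs, n=2000, rng=0) == 1.0

    def test_independent_uniform_null(self, tiny_trained_models):
        res = tiny_trained_models["cgvae"]
        K = 4
        clfs = [_UniformClassifier(K, 1), _UniformClassifier(K, 2)]
        frac = coherence_eval(res, clfs, n=2000, rng=0)
        band = 1.96 * np.sqrt((1 / K) * (1 - 1 / K) / 2000)
        assert abs(frac - 1 / K) < band * 1.5

    def test_zero_draws_rejected(self, tiny_trained_models):
        with pytest.raises(ValueError):
            coherence_eval(tiny_trained_models["ccvae"], [None, None], n=0)

    def test_consistent_relabeling_invariance(self, tiny_trained_models):
        res = tiny_trained_models["poe"]
        labels = np.arange(2000) % 3
        a = coherence_eval(res, [_FixedClassifier(labels), _FixedClassifier(labels)],
                           n=500, rng=0)
        relabeled = (labels + 1) % 3
        b = coherence_eval(res, [_FixedClassifier(relabeled),
                                 _FixedClassifier(relabeled)], n=500, rng=0)
        assert a == b


class TestDownstream:
    def test_one_hot_features_perfect(self, rng):
        n = 200
        labels = rng.integers(0, 3, n)
        X = np.eye(3)[labels]
        from jointomics.data import make_split

        split = make_split(labels, n, (0.6, 0.2, 0.2), 0).assignment
        r = downstream_classify(X, labels, split, classifier="svm", seed=0)
        assert r.mcc == 1.0
        assert r.ci_low == r.ci_high == 1.0

    def test_shuffled_labels_near_zero(self, rng):
        n = 300
        labels = rng.integers(0, 3, n)
        X = rng.normal(size=(n, 4))
        from jointomics.data import make_split

        split = make_split(labels, n, (0.6, 0.2, 0.2), 0).assignment
        r = downstream_classify(X, labels, split, classifier="svm", seed=0)
        assert abs(r.mcc) < 0.35

    def test_bootstrap_ci_matches_independent_resampler(self, rng):
        y_true = rng.integers(0, 3, 100)
        y_pred = np.where(rng.random(100) < 0.7, y_true, rng.integers(0, 3, 100))
        lo, hi = bootstrap_mcc_ci(y_true, y_pred, n_boot=100, seed=7)
        # independent resampling at the same seed
        rng2 = np.random.default_rng(7)
        vals = []
        for _ in range(100):
            idx = rng2.integers(0, 100, 100)
            vals.append(mcc(y_true[idx], y_pred[idx]))
        lo2, hi2 = np.percentile(vals, [2.5, 97.5])
        assert lo == pytest.approx(lo2) and hi == pytest.approx(hi2)

    def test_empty_grid_rejected(self, rng):
        n = 60
        labels = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3))
        from jointomics.data import make_split

        split = make_split(labels, n, (0.6, 0.2, 0.2), 0).assignment
        with pytest.raises(ValueError):
            downstream_classify(X, labels, split, classifier="svm", grid=())


class TestImputeThenClassify:
    def _setup(self, seed=0):
        ds = two_modality_dataset(n=200, seed=seed)
        tr = ds.split_subset("train")
        pca_maps = []
        pcs = []
        for m, (spec, X) in enumerate(ds.modalities):
            maps, _ = pca_fit_transform(encoder_input(tr.matrix(m), spec), 3)
            pca_maps.append(maps)
            pcs.append(maps.transform(encoder_input(X, spec)))
        feats = np.concatenate(pcs, axis=1)
        clf = downstream_classify(feats, ds.labels, ds.split, classifier="svm",
                                  seed=seed).classifier
        return ds, pca_maps, clf

    def test_perfect_imputer_full_agreement(self):
        ds, pca_maps, clf = self._setup()

        class Oracle:
            def impute(self, Xs, source, target):
                return lk.GaussianParams(mean=Xs[int(target)], sd=1.0)

        _, agreement, _ = impute_then_classify(Oracle(), ds, 0, pca_maps, clf)
        assert agreement == 1.0

    def test_mean_imputer_reproducible(self):
        ds, pca_maps, clf = self._setup()
        mi = MeanImputer.fit(ds)
        _, a1, _ = impute_then_classify(mi, ds, 0, pca_maps, clf)
        _, a2, _ = impute_then_classify(mi, ds, 0, pca_maps, clf)
        assert 0.0 <= a1 <= 1.0
        assert a1 == a2
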