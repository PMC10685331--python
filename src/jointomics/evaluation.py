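"""Evaluation suite: cross-modal imputation scoring, generation coherence,
downstream classification (SVM / MLP) with bootstrap CIs, impute-then-classify
agreement, and paired significance testing with family-wise error control.

All evaluations are deterministic given (model, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, matthews_corrcoef
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from . import autodiff as ad
from . import likelihoods as lk
from .data import MultiOmicsDataset
from .models import encoder_input
from .nn import MLP, Adam


# ----------------------------------------------------------------------
# imputation
@dataclass
class ImputationResult:
    ll: np.ndarray           # per-sample feature-averaged log-likelihood
    median: float
    iqr: float
    outliers: np.ndarray     # True where |ll - median| > 1.5 * IQR

    def __len__(self):
        return len(self.ll)


def outlier_flags(ll: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Samples whose log-likelihood lies further than ``factor`` times the
    interquartile range from the median."""
    ll = np.asarray(ll, dtype=float)
    q1, med, q3 = np.percentile(ll, [25, 50, 75])
    return np.abs(ll - med) > factor * (q3 - q1)


def imputation_eval(imputer, dataset: MultiOmicsDataset, source, target,
                    split: str = "test") -> ImputationResult:
    """Per-sample imputation log-likelihood of ``target`` given ``source``.

    ``imputer`` is anything exposing ``impute(Xs, source, target)`` returning
    likelihood parameters (a fitted VAE results object, a wrapped linear
    factorization, the GLM baseline or the train-mean baseline).
    """
    ds = dataset.split_subset(split) if dataset.split is not None else dataset
    Xs = [X for _, X in ds.modalities]
    target = int(target)
    params = imputer.impute(Xs, source, target)
    ll = np.asarray(ad.value_of(
        lk.feature_mean_ll(Xs[target], params, ds.specs[target])
    ))
    q1, med, q3 = np.percentile(ll, [25, 50, 75])
    return ImputationResult(ll=ll, median=float(med), iqr=float(q3 - q1),
                            outliers=outlier_flags(ll))


# ----------------------------------------------------------------------
# paired statistics
def paired_test(ll_a, ll_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-sample scores."""
    a = np.asarray(ll_a, dtype=float)
    b = np.asarray(ll_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value degenerate at 1")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down family-wise adjustment (monotone, >= raw)."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def compare_to_baseline(lls: dict, baseline, alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon tests of each method's per-sample LLs against a baseline
    vector, Holm-adjusted across the family of methods."""
    names = sorted(lls)
    raw = np.array([paired_test(lls[n], baseline) for n in names])
    adj = holm_adjust(raw)
    better = [float(np.median(np.asarray(lls[n]) - np.asarray(baseline))) > 0
              for n in names]
    return pd.DataFrame({"method": names, "p_raw": raw, "p_holm": adj,
                         "significant": adj < alpha, "median_improvement": better})


# ----------------------------------------------------------------------
# classifiers
@dataclass
class ClassifierConfig:
    hidden: list = field(default_factory=lambda: [64])
    learning_rate: float = 1e-4
    epochs: int = 150
    batch_size: int = 128
    seed: int = 0


class PerceptronClassifier:
    """Softmax MLP trained with Adam; the epoch with the lowest validation
    cross-entropy is kept."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.classes_: np.ndarray | None = None
        self.net: MLP | None = None

    def _xent(self, X, y_idx, train, rng):
        logits = self.net.forward(X, train=train, rng=rng)
        shift = ad.value_of(logits).max(axis=1, keepdims=True)
        lse = ad.log(ad.sum_(ad.exp(logits - shift), axis=1)) + shift.ravel()
        onehot = np.eye(len(self.classes_))[y_idx]
        picked = ad.sum_(logits * onehot, axis=1)
        return ad.mean_(lse - picked)

    def fit(self, X_train, y_train, X_val, y_val):
        cfg = self.config
        X_train = np.asarray(X_train, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        self.classes_, ytr = np.unique(y_train, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("classifier needs at least two classes in training data")
        lookup = {c: i for i, c in enumerate(self.classes_)}
        yva = np.array([lookup[c] for c in y_val])
        rng = np.random.default_rng(cfg.seed)
        self.net = MLP(X_train.shape[1], list(cfg.hidden), len(self.classes_), rng)
        opt = Adam(self.net.parameters(), lr=cfg.learning_rate)
        n = len(ytr)
        best = np.inf
        best_state = None
        self.val_history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                loss = self._xent(X_train[idx], ytr[idx], True, rng)
                loss.backward()
                opt.step()
            val = float(ad.value_of(self._xent(X_val, yva, False, None)))
            self.val_history_.append(val)
            if val < best:
                best = val
                best_state = [p.value.copy() for p in self.net.parameters()]
        for p, v in zip(self.net.parameters(), best_state):
            p.value = v
        self.best_val_loss_ = best
        return self

    def decision_function(self, X):
        return self.net.forward(np.asarray(X, dtype=float), numpy=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_modality_classifier(X, labels, split, spec=None,
                              config: ClassifierConfig | None = None):
    """Two-layer perceptron predicting the class from one modality's profile.

    ``split`` gives per-sample train/val/test assignment.  When a
    ModalitySpec is passed the profile is featurized the same way encoder
    inputs are (one-hot categorical, log1p counts), so generated point
    profiles can be classified consistently.  Returns the fitted classifier
    with its held-out test accuracy in ``test_accuracy_`` (so unusable
    classifiers can be rejected).
    """
    X = np.asarray(X, dtype=float)
    if spec is not None:
        X = encoder_input(X, spec)
    labels = np.asarray(labels)
    split = np.asarray(split)
    tr, va, te = (split == "train", split == "val", split == "test")
    clf = PerceptronClassifier(config or ClassifierConfig(hidden=[64, 64]))
    clf.fit(X[tr], labels[tr], X[va], labels[va])
    clf.test_accuracy_ = clf.score(X[te], labels[te]) if te.any() else np.nan
    clf.spec_ = spec
    return clf


# ----------------------------------------------------------------------
# generation coherence
def coherence_eval(results, classifiers, n: int = 2000,
                   rng: np.random.Generator | int | None = None) -> float:
    """Fraction of prior draws whose decodings all receive the same class.

    ``classifiers`` holds one per-modality classifier (as returned by
    :func:`train_modality_classifier`) in modality order.
    """
    if n <= 0:
        raise ValueError("coherence requires at least one prior draw")
    if len(classifiers) != len(results.specs):
        raise ValueError("one classifier per modality is required")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    _, params_list = results.sample_prior_decode(n, rng)
    preds = []
    for clf, params, spec in zip(classifiers, params_list, results.specs):
        profile = lk.point_profile(params)
        feat = encoder_input(profile, spec) if getattr(clf, "spec_", None) is not None \
            else profile
        preds.append(np.asarray(clf.predict(feat)))
    agree = np.ones(n, dtype=bool)
    for p in preds[1:]:
        agree &= (p == preds[0])
    return float(agree.mean())


# ----------------------------------------------------------------------
# downstream classification
def mcc(y_true, y_pred) -> float:
    """Multiclass Matthews correlation coefficient; degenerate cases -> 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


SVM_L2_GRID = (1e-4, 1e-3, 0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass
class DownstreamResult:
    mcc: float
    ci_low: float
    ci_high: float
    per_class_f1: dict
    predictions: np.ndarray
    classifier: object
    selected: dict


def bootstrap_mcc_ci(y_true, y_pred, n_boot: int = 100, seed: int = 0,
                     level: float = 0.95):
    """Percentile bootstrap CI for the MCC over resampled test samples."""
    rng = np.random.default_rng(seed)
    n = len(y_true)
    vals = np.empty(n_boot)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = mcc(y_true[idx], y_pred[idx])
    lo, hi = np.percentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def downstream_classify(features, labels, split, classifier: str = "mlp",
                        seed: int = 0, grid=SVM_L2_GRID,
                        mlp_config: ClassifierConfig | None = None) -> DownstreamResult:
    """Classify samples from embedding (or PC) features.

    ``svm``: linear SVM; the L2 regularization weight is selected on
    validation MCC over ``grid``.  ``mlp``: one 64-unit hidden layer,
    learning rate 1e-4, 150 epochs, cross-entropy, epoch selected on
    validation loss.  Reports test MCC with a 95% CI from 100 bootstrap
    resamples of the test samples and per-class F1 (classes absent from the
    test split are excluded).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    split = np.asarray(split)
    tr, va, te = (split == "train", split == "val", split == "test")
    selected: dict = {}
    if classifier == "svm":
        if not grid:
            raise ValueError("SVM grid must be non-empty")
        best_lam, best_val, best_clf = None, -np.inf, None
        for lam in grid:
            clf = LinearSVC(C=1.0 / lam, max_iter=20000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[tr], labels[tr])
            val = mcc(labels[va], clf.predict(X[va]))
            if val > best_val:
                best_lam, best_val, best_clf = lam, val, clf
        clf = best_clf
        selected["l2_weight"] = best_lam
        selected["val_mcc"] = best_val
    elif classifier == "mlp":
        cfg = mlp_config or ClassifierConfig(hidden=[64], learning_rate=1e-4,
                                             epochs=150, seed=seed)
        clf = PerceptronClassifier(cfg)
        clf.fit(X[tr], labels[tr], X[va], labels[va])
        selected["best_epoch"] = int(np.argmin(clf.val_history_))
    else:
        raise ValueError("classifier must be 'svm' or 'mlp'")
    y_pred = np.asarray(clf.predict(X[te]))
    y_test = labels[te]
    test_mcc = mcc(y_test, y_pred)
    lo, hi = bootstrap_mcc_ci(y_test, y_pred, n_boot=100, seed=seed)
    present = np.unique(y_test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1s = f1_score(y_test, y_pred, labels=present, average=None)
    per_class = {str(c): float(f) for c, f in zip(present, f1s)}
    return DownstreamResult(mcc=test_mcc, ci_low=lo, ci_high=hi,
                            per_class_f1=per_class, predictions=y_pred,
                            classifier=clf, selected=selected)


# ----------------------------------------------------------------------
# impute-then-classify
def impute_then_classify(results, dataset: MultiOmicsDataset, measured: int,
                         pca_maps, multimodal_classifier):
    """Impute the missing modality, classify on concatenated per-modality PCs,
    and compare against predictions made with both modalities measured.

    ``pca_maps`` holds one fitted :class:`~jointomics.linear.PCAMaps` per
    modality (fitted on featurized training profiles).  Only the two-modality
    case is supported.  Returns ``(predictions, agreement, mcc)``.
    """
    if dataset.n_modalities != 2:
        raise ValueError("impute-then-classify supports exactly two modalities")
    measured = int(measured)
    missing = 1 - measured
    te = dataset.split_subset("test")
    Xs = [X for _, X in te.modalities]

    def project(X, m):
        return pca_maps[m].transform(encoder_input(X, te.specs[m]))

    # both measured
    both = np.concatenate([project(Xs[0], 0), project(Xs[1], 1)], axis=1)
    pred_both = np.asarray(multimodal_classifier.predict(both))
    # measured + imputed
    params = results.impute(Xs, source=[measured], target=missing)
    imputed_profile = lk.point_profile(params)
    parts = [None, None]
    parts[measured] = project(Xs[measured], measured)
    parts[missing] = project(imputed_profile, missing)
    mixed = np.concatenate(parts, axis=1)
    pred_mixed = np.asarray(multimodal_classifier.predict(mixed))
    agreement = float(np.mean(pred_mixed == pred_both))
    m = mcc(te.labels, pred_mixed) if te.labels is not None else np.nan
    return pred_mixed, agreement, m


# ----------------------------------------------------------------------
@dataclass
class EvaluationReport:
    """Container for the evaluation outputs; writes TSVs + a JSON summary."""

    imputation: dict = field(default_factory=dict)   # (method, src->tgt) -> ImputationResult
    coherence: dict = field(default_factory=dict)    # method -> fraction
    classification: dict = field(default_factory=dict)  # (method, inputs, clf) -> DownstreamResult
    agreement: dict = field(default_factory=dict)    # (method, measured) -> rate
    tests: pd.DataFrame | None = None
    factor_tables: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out: dict = {"schema_version": 1}
        out["imputation_median_ll"] = {
            f"{m}:{task}": res.median for (m, task), res in sorted(self.imputation.items())
        }
        out["coherence"] = {k: v for k, v in sorted(self.coherence.items())}
        out["classification_mcc"] = {
            f"{m}:{inp}:{clf}": {"mcc": r.mcc, "ci": [r.ci_low, r.ci_high]}
            for (m, inp, clf), r in sorted(self.classification.items())
        }
        out["impute_classify_agreement"] = {
            f"{m}:measured={meas}": v for (m, meas), v in sorted(self.agreement.items())
        }
        if self.tests is not None:
            out["paired_tests"] = self.tests.to_dict(orient="records")
        return out

    def write(self, dirpath: str) -> None:
        import json
        import os

        os.makedirs(dirpath, exist_ok=True)
        if self.imputation:
            rows = []
            for (m, task), res in sorted(self.imputation.items()):
                for i, v in enumerate(res.ll):
                    rows.append({"method": m, "task": task, "sample": i, "ll": v,
                                 "outlier": bool(res.outliers[i])})
            pd.DataFrame(rows).to_csv(os.path.join(dirpath, "imputation_ll.tsv"),
                                      sep="\t", index=False)
        if self.tests is not None:
            self.tests.to_csv(os.path.join(dirpath, "paired_tests.tsv"),
                              sep="\t", index=False)
        for name, table in self.factor_tables.items():
            table.to_csv(os.path.join(dirpath, f"factors_{name}.tsv"),
                         sep="\t", index=False)
        with open(os.path.join(dirpath, "summary.json"), "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
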