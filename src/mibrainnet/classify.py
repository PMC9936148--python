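"""Classifiers, majority-vote ensemble, and cross-validation harnesses.

Three base classifiers — k-nearest-neighbors, shrinkage LDA (Ledoit-Wolf
analytic shrinkage of the class covariance, stable when trials are scarce
relative to features) and a 10-tree random forest — are combined by
majority vote, three-way ties going to the sLDA prediction. Evaluation
refits every data-dependent stage (CSP, fusion scaling, feature selection,
classifiers) inside each training fold, so no test information leaks into
the fitted pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold, StratifiedShuffleSplit

__all__ = ["ClassifierBundle", "EvalReport", "train_classifiers", "predict_ensemble", "evaluate_features"]

CLASSIFIER_NAMES = ("knn", "slda", "rf")


@dataclass
class ClassifierBundle:
    knn: KNeighborsClassifier
    slda: LinearDiscriminantAnalysis
    rf: RandomForestClassifier

    def predict_each(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "knn": self.knn.predict(X),
            "slda": self.slda.predict(X),
            "rf": self.rf.predict(X),
        }


@dataclass
class EvalReport:
    """Per-classifier and ensemble accuracies over a CV scheme."""

    scheme: str
    accuracies: dict[str, np.ndarray]  # classifier -> per-fold accuracy
    confusion: dict[str, np.ndarray]  # classifier -> pooled C x C counts
    classes: np.ndarray
    seed: int

    def mean_accuracy(self, name: str = "ensemble") -> float:
        return float(np.mean(self.accuracies[name]))

    def sd_accuracy(self, name: str = "ensemble") -> float:
        return float(np.std(self.accuracies[name]))

    def summary(self) -> str:
        lines = [f"scheme={self.scheme} seed={self.seed}"]
        for name in (*CLASSIFIER_NAMES, "ensemble"):
            lines.append(
                f"  {name:8s} accuracy = {self.mean_accuracy(name):.4f} "
                f"+/- {self.sd_accuracy(name):.4f}"
            )
        return "\n".join(lines)


def train_classifiers(
    X: np.ndarray, y: np.ndarray, knn_k: int = 5, rf_trees: int = 10, seed: int = 0
) -> ClassifierBundle:
    """Fit KNN, shrinkage LDA and a seeded random forest on training data."""
    y = np.asarray(y, int)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    knn = KNeighborsClassifier(n_neighbors=min(knn_k, len(y))).fit(X, y)
    slda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
    rf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed).fit(X, y)
    return ClassifierBundle(knn, slda, rf)


def predict_ensemble(models: ClassifierBundle, X: np.ndarray) -> np.ndarray:
    """Majority vote of the three classifiers; 3-way ties -> sLDA's vote."""
    votes = models.predict_each(X)
    stacked = np.stack([votes[n] for n in CLASSIFIER_NAMES])
    out = np.empty(stacked.shape[1], dtype=int)
    for i in range(stacked.shape[1]):
        vals, counts = np.unique(stacked[:, i], return_counts=True)
        if counts.max() == 1:  # all three disagree
            out[i] = votes["slda"][i]
        else:
            out[i] = vals[np.argmax(counts)]
    return out


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {int(c): i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[int(t)], idx[int(p)]] += 1
    return cm


def make_splitter(scheme: str, repeats: int, seed: int):
    """CV splitter from a scheme string: 'kfold:10' or 'split:0.5'."""
    kind, _, arg = scheme.partition(":")
    if kind == "kfold":
        k = int(arg or 10)
        if repeats > 1:
            return RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if kind == "split":
        frac = float(arg or 0.5)
        return StratifiedShuffleSplit(n_splits=repeats, test_size=frac, random_state=seed)
    raise ValueError(f"unknown scheme {scheme!r}")


def evaluate_features(
    fit_fn,
    labels: np.ndarray,
    scheme: str = "kfold:10",
    repeats: int = 1,
    seed: int = 0,
    knn_k: int = 5,
    rf_trees: int = 10,
) -> EvalReport:
    """Cross-validate a refit-per-fold pipeline.

    ``fit_fn(train_idx, test_idx) -> (X_train, X_test)`` must fit every
    data-dependent stage on the training indices only and return the final
    feature matrices for both partitions. Folds are stratified and seeded.
    """
    labels = np.asarray(labels, int)
    classes = np.unique(labels)
    splitter = make_splitter(scheme, repeats, seed)
    accs: dict[str, list[float]] = {n: [] for n in (*CLASSIFIER_NAMES, "ensemble")}
    cms = {n: np.zeros((classes.size, classes.size), int) for n in (*CLASSIFIER_NAMES, "ensemble")}
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(labels.size), labels)):
        assert not set(tr) & set(te), "train/test partitions overlap"
        X_tr, X_te = fit_fn(tr, te)
        bundle = train_classifiers(X_tr, labels[tr], knn_k, rf_trees, seed + fold)
        preds = bundle.predict_each(X_te)
        preds["ensemble"] = predict_ensemble(bundle, X_te)
        for name, pred in preds.items():
            cm = _confusion(labels[te], pred, classes)
            cms[name] += cm
            accs[name].append(np.trace(cm) / cm.sum())
    return EvalReport(
        scheme, {n: np.asarray(a) for n, a in accs.items()}, cms, classes, seed
    )
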