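"""Nested cross-validated PCA + SVM group classification.

The pipeline mirrors common practice for small-cohort diagnostic
classifiers: features are standardized and decomposed with PCA, an SVM
is trained with hyperparameters (number of components, kernel, C,
gamma) chosen by grid search in an inner cross-validation loop, and
performance is evaluated as the mean ROC AUC over a stratified tenfold
outer loop. Scaling and PCA are fit on training folds only. Two feature
sets can be compared with a 30-iteration bootstrap cross-validation and
an unpaired two-sided t-test (df = 58).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "EvalResult", "roc_auc", "nested_cv", "bootstrap_compare"]


@dataclass
class ClassifierSpec:
    """Search grid and cross-validation layout for one classifier."""

    pca_components: tuple = (2, 5, 10, 20)
    kernels: tuple = ("linear", "rbf")
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.01, 0.001)
    outer_folds: int = 10
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (self.pca_components and self.kernels and self.c_grid and self.gamma_grid):
            raise ValueError("grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class EvalResult:
    fold_aucs: list
    mean_auc: float
    mean_roc: tuple  # (fpr grid, mean tpr)
    confusion_pct: dict  # true group -> {predicted group -> mean %}
    chosen_params: list  # per-fold best hyperparameters


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve.

    Ties are handled by the rank (Mann-Whitney) convention: a tied
    positive/negative pair contributes 1/2.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _grid(spec: ClassifierSpec, n_features: int, n_train: int):
    # PCA is fit on inner-loop training folds; components cannot exceed
    # the smallest such fold's sample count
    inner_train = n_train - (n_train + spec.inner_folds - 1) // spec.inner_folds
    max_comp = max(1, min(n_features, inner_train - 1))
    comps = sorted({min(c, max_comp) for c in spec.pca_components})
    grid = [
        {
            "pca__n_components": comps,
            "svc__kernel": ["linear"],
            "svc__C": list(spec.c_grid),
        }
    ]
    if "rbf" in spec.kernels:
        grid.append(
            {
                "pca__n_components": comps,
                "svc__kernel": ["rbf"],
                "svc__C": list(spec.c_grid),
                "svc__gamma": list(spec.gamma_grid),
            }
        )
    if "linear" not in spec.kernels:
        grid = grid[1:]
    return grid


def nested_cv(X, y, spec: ClassifierSpec | None = None) -> EvalResult:
    """Nested cross-validated evaluation of the PCA + SVM classifier.

    Outer loop: stratified ``outer_folds``-fold split (seeded shuffle);
    inner loop: grid search maximizing AUC. Decision-function scores
    feed the ROC; the confusion matrix uses the default 0 threshold.
    The returned ROC curve is the mean of per-fold curves interpolated
    onto a common false-positive-rate grid.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    pos = classes[1]
    y_bin = (y == pos).astype(int)

    outer = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True, random_state=spec.seed)
    inner = StratifiedKFold(
        n_splits=spec.inner_folds, shuffle=True, random_state=spec.seed + 1
    )
    fpr_grid = np.linspace(0.0, 1.0, 101)

    fold_aucs = []
    tprs = []
    chosen = []
    confusion = {c: {c2: [] for c2 in classes} for c in classes}
    for train_idx, test_idx in outer.split(X, y_bin):
        pipe = Pipeline(
            [("scale", StandardScaler()), ("pca", PCA()), ("svc", SVC())]
        )
        search = GridSearchCV(
            pipe,
            _grid(spec, X.shape[1], len(train_idx)),
            scoring="roc_auc",
            cv=inner,
            n_jobs=1,
        )
        search.fit(X[train_idx], y_bin[train_idx])
        chosen.append(search.best_params_)
        scores = search.decision_function(X[test_idx])
        y_test = y_bin[test_idx]
        if len(np.unique(y_test)) < 2:
            raise RuntimeError("outer fold with one class despite stratification")
        fold_aucs.append(roc_auc(scores, y_test))
        fpr, tpr, _ = roc_curve(y_test, scores)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        pred = np.where(scores > 0.0, 1, 0)
        for ci, clabel in enumerate(classes):
            mask = y_test == ci
            if mask.any():
                for cj, plabel in enumerate(classes):
                    confusion[clabel][plabel].append(100.0 * np.mean(pred[mask] == cj))

    confusion_pct = {
        c: {c2: float(np.mean(v)) for c2, v in row.items()} for c, row in confusion.items()
    }
    return EvalResult(
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=float(np.mean(fold_aucs)),
        mean_roc=(fpr_grid, np.mean(tprs, axis=0)),
        confusion_pct=confusion_pct,
        chosen_params=chosen,
    )


def bootstrap_compare(
    spec_a: ClassifierSpec,
    spec_b: ClassifierSpec,
    X_a,
    X_b,
    y,
    iterations: int = 30,
    seed: int = 0,
):
    """Compare two classifiers with bootstrap cross-validation.

    For each of ``iterations`` rounds, participants are resampled with
    replacement (the same resample for both feature sets), each
    classifier is evaluated with its nested tenfold CV, and the two
    samples of mean AUCs are compared with an unpaired two-sided t-test:
    df = 2 * iterations - 2 (58 for the default 30).

    Returns (t, df, p).
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    y = np.asarray(y)
    if len(X_a) != len(y) or len(X_b) != len(y):
        raise ValueError("feature sets must cover the same participants")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs_a, aucs_b = [], []
    for it in range(iterations):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2 and min(np.bincount((y[idx] == np.unique(y)[1]).astype(int))) >= spec_a.outer_folds:
                break
        else:
            raise RuntimeError("could not draw a usable bootstrap resample")
        sub_seed = int(rng.integers(2**31))
        res_a = nested_cv(X_a[idx], y[idx], _reseed(spec_a, sub_seed))
        res_b = nested_cv(X_b[idx], y[idx], _reseed(spec_b, sub_seed))
        aucs_a.append(res_a.mean_auc)
        aucs_b.append(res_b.mean_auc)
    df = 2 * iterations - 2
    a = np.asarray(aucs_a)
    b = np.asarray(aucs_b)
    if np.allclose(a, b):
        return 0.0, df, 1.0
    t, p = stats.ttest_ind(a, b)
    return float(t), df, float(p)


def _reseed(spec: ClassifierSpec, seed: int) -> ClassifierSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)
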