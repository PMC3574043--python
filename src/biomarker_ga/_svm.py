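"""Gaussian-kernel SVM train/predict shared by the GA fitness and the
pair/evaluation accuracy measurements.

The GA evaluates tens of thousands of tiny SVM problems (around 100
samples, 15 features), where estimator construction and input validation
cost more than the optimization itself. When scikit-learn's low-level
libsvm bindings are importable we call them directly — with C-SVC, the
same C and gamma, they produce bit-identical predictions to
``sklearn.svm.SVC`` (asserted in the test suite) — and fall back to SVC
otherwise.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

try:  # fast path: raw libsvm bindings
    from sklearn.svm import _libsvm as _raw

    _raw.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _raw = None


def rbf_train_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    c: float = 1.0,
    gamma: float | None = None,
) -> np.ndarray:
    """Train a C-SVC with RBF kernel and predict the test rows.

    ``gamma`` defaults to 1 / n_features (the classic libsvm default).
    Labels may be any integer coding; predictions use the same coding.
    """
    if gamma is None:
        gamma = 1.0 / x_train.shape[1]
    if _raw is not None:
        xt = np.ascontiguousarray(x_train, dtype=np.float64)
        yt = np.ascontiguousarray(y_train, dtype=np.float64)
        model = _raw.fit(xt, yt, svm_type=0, kernel="rbf", C=float(c), gamma=float(gamma))
        pred = _raw.predict(
            np.ascontiguousarray(x_test, dtype=np.float64),
            *model[:7],
            svm_type=0,
            kernel="rbf",
            gamma=float(gamma),
        )
        return pred
    clf = SVC(C=c, kernel="rbf", gamma=gamma)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    c: float = 1.0,
    gamma: float | None = None,
) -> float:
    """Mean per-fold accuracy of the RBF SVM over a frozen fold split."""
    accs = []
    for train_idx, test_idx in folds:
        pred = rbf_train_predict(x[train_idx], y[train_idx], x[test_idx], c=c, gamma=gamma)
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-stratified k-fold index split, shuffled from ``rng``."""
    n = len(y)
    test_sets: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            test_sets[i % n_folds].append(int(j))
    folds = []
    everything = np.arange(n)
    for te in test_sets:
        te_arr = np.array(sorted(te), dtype=np.intp)
        tr_arr = np.setdiff1d(everything, te_arr)
        folds.append((tr_arr, te_arr))
    return folds
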