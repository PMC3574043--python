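"""Cross-validated evaluation of selected genes and redundancy profiling.

Two evaluation tracks mirror how biomarker candidates are judged:

* top-k evaluation — per cross-validation fold, rank genes on the
  training subset only, keep the best k, train a classifier on those
  genes and measure accuracy on the held-out subjects;
* small-set evaluation — score each individual GA final set (trained on
  the fold's training samples) on the fold's test samples, then average
  per set size, to compare single-run sets against the combined
  frequency ranking at matched sizes.

Redundancy of a ranking is profiled by the pairwise mutual information
among its top genes: high MI between two genes means that one carries
little information beyond the other.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from biomarker_ga import _svm
from biomarker_ga.preprocess import FoldPlan
from biomarker_ga.rankers import RankedList, equal_frequency_codes

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm_linear", "svm_rbf", "random_forest")


def _encode(annotation: pd.DataFrame, columns) -> np.ndarray:
    ann = annotation.set_index("sample_id").loc[list(columns)]
    labels = ann["class_label"].to_numpy()
    classes = sorted(set(labels))
    return (labels == classes[0]).astype(np.float64)


def _train_predict(
    name: str,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int,
    n_rf_trees: int,
) -> np.ndarray:
    if name == "svm_rbf":
        return _svm.rbf_train_predict(x_train, y_train, x_test)
    if name == "svm_linear":
        clf = SVC(C=1.0, kernel="linear")
    elif name == "random_forest":
        clf = RandomForestClassifier(n_estimators=n_rf_trees, random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def accuracy_topk(
    fold_rankings: list[RankedList],
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    foldplan: FoldPlan,
    k_values: tuple[int, ...] = (50, 40, 30, 20, 15, 10, 5, 3, 2, 1),
    classifiers: tuple[str, ...] = CLASSIFIERS,
    n_rf_trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out accuracy of the top-k genes of each fold's ranking.

    ``fold_rankings[f]`` must have been computed on fold f's *training*
    samples only; the test samples enter only for measuring accuracy
    (correct / total). Returns a long table with per-fold rows; average
    over folds with :func:`summarize_accuracy`.
    """
    if len(fold_rankings) != foldplan.n_folds:
        raise ValueError("one ranking per fold required")
    rows = []
    for f, (train, test) in enumerate(foldplan.folds):
        ranking = fold_rankings[f]
        x_tr_all = expression.loc[:, list(train)]
        x_te_all = expression.loc[:, list(test)]
        y_tr = _encode(annotation, train)
        y_te = _encode(annotation, test)
        for k in k_values:
            genes = ranking.top(k)
            if len(genes) < k:
                logger.warning("fold %d: ranking shorter than k=%d, truncated", f, k)
            xtr = np.ascontiguousarray(x_tr_all.loc[genes].to_numpy().T)
            xte = np.ascontiguousarray(x_te_all.loc[genes].to_numpy().T)
            for name in classifiers:
                pred = _train_predict(name, xtr, y_tr, xte, seed, n_rf_trees)
                rows.append(
                    {
                        "classifier": name,
                        "k": k,
                        "fold": f,
                        "accuracy": float(np.mean(pred == y_te)),
                    }
                )
    return pd.DataFrame(rows)


def summarize_accuracy(table: pd.DataFrame, by: tuple[str, ...] = ("classifier", "k")) -> pd.DataFrame:
    """Mean accuracy over folds, keeping the fold dispersion."""
    g = table.groupby(list(by))["accuracy"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "accuracy", "std": "accuracy_sd", "count": "n_folds"})


def small_set_accuracy(
    fold_sets: list[list[tuple[str, ...]]],
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    foldplan: FoldPlan,
) -> pd.DataFrame:
    """Test accuracy of each single-run GA set, grouped by set size.

    Every set (selected on the fold's training samples) trains a
    Gaussian SVM on the training samples and is scored on the fold's
    test samples; accuracies are averaged per set cardinality within
    each fold. Returns a long table (fold, size, accuracy, n_sets).
    """
    if len(fold_sets) != foldplan.n_folds:
        raise ValueError("one list of gene sets per fold required")
    rows = []
    for f, (train, test) in enumerate(foldplan.folds):
        y_tr = _encode(annotation, train)
        y_te = _encode(annotation, test)
        by_size: dict[int, list[float]] = {}
        for s in fold_sets[f]:
            genes = list(s)
            xtr = np.ascontiguousarray(expression.loc[genes, list(train)].to_numpy().T)
            xte = np.ascontiguousarray(expression.loc[genes, list(test)].to_numpy().T)
            pred = _svm.rbf_train_predict(xtr, y_tr, xte)
            by_size.setdefault(len(genes), []).append(float(np.mean(pred == y_te)))
        for size, accs in sorted(by_size.items()):
            rows.append(
                {"fold": f, "size": size, "accuracy": float(np.mean(accs)), "n_sets": len(accs)}
            )
    return pd.DataFrame(rows)


def mutual_information_bits(
    a: np.ndarray, b: np.ndarray, n_bins: int = 10
) -> float:
    """Plug-in mutual information of two genes after equal-frequency
    binning, in bits."""
    ca = equal_frequency_codes(a, n_bins)
    cb = equal_frequency_codes(b, n_bins)
    n = len(ca)
    ka, kb = ca.max() + 1, cb.max() + 1
    joint = np.bincount(ca * kb + cb, minlength=ka * kb).astype(float) / n
    pa = np.bincount(ca, minlength=ka).astype(float) / n
    pb = np.bincount(cb, minlength=kb).astype(float) / n

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return h(pa) + h(pb) - h(joint)


def pairwise_mutual_information(
    expression: pd.DataFrame,
    genes: list[str],
    n_bins: int = 10,
) -> pd.DataFrame:
    """MI in bits for all pairs among ``genes`` over all samples.

    The result carries ``mean`` and ``median`` summaries in
    ``DataFrame.attrs``. Genes with fewer distinct values than bins are
    binned more coarsely (logged inside the binning helper).
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    values = {g: expression.loc[g].to_numpy() for g in genes}
    rows = [
        {"gene_i": gi, "gene_j": gj, "mi": mutual_information_bits(values[gi], values[gj], n_bins)}
        for gi, gj in itertools.combinations(genes, 2)
    ]
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df["mi"].mean())
    df.attrs["median"] = float(df["mi"].median())
    return df
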