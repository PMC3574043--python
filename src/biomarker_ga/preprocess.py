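"""Differential-expression filtering and leakage-free fold construction.

The candidate-gene pool for feature selection is built in three steps:
probes mapping to the same gene symbol are averaged, genes are tested
for a class difference with a Welch two-sample t-test and filtered at a
Benjamini-Hochberg FDR of 0.1, and the survivors are ranked by absolute
log fold change with the top 1,000 kept.

Cross-validation folds are built at the *subject* level: all samples of
one subject land in the same fold, because repeated measurements of one
brain are correlated and splitting them across train and test would leak
information. Class counts and stratum (brain-region analog) proportions
are balanced across folds as far as integer constraints allow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EmptyFilterError(ValueError):
    """No gene survived the FDR filter."""


def aggregate_probes(
    probe_matrix: pd.DataFrame, mapping: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by averaging probes.

    Parameters
    ----------
    probe_matrix
        probes x samples expression values.
    mapping
        Two columns, ``probe_id`` and ``gene_symbol``. Probes absent
        from the mapping (or mapped to a null symbol) are dropped and
        counted in the log.
    """
    if mapping.empty:
        raise ValueError("probe-to-gene mapping is empty")
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"mapping must have columns {sorted(required)}")
    lookup = mapping.dropna(subset=["gene_symbol"]).set_index("probe_id")["gene_symbol"]
    mapped = probe_matrix.index.intersection(lookup.index)
    n_unmapped = probe_matrix.shape[0] - len(mapped)
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)
    sub = probe_matrix.loc[mapped]
    gene_matrix = sub.groupby(lookup.loc[mapped].to_numpy()).mean()
    gene_matrix.index.name = "gene"
    return gene_matrix


def _class_arrays(
    matrix: pd.DataFrame, annotation: pd.DataFrame, positive_label: str | None = None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    ann = annotation.set_index("sample_id").loc[list(matrix.columns)]
    labels = ann["class_label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    pos = positive_label if positive_label is not None else classes[0]
    neg = [c for c in classes if c != pos][0]
    values = matrix.to_numpy()
    return values[:, labels == pos], values[:, labels == neg], pos, neg


def welch_fdr_filter(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    fdr_cutoff: float = 0.1,
    positive_label: str | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test with BH-FDR filtering.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``q``,
    ``fold_change`` (difference of class means on the log scale,
    positive class minus the other; the positive class defaults to the
    lexicographically first label), ``retained`` and ``rank`` (filled by
    :func:`rank_by_fold_change`, NaN here).

    Genes with zero variance in both classes and equal means get p = 1
    rather than raising, so degenerate synthetic inputs run through.
    """
    a, b, pos, neg = _class_arrays(matrix, annotation, positive_label)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least two samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance genes assigned p = 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    fold_change = a.mean(axis=1) - b.mean(axis=1)
    result = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "fold_change": fold_change,
            "retained": q <= fdr_cutoff,
            "rank": np.nan,
        },
        index=matrix.index,
    )
    result.attrs["positive_label"] = pos
    result.attrs["negative_label"] = neg
    result.attrs["fdr_cutoff"] = fdr_cutoff
    return result


def rank_by_fold_change(
    filter_result: pd.DataFrame,
    matrix: pd.DataFrame,
    top_k: int = 1000,
    signed: bool = False,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Rank retained genes by fold change and truncate to ``top_k``.

    By default genes are sorted by |fold change| descending, so strongly
    down-regulated genes rank as highly as up-regulated ones; a signed
    descending sort is available via ``signed=True``. Ties break by
    smaller q, then gene symbol.

    Returns the ranked gene list, the reduced matrix (rows in rank
    order) and the filter table with ``rank`` filled in for retained
    genes.
    """
    retained = filter_result[filter_result["retained"]].copy()
    if retained.empty:
        raise EmptyFilterError("no gene passed the FDR filter")
    key = retained["fold_change"] if signed else retained["fold_change"].abs()
    retained = retained.assign(_key=key, _gene=retained.index)
    # stable sorts: symbol, then q, then fold-change key -> deterministic ties
    retained = retained.sort_values(by=["q", "_gene"], ascending=[True, True])
    retained = retained.sort_values(by="_key", ascending=False, kind="stable")
    ranked = retained.index.to_list()[: min(top_k, len(retained))]

    out = filter_result.copy()
    out.loc[ranked, "rank"] = np.arange(1, len(ranked) + 1, dtype=float)
    reduced = matrix.loc[ranked]
    return ranked, reduced, out


@dataclass(frozen=True)
class FoldPlan:
    """Grouped, stratified cross-validation folds over sample IDs.

    ``folds[k]`` is a (train_samples, test_samples) pair; no subject
    appears on both sides of any fold.
    """

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    test_subjects: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "folds": [
                {"train": list(tr), "test": list(te), "test_subjects": list(ts)}
                for (tr, te), ts in zip(self.folds, self.test_subjects)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            folds=tuple(
                (tuple(f["train"]), tuple(f["test"])) for f in payload["folds"]
            ),
            test_subjects=tuple(tuple(f["test_subjects"]) for f in payload["folds"]),
            seed=payload["seed"],
        )


def make_grouped_folds(
    annotation: pd.DataFrame, n_folds: int = 3, seed: int = 0
) -> FoldPlan:
    """Assign whole subjects to folds, balancing class and strata.

    Subjects of each class are shuffled (seeded) and dealt round-robin
    to folds, so per-fold class counts differ by at most one subject;
    since each subject carries one sample per stratum, stratum
    proportions follow automatically. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    subj = annotation.drop_duplicates("subject_id").set_index("subject_id")
    classes = sorted(subj["class_label"].unique())
    if len(classes) != 2:
        raise ValueError("annotation must contain exactly two classes")
    for c in classes:
        if (subj["class_label"] == c).sum() < n_folds:
            raise ValueError(f"fewer than {n_folds} subjects in class {c!r}")

    fold_of_subject: dict[str, int] = {}
    for c in classes:
        members = sorted(subj.index[subj["class_label"] == c])
        rng.shuffle(members)
        for i, s in enumerate(members):
            fold_of_subject[s] = i % n_folds

    samples = annotation[["sample_id", "subject_id"]]
    folds = []
    test_subjects = []
    for k in range(n_folds):
        in_test = samples["subject_id"].map(fold_of_subject) == k
        test = tuple(samples.loc[in_test, "sample_id"])
        train = tuple(samples.loc[~in_test, "sample_id"])
        folds.append((train, test))
        test_subjects.append(tuple(sorted({s for s, f in fold_of_subject.items() if f == k})))
    return FoldPlan(folds=tuple(folds), test_subjects=tuple(test_subjects), seed=seed)


def write_filter_tsv(filter_result: pd.DataFrame, path: str | Path) -> None:
    filter_result.to_csv(path, sep="\t", index_label="gene")


def read_filter_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
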