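"""Single-gene importance rankers and rank aggregation.

Three ways of scoring genes are supported, matching the three selection
methods compared throughout the package:

* information gain after supervised MDL discretization (Fayyad-Irani
  recursive binary splitting), in bits;
* random-forest mean decrease accuracy: per tree, the drop in correctly
  classified out-of-bag instances after permuting one gene's values,
  averaged over all trees and over repeated forests;
* occurrence frequency of a gene across many GA/SVM final sets.

``combine_ranks`` merges any rankings by averaging rank positions, the
standard way to aggregate scores living on incomparable scales.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by an importance score from one selection method.

    ``table`` has columns ``gene``, ``score``, ``rank`` (1 = most
    important). Higher score means more important; ties break by gene
    symbol so rankings are reproducible.
    """

    method: str
    table: pd.DataFrame

    @classmethod
    def from_scores(cls, method: str, scores: pd.Series | dict) -> "RankedList":
        s = pd.Series(scores, dtype=float)
        df = pd.DataFrame({"gene": s.index.astype(str), "score": s.to_numpy()})
        df = df.sort_values(by=["gene"]).sort_values(by="score", ascending=False, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        return cls(method=method, table=df.reset_index(drop=True))

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].to_list()

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, method: str | None = None) -> "RankedList":
        table = pd.read_csv(path, sep="\t")
        return cls(method=method or Path(path).stem, table=table)


# ---------------------------------------------------------------------------
# information gain with Fayyad-Irani MDL discretization

def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _label_entropy(y: np.ndarray) -> float:
    return _entropy_from_counts(np.bincount(y))


def best_binary_cut(values: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Cut point minimizing the weighted class entropy of the two halves.

    Candidate cuts are midpoints between adjacent distinct sorted
    values. Returns (cut, conditional_entropy) or None when the gene is
    constant. Ties resolve to the smallest cut.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    yy = y[order]
    n = len(v)
    boundaries = np.flatnonzero(v[:-1] < v[1:])  # cut after these positions
    if boundaries.size == 0:
        return None
    ones = np.cumsum(yy == 1)
    n_left = boundaries + 1
    ones_left = ones[boundaries]
    zeros_left = n_left - ones_left
    ones_right = ones[-1] - ones_left
    zeros_right = (n - n_left) - ones_right

    def h(a, b):
        tot = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            pa = np.where(tot > 0, a / tot, 0.0)
            pb = np.where(tot > 0, b / tot, 0.0)
            out = -(np.where(pa > 0, pa * np.log2(pa), 0.0) + np.where(pb > 0, pb * np.log2(pb), 0.0))
        return out

    cond = n_left / n * h(zeros_left, ones_left) + (n - n_left) / n * h(zeros_right, ones_right)
    best = int(np.argmin(cond))  # argmin takes the first = smallest cut on ties
    cut = (v[boundaries[best]] + v[boundaries[best] + 1]) / 2.0
    return float(cut), float(cond[best])


def _mdl_accepts(y: np.ndarray, y_left: np.ndarray, y_right: np.ndarray) -> bool:
    """Fayyad-Irani MDL criterion for accepting a binary split."""
    n = len(y)
    ent = _label_entropy(y)
    ent_l = _label_entropy(y_left)
    ent_r = _label_entropy(y_right)
    gain = ent - (len(y_left) / n) * ent_l - (len(y_right) / n) * ent_r
    k = len(np.unique(y))
    k_l = len(np.unique(y_left))
    k_r = len(np.unique(y_right))
    delta = math.log2(3**k - 2) - (k * ent - k_l * ent_l - k_r * ent_r)
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_cut_points(values: np.ndarray, y: np.ndarray) -> list[float]:
    """Recursive MDL-accepted binary cut points, ascending."""
    result = best_binary_cut(values, y)
    if result is None:
        return []
    cut, _ = result
    left = values < cut
    if not _mdl_accepts(y, y[left], y[~left]):
        return []
    cuts = mdl_cut_points(values[left], y[left])
    cuts.append(cut)
    cuts.extend(mdl_cut_points(values[~left], y[~left]))
    return cuts


def information_gain(
    values: np.ndarray, y: np.ndarray, method: str = "mdl", n_bins: int = 10
) -> float:
    """IG of one gene in bits: H(class) - H(class | discretized gene).

    ``method='mdl'`` uses the MDL cut-point search; genes for which no
    cut is accepted score 0. ``method='bins'`` falls back to fixed
    equal-frequency binning.
    """
    if method == "mdl":
        cuts = mdl_cut_points(values, y)
        if not cuts:
            return 0.0
        codes = np.searchsorted(np.array(cuts), values)
    elif method == "bins":
        codes = equal_frequency_codes(values, n_bins)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    n = len(y)
    cond = 0.0
    for b in np.unique(codes):
        in_bin = codes == b
        cond += in_bin.sum() / n * _label_entropy(y[in_bin])
    return _label_entropy(y) - cond


def equal_frequency_codes(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; bin count shrinks for heavily tied genes."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    if len(edges) < n_bins - 1:
        logger.debug("tied values reduced bin count to %d", len(edges) + 1)
    return np.searchsorted(edges, values, side="right")


def _encode_labels(annotation: pd.DataFrame, columns) -> np.ndarray:
    ann = annotation.set_index("sample_id").loc[list(columns)]
    labels = ann["class_label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    return (labels == classes[0]).astype(np.intp)


def information_gain_rank(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "mdl",
    n_bins: int = 10,
) -> RankedList:
    """Score every gene by information gain (deterministic)."""
    y = _encode_labels(annotation, expression.columns)
    values = expression.to_numpy()
    scores = {
        gene: information_gain(values[i], y, method=method, n_bins=n_bins)
        for i, gene in enumerate(expression.index)
    }
    return RankedList.from_scores("information_gain", scores)


# ---------------------------------------------------------------------------
# random-forest mean decrease accuracy

@dataclass(frozen=True)
class RFImportanceConfig:
    """Forest settings for mean-decrease-accuracy scoring.

    Trees are grown to purity on bootstrap samples with
    ``max_features`` (default ceil(sqrt(m))) candidate genes per split;
    the final score averages ``n_repeats`` independent forests.
    """

    n_trees: int = 1000
    n_repeats: int = 3
    max_features: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be >= 1")


def rf_importance_rank(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    config: RFImportanceConfig | None = None,
    seed: int = 0,
) -> RankedList:
    """Mean decrease accuracy over out-of-bag instances.

    For each bootstrap tree, out-of-bag samples are classified before
    (``c_before``) and after (``c_after``) permuting one gene's values;
    the gene's score is the mean of ``c_before - c_after`` over all
    trees, averaged over repeated forests. Permuting a gene a tree never
    splits on cannot change its predictions, so only genes used by the
    tree are evaluated.
    """
    config = config or RFImportanceConfig()
    config.validate()
    y = _encode_labels(annotation, expression.columns)
    x = np.ascontiguousarray(expression.to_numpy().T)
    n, m = x.shape
    k = config.max_features or int(math.ceil(math.sqrt(m)))
    rng = np.random.default_rng(seed)

    repeat_scores = np.zeros((config.n_repeats, m))
    for r in range(config.n_repeats):
        drop = np.zeros(m)
        for _ in range(config.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size == 0:
                continue
            tree = DecisionTreeClassifier(
                criterion="entropy",
                max_features=k,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(x[boot], y[boot])
            x_oob = x[oob]
            c_before = int((tree.predict(x_oob) == y[oob]).sum())
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for g in used:
                x_perm = x_oob.copy()
                x_perm[:, g] = rng.permutation(x_perm[:, g])
                c_after = int((tree.predict(x_perm) == y[oob]).sum())
                drop[g] += c_before - c_after
        repeat_scores[r] = drop / config.n_trees
    scores = pd.Series(repeat_scores.mean(axis=0), index=expression.index)
    return RankedList.from_scores("random_forest", scores)


# ---------------------------------------------------------------------------
# GA frequency ranking and rank aggregation

def frequency_rank(gene_sets: list[tuple[str, ...]]) -> RankedList:
    """Score = number of final gene sets containing the gene."""
    if not gene_sets:
        raise ValueError("need at least one gene set")
    counts = Counter(g for s in gene_sets for g in set(s))
    return RankedList.from_scores("ga_frequency", dict(counts))


def combine_ranks(lists: list[RankedList], top_n: int = 20) -> RankedList:
    """Average rank positions over several rankings.

    A gene absent from one list is treated as ranking just below that
    list's last entry (rank = list length + 1). The combined table is
    ordered by ascending average rank (tie: gene symbol) and truncated
    to ``top_n``; its ``score`` column is the negated average rank so
    that, as everywhere else, larger scores mean more important, with
    the plain average kept in ``average_rank``.
    """
    if len(lists) < 2:
        raise ValueError("need at least two rankings to combine")
    if any(rl.table.empty for rl in lists):
        raise ValueError("cannot combine an empty ranking")
    universe = sorted(set(g for rl in lists for g in rl.genes))
    avg = {}
    for gene in universe:
        ranks = []
        for rl in lists:
            pos = rl.table.loc[rl.table["gene"] == gene, "rank"]
            ranks.append(int(pos.iloc[0]) if len(pos) else len(rl.table) + 1)
        avg[gene] = float(np.mean(ranks))
    s = pd.Series(avg).sort_index()
    s = s.sort_values(kind="stable")
    df = pd.DataFrame(
        {
            "gene": s.index[:top_n],
            "score": -s.to_numpy()[:top_n],
            "rank": np.arange(1, min(top_n, len(s)) + 1),
            "average_rank": s.to_numpy()[:top_n],
        }
    )
    return RankedList(method="combined", table=df.reset_index(drop=True))
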