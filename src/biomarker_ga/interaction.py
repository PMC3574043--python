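"""Joint-occurrence analysis of gene pairs across GA/SVM final sets.

A single GA run returns one small gene set; over many runs, two genes
that help the classifier *in combination* end up in the same final set
more often than independence predicts, while mutually redundant genes
end up together less often. For genes i and j with single occurrence
counts k_i, k_j over S runs, the expected joint count under independence
is

    k'_ij = k_i * k_j / S

and the strength of over-/under-representation is the log ratio

    importance_jo = log(k_ij / k'_ij)

(natural log; only the ordering matters downstream). Significance comes
from a chi-square test with 1 df on the 2x2 per-run presence/absence
table, BH-FDR corrected at 0.05 across the pairs whose expectation
exceeds 5 (the usual chi-square validity requirement).

Pair quality is measured by the cross-validated Gaussian-SVM accuracy
of each gene alone and of the pair, giving the mean and minimal
accuracy gains of combining them.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from biomarker_ga import _svm
from biomarker_ga.ga_svm import prepare_inputs

logger = logging.getLogger(__name__)

OVER = "over"
UNDER = "under"


def count_occurrences(
    gene_sets: list[tuple[str, ...]],
) -> tuple[Counter, Counter]:
    """Single-gene and pairwise co-membership counts over the sets.

    A set of n genes contributes n(n-1)/2 pairs. Pair keys are sorted
    2-tuples of symbols.
    """
    singles: Counter = Counter()
    pairs: Counter = Counter()
    for s in gene_sets:
        members = sorted(set(s))
        singles.update(members)
        pairs.update(itertools.combinations(members, 2))
    return singles, pairs


def chi2_presence_table(
    k_i: int, k_j: int, k_ij: int, n_runs: int
) -> tuple[float, float]:
    """Chi-square statistic and p-value (1 df, no continuity correction)
    of the 2x2 table (both, i only, j only, neither) over ``n_runs`` sets.
    """
    a = k_ij
    b = k_i - k_ij
    c = k_j - k_ij
    d = n_runs - k_i - k_j + k_ij
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    denom = row1 * row2 * col1 * col2
    if denom == 0:
        return 0.0, 1.0
    stat = n_runs * (a * d - b * c) ** 2 / denom
    return float(stat), float(stats.chi2.sf(stat, df=1))


def pair_statistics(
    singles: Counter,
    pairs: Counter,
    n_runs: int,
    fdr_cutoff: float = 0.05,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Per-pair expected counts, chi-square significance and importance.

    All pairs of observed genes are enumerated (a pair never seen
    together can still be significantly under-represented). The
    expectation filter ``k'_ij > min_expected`` is applied before the
    BH correction, so only valid pairs enter the p-value list; pairs
    failing it keep ``valid = False`` and q = NaN. ``importance_jo`` is
    -inf for pairs never observed together.
    """
    from statsmodels.stats.multitest import multipletests

    genes = sorted(singles)
    rows = []
    for gi, gj in itertools.combinations(genes, 2):
        k_i, k_j = singles[gi], singles[gj]
        k_ij = pairs.get((gi, gj), 0)
        expected = k_i * k_j / n_runs
        valid = expected > min_expected
        stat, p = chi2_presence_table(k_i, k_j, k_ij, n_runs)
        with np.errstate(divide="ignore"):
            importance = float(np.log(k_ij / expected)) if expected > 0 else np.nan
        rows.append(
            {
                "gene_i": gi,
                "gene_j": gj,
                "k_i": k_i,
                "k_j": k_j,
                "k_ij": k_ij,
                "expected": expected,
                "chi2": stat,
                "p": p,
                "valid": valid,
                "importance_jo": importance,
                "direction": UNDER if k_ij < expected else OVER,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["significant"] = False
    if df["valid"].any():
        mask = df["valid"].to_numpy()
        _, q, _, _ = multipletests(df.loc[mask, "p"], method="fdr_bh")
        df.loc[mask, "q"] = q
        df.loc[mask, "significant"] = q <= fdr_cutoff
    df.attrs["n_runs"] = n_runs
    return df


@dataclass(frozen=True)
class PairAccuracy:
    """Cross-validated accuracies of two genes alone and combined."""

    gene_i: str
    gene_j: str
    acc_i: float
    acc_j: float
    acc_ij: float

    @property
    def gain_mean(self) -> float:
        return self.acc_ij - (self.acc_i + self.acc_j) / 2.0

    @property
    def gain_min(self) -> float:
        return self.acc_ij - max(self.acc_i, self.acc_j)


def pair_svm_accuracy(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_i: str,
    gene_j: str,
    seed: int = 0,
    n_folds: int = 10,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PairAccuracy:
    """Gaussian-SVM accuracy of each gene alone and of the pair.

    The same frozen stratified split is used for all three fits, so the
    gains are not artifacts of different splits; a precomputed ``folds``
    list lets callers share one split across many pairs.
    """
    x, y, genes = prepare_inputs(expression.loc[[gene_i, gene_j]], annotation)
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = _svm.stratified_folds(y, n_folds, rng)
    acc_i = _svm.cv_accuracy(np.ascontiguousarray(x[:, [0]]), y, folds)
    acc_j = _svm.cv_accuracy(np.ascontiguousarray(x[:, [1]]), y, folds)
    acc_ij = _svm.cv_accuracy(x, y, folds)
    return PairAccuracy(gene_i, gene_j, acc_i, acc_j, acc_ij)


def accumulate_top_pairs(
    pair_stats: pd.DataFrame,
    accuracies: dict[tuple[str, str], PairAccuracy],
    sizes: tuple[int, ...] = tuple(range(3, 76, 3)),
) -> pd.DataFrame:
    """Running means of pair accuracy measures over accumulating pairs.

    Significant valid pairs are sorted by ``importance_jo`` (descending
    for over-represented, ascending for under-represented) and the
    accuracy, mean gain and minimal gain are averaged over the first
    3, 6, ... pairs per direction. Sizes beyond the available number of
    pairs are truncated.
    """
    rows = []
    sig = pair_stats[pair_stats["significant"] & pair_stats["valid"]]
    if sig.empty:
        logger.warning("no significant pairs: accumulation table is empty")
    for direction in (OVER, UNDER):
        sub = sig[sig["direction"] == direction]
        sub = sub.sort_values(
            "importance_jo", ascending=(direction == UNDER), kind="stable"
        )
        pair_keys = list(zip(sub["gene_i"], sub["gene_j"]))
        accs = np.array([accuracies[k].acc_ij for k in pair_keys])
        gmean = np.array([accuracies[k].gain_mean for k in pair_keys])
        gmin = np.array([accuracies[k].gain_min for k in pair_keys])
        for size in sizes:
            if size > len(pair_keys) or size < 1:
                continue
            rows.append(
                {
                    "direction": direction,
                    "size": size,
                    "mean_acc": float(accs[:size].mean()),
                    "mean_gain_mean": float(gmean[:size].mean()),
                    "mean_gain_min": float(gmin[:size].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["direction", "size", "mean_acc", "mean_gain_mean", "mean_gain_min"])


def compare_gain_distributions(
    over_gains: np.ndarray, under_gains: np.ndarray
) -> float:
    """Two-sided Welch t-test p-value comparing the two gain samples.

    Zero variance in both groups with equal means yields p = 1.
    """
    over_gains = np.asarray(over_gains, dtype=float)
    under_gains = np.asarray(under_gains, dtype=float)
    if len(over_gains) < 2 or len(under_gains) < 2:
        raise ValueError("need at least two values per group")
    if over_gains.std() == 0 and under_gains.std() == 0:
        return 1.0 if over_gains.mean() == under_gains.mean() else 0.0
    _, p = stats.ttest_ind(over_gains, under_gains, equal_var=False)
    return float(p)


def pairs_table_with_accuracy(
    pair_stats: pd.DataFrame,
    accuracies: dict[tuple[str, str], PairAccuracy],
) -> pd.DataFrame:
    """Join accuracy measurements onto the pair-statistics table."""
    df = pair_stats.copy()
    cols = {"acc_i": [], "acc_j": [], "acc_ij": [], "gain_mean": [], "gain_min": []}
    for gi, gj in zip(df["gene_i"], df["gene_j"]):
        pa = accuracies.get((gi, gj))
        cols["acc_i"].append(pa.acc_i if pa else np.nan)
        cols["acc_j"].append(pa.acc_j if pa else np.nan)
        cols["acc_ij"].append(pa.acc_ij if pa else np.nan)
        cols["gain_mean"].append(pa.gain_mean if pa else np.nan)
        cols["gain_min"].append(pa.gain_min if pa else np.nan)
    for k, v in cols.items():
        df[k] = v
    return df
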