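import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from biomarker_ga import interaction, synthetic_data


def test_hand_counted_occurrences():
    singles, pairs = interaction.count_occurrences(
        [("a", "b", "c"), ("a", "b"), ("b", "c")]
    )
    assert singles == Counter({"b": 3, "a": 2, "c": 2})
    assert pairs == Counter({("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 1})


def test_fifteen_gene_set_contributes_105_pairs():
    genes = tuple(f"g{i}" for i in range(15))
    _, pairs = interaction.count_occurrences([genes])
    assert len(pairs) == 15 * 14 // 2 == 105
    assert all(v == 1 for v in pairs.values())


def test_counts_match_quadratic_brute_force():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(30)]
    sets = [
        tuple(np.array(genes)[rng.choice(30, size=rng.integers(2, 12), replace=False)])
        for _ in range(400)
    ]
    singles, pairs = interaction.count_occurrences(sets)
    brute_singles, brute_pairs = Counter(), Counter()
    for s in sets:
        for g in s:
            brute_singles[g] += 1
        for i in range(len(s)):
            for j in range(len(s)):
                if s[i] < s[j]:
                    brute_pairs[(s[i], s[j])] += 1
    assert singles == brute_singles
    assert pairs == brute_pairs


def test_count_conservation_invariants():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(25)]
    sets = [
        tuple(np.array(genes)[rng.choice(25, size=rng.integers(1, 9), replace=False)])
        for _ in range(200)
    ]
    singles, pairs = interaction.count_occurrences(sets)
    assert sum(singles.values()) == sum(len(s) for s in sets)
    assert sum(pairs.values()) == sum(len(s) * (len(s) - 1) // 2 for s in sets)


def test_expected_count_formula():
    """k_i=600, k_j=500 over 3000 runs give expectation 100."""
    singles = Counter({"a": 600, "b": 500})
    pairs = Counter({("a", "b"): 100})
    stats = interaction.pair_statistics(singles, pairs, n_runs=3000)
    row = stats.iloc[0]
    assert row["expected"] == pytest.approx(100.0)
    assert row["importance_jo"] == pytest.approx(0.0)
    assert row["direction"] == interaction.OVER


def test_zero_joint_count_gives_negative_infinity():
    singles = Counter({"a": 100, "b": 100})
    stats = interaction.pair_statistics(singles, Counter(), n_runs=200)
    row = stats.iloc[0]
    assert row["importance_jo"] == -np.inf
    assert row["direction"] == interaction.UNDER


def test_chi2_matches_contingency_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n_runs = 500
        k_ij = int(rng.integers(1, 80))
        k_i = k_ij + int(rng.integers(1, 100))
        k_j = k_ij + int(rng.integers(1, 100))
        stat, p = interaction.chi2_presence_table(k_i, k_j, k_ij, n_runs)
        table = [
            [k_ij, k_i - k_ij],
            [k_j - k_ij, n_runs - k_i - k_j + k_ij],
        ]
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_importance_antisymmetric_around_expectation():
    """Swapping observed k with k'^2/k mirrors the log ratio's sign."""
    singles = Counter({"a": 300, "b": 200})
    n_runs = 1000
    expected = 300 * 200 / n_runs
    k = 40
    over = interaction.pair_statistics(singles, Counter({("a", "b"): k}), n_runs).iloc[0]
    mirrored = int(round(expected**2 / k))
    under = interaction.pair_statistics(singles, Counter({("a", "b"): mirrored}), n_runs).iloc[0]
    assert over["importance_jo"] == pytest.approx(-under["importance_jo"], abs=0.01)


def test_expectation_filter_applied_before_fdr():
    singles = Counter({"a": 200, "b": 150, "c": 4, "d": 3})
    pairs = Counter({("a", "b"): 150, ("a", "c"): 2, ("c", "d"): 1})
    stats = interaction.pair_statistics(singles, pairs, n_runs=300, min_expected=5)
    low = stats[(stats["gene_i"] == "c") & (stats["gene_j"] == "d")].iloc[0]
    assert not low["valid"] and np.isnan(low["q"])
    high = stats[(stats["gene_i"] == "a") & (stats["gene_j"] == "b")].iloc[0]
    assert high["valid"] and not np.isnan(high["q"])


# ---------------------------------------------------------------------------
# pair accuracies

@pytest.fixture(scope="module")
def pair_data():
    cfg = synthetic_data.SynthConfig(
        n_genes=30,
        n_subjects=30,
        samples_per_subject=4,
        n_informative=4,
        effect_size=1.2,
        n_redundancy_blocks=0,
        block_size=0,
        seed=21,
    )
    expr, ann, truth = synthetic_data.generate_dataset(cfg)
    expr, dup = synthetic_data.add_duplicates(expr, truth.informative_genes[0], 1, jitter_sd=0.02, seed=1)
    expr, syn = synthetic_data.add_synergy_pair(expr, ann, separation=1.4, jitter_sd=0.2, seed=2)
    return expr, ann, truth, dup[0], syn


def test_duplicate_pair_adds_no_information(pair_data):
    expr, ann, truth, dup, _ = pair_data
    pa = interaction.pair_svm_accuracy(expr, ann, truth.informative_genes[0], dup, seed=0)
    assert pa.gain_min <= 0.01


def test_synergy_pair_gains_accuracy(pair_data):
    expr, ann, _, _, syn = pair_data
    pa = interaction.pair_svm_accuracy(expr, ann, syn[0], syn[1], seed=0)
    assert pa.gain_min >= 0.1


def test_min_gain_never_exceeds_mean_gain(pair_data):
    expr, ann, truth, _, _ = pair_data
    rng = np.random.default_rng(5)
    genes = list(expr.index)
    for _ in range(10):
        gi, gj = rng.choice(genes, size=2, replace=False)
        pa = interaction.pair_svm_accuracy(expr, ann, gi, gj, seed=int(rng.integers(100)))
        assert pa.gain_min <= pa.gain_mean + 1e-12
        assert 0.0 <= pa.acc_ij <= 1.0


# ---------------------------------------------------------------------------
# accumulation and gain comparison

def _fake_stats_and_accs(n_over=8, n_under=8):
    rows = []
    accs = {}
    rng = np.random.default_rng(0)
    for d, n, base in ((interaction.OVER, n_over, 0.2), (interaction.UNDER, n_under, 0.0)):
        for i in range(n):
            gi, gj = f"{d}{i}a", f"{d}{i}b"
            rows.append(
                {
                    "gene_i": gi,
                    "gene_j": gj,
                    "importance_jo": (1.0 + i) * (1 if d == interaction.OVER else -1),
                    "direction": d,
                    "significant": True,
                    "valid": True,
                }
            )
            acc = 0.6 + 0.3 * rng.random()
            accs[(gi, gj)] = interaction.PairAccuracy(gi, gj, acc - base - 0.05, acc - base, acc)
    return pd.DataFrame(rows), accs


def test_accumulation_running_means():
    stats, accs = _fake_stats_and_accs()
    table = interaction.accumulate_top_pairs(stats, accs, sizes=(3, 6))
    over = stats[stats["direction"] == interaction.OVER].sort_values("importance_jo", ascending=False)
    first6 = [accs[(r.gene_i, r.gene_j)].gain_mean for r in over.head(6).itertuples()]
    row = table[(table["direction"] == interaction.OVER) & (table["size"] == 6)].iloc[0]
    assert row["mean_gain_mean"] == pytest.approx(np.mean(first6))


def test_accumulation_single_pair():
    stats, accs = _fake_stats_and_accs(n_over=1, n_under=0)
    table = interaction.accumulate_top_pairs(stats, accs, sizes=(1, 3))
    assert len(table) == 1
    key = (stats.iloc[0]["gene_i"], stats.iloc[0]["gene_j"])
    assert table.iloc[0]["mean_acc"] == pytest.approx(accs[key].acc_ij)


def test_no_significant_pairs_gives_empty_table():
    stats, accs = _fake_stats_and_accs(n_over=2, n_under=0)
    stats["significant"] = False
    table = interaction.accumulate_top_pairs(stats, accs)
    assert table.empty


def test_gain_comparison_identical_groups_p_one():
    assert interaction.compare_gain_distributions([1, 1, 1], [1, 1, 1]) == 1.0


def test_gain_comparison_matches_textbook_welch():
    a, b = np.array([10.0, 11.0, 12.0]), np.array([0.0, 1.0, 2.0])
    p = interaction.compare_gain_distributions(a, b)
    se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
    from scipy.stats import t as tdist

    assert p == pytest.approx(2 * tdist.sf(abs(t), df), abs=1e-10)


def test_gain_comparison_symmetric():
    a, b = [0.1, 0.3, 0.2], [0.0, 0.05, 0.1]
    assert interaction.compare_gain_distributions(a, b) == pytest.approx(
        interaction.compare_gain_distributions(b, a)
    )
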