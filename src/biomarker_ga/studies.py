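"""Pre-registered synthetic validation studies.

Each study fixes a synthetic dataset and a reduced-scale GA
configuration, runs the relevant pipeline stages, and returns the
measured quantities. The studies validate, on data with known ground
truth, the behaviours the selector is used for in practice:

* ``marker_recovery`` — does repeated GA/SVM selection concentrate on
  the planted informative genes?
* ``redundancy`` — are near-duplicate genes split across runs (negative
  joint-occurrence importance, lower top-list mutual information than
  a univariate ranker, no accuracy gain from a duplicate pair)?
* ``synergy`` — are jointly-informative gene pairs over-represented in
  the final sets, and do over-represented pairs show larger accuracy
  gains than under-represented ones?
* ``statistical_control`` — do the pair chi-square/FDR machinery, the
  Welch filter and the hypergeometric ORA hold their nominal error
  rates on null inputs?
* ``leakage_canary`` — does subject-grouped cross-validation remove the
  optimistic bias that a deliberately leaked ranking exhibits?

Problem sizes are reduced relative to a full microarray study (pools of
60-500 genes, 50-600 GA runs) so each study completes in minutes on one
CPU; the GA settings are scaled proportionally (population 36-60, 8-12
generations, offspring and mutants at the standard 0.8/0.1 fractions of
the population).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import stats as sstats

from biomarker_ga import _svm, evaluation, interaction, preprocess, synthetic_data
from biomarker_ga.config import stage_seed
from biomarker_ga.enrichment import hypergeometric_ora
from biomarker_ga.ga_svm import GAConfig, prepare_inputs, run_ga
from biomarker_ga.rankers import frequency_rank, information_gain_rank

logger = logging.getLogger(__name__)


def _run_ga_batch(expr, ann, config, n_runs, base_seed):
    """Seeded independent GA runs returning sets, traces and sizes."""
    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    sets, traces = [], []
    for child in children:
        res = run_ga(expr, ann, config, seed=np.random.default_rng(child))
        sets.append(res.best_genes)
        traces.append(res.trace_best)
    return sets, traces


def marker_recovery_study(seed: int = 1) -> dict:
    """Repeated GA/SVM selection on data with 10 planted markers.

    500-gene pool, 120 samples (30 subjects x 4), 10 informative genes
    at 1.5 sigma; 50 GA runs with population 60 and 12 generations.
    Reports how many planted genes reach the top 20 of the frequency
    ranking, whether every best-fitness trace is monotone, and the
    final set sizes.
    """
    cfg = synthetic_data.SynthConfig(
        n_genes=500,
        n_subjects=30,
        samples_per_subject=4,
        n_informative=10,
        effect_size=1.5,
        n_redundancy_blocks=0,
        block_size=0,
        subject_effect_sd=0.5,
        noise_sd=1.0,
        class_balance=0.5,
        seed=stage_seed(seed, "recovery-data"),
    )
    expr, ann, truth = synthetic_data.generate_dataset(cfg)
    # inclusion probability kept at the full-scale value (15/1000), so
    # initial chromosomes hold ~7-8 genes on the halved pool
    ga = GAConfig(
        population_size=60, generations=12, n_offspring=48, n_mutants=6,
        init_inclusion_prob=15 / 1000,
    )
    sets, traces = _run_ga_batch(expr, ann, ga, 50, stage_seed(seed, "recovery-ga"))
    ranking = frequency_rank(sets)
    top20 = set(ranking.top(20))
    sizes = [len(s) for s in sets]
    return {
        "n_recovered_top20": len(top20 & set(truth.informative_genes)),
        "traces_monotone": all(
            all(b >= a - 1e-12 for a, b in zip(t, t[1:])) for t in traces
        ),
        "max_set_size": max(sizes),
        "median_set_size": float(np.median(sizes)),
        "ranking": ranking,
        "truth": truth,
        "sets": sets,
    }


def redundancy_study(seed: int = 1) -> dict:
    """Duplicate one strong marker five-fold and watch selection split.

    150 background genes with 24 moderately informative markers, plus
    one strong (2 sigma) gene duplicated five times with probe-level
    jitter. 250 GA runs; joint-occurrence statistics for the duplicate
    pairs, mean pairwise MI of the GA top-20 vs the information-gain
    top-20, and the SVM accuracy gain of a duplicate pair.
    """
    cfg = synthetic_data.SynthConfig(
        n_genes=150,
        n_subjects=30,
        samples_per_subject=4,
        n_informative=24,
        effect_size=1.2,
        n_redundancy_blocks=0,
        block_size=0,
        subject_effect_sd=0.5,
        class_balance=0.5,
        seed=stage_seed(seed, "redundancy-data"),
    )
    expr, ann, truth = synthetic_data.generate_dataset(cfg)
    strong = "STRONG"
    expr = synthetic_data.add_informative_gene(
        expr, ann, strong, effect=2.0, seed=stage_seed(seed, "redundancy-strong")
    )
    expr, copies = synthetic_data.add_duplicates(
        expr, strong, n_copies=5, jitter_sd=0.05, seed=stage_seed(seed, "redundancy-dup")
    )
    group = [strong] + copies

    ga = GAConfig(
        population_size=40, generations=10, n_offspring=32, n_mutants=4, mean_initial_genes=12
    )
    n_runs = 250
    sets, _ = _run_ga_batch(expr, ann, ga, n_runs, stage_seed(seed, "redundancy-ga"))
    singles, pair_counts = interaction.count_occurrences(sets)
    pstats = interaction.pair_statistics(singles, pair_counts, n_runs=n_runs)

    dup_keys = {tuple(sorted(p)) for p in itertools.combinations(group, 2)}
    is_dup = pstats.apply(lambda r: (r["gene_i"], r["gene_j"]) in dup_keys, axis=1)
    dup_valid = pstats[is_dup & pstats["valid"]]

    ga_rank = frequency_rank(sets)
    ig_rank = information_gain_rank(expr, ann)
    mi_ga = evaluation.pairwise_mutual_information(expr, ga_rank.top(20))
    mi_ig = evaluation.pairwise_mutual_information(expr, ig_rank.top(20))

    pa = interaction.pair_svm_accuracy(
        expr, ann, strong, copies[0], seed=stage_seed(seed, "redundancy-cv")
    )
    return {
        "n_dup_pairs_valid": len(dup_valid),
        "dup_importance_max": float(dup_valid["importance_jo"].max()) if len(dup_valid) else float("nan"),
        "all_dup_pairs_underrepresented": bool((dup_valid["importance_jo"] < 0).all()) and len(dup_valid) > 0,
        "mi_ga_top20": mi_ga.attrs["mean"],
        "mi_ig_top20": mi_ig.attrs["mean"],
        "duplicate_gain_min": pa.gain_min,
        "ga_ranking": ga_rank,
        "ig_ranking": ig_rank,
        "group": group,
        "pair_stats": pstats,
        "sets": sets,
    }


def synergy_study(seed: int = 1) -> dict:
    """Planted two-gene synergies in a weak-marker background.

    Pool of ~62 genes: 17 synergy pairs (class encoded in which member
    of the pair is larger; separation graded 1.3 down to 0.85, the
    first pair strongest), 10 weak single markers, and background
    noise. The focal checks — the strongest planted pair is
    significantly over-represented and gains accuracy over its best
    single gene — use a 200-run batch. Pair-level statistics for the
    accumulation curve pool 600 runs (the same 200 plus an extension),
    because chi-square validity (expectation > 5) and FDR power for the
    many weaker pairs need the larger run count; under-represented
    pairs arise from substitution between competing synergy pairs.
    """
    cfg = synthetic_data.SynthConfig(
        n_genes=28,
        n_subjects=30,
        samples_per_subject=4,
        n_informative=10,
        effect_size=0.8,
        n_redundancy_blocks=0,
        block_size=0,
        subject_effect_sd=0.5,
        class_balance=0.5,
        seed=stage_seed(seed, "synergy-data"),
    )
    expr, ann, truth = synthetic_data.generate_dataset(cfg)
    # 17 synergy pairs, graded separation, pair 0 strongest
    separations = [1.3] + list(np.linspace(1.0, 0.85, 16))
    pair_names = []
    for i, sep in enumerate(separations):
        names = (f"SYN{i:02d}A", f"SYN{i:02d}B")
        expr, names = synthetic_data.add_synergy_pair(
            expr,
            ann,
            names=names,
            separation=float(sep),
            shared_sd=1.0,
            jitter_sd=0.3,
            seed=stage_seed(seed, f"synergy-pair{i}"),
        )
        pair_names.append(tuple(sorted(names)))

    ga = GAConfig(
        population_size=36, generations=8, n_offspring=28, n_mutants=4, mean_initial_genes=15
    )
    n_focal_runs, n_runs = 200, 600
    sets, _ = _run_ga_batch(expr, ann, ga, n_runs, stage_seed(seed, "synergy-ga"))
    singles, pair_counts = interaction.count_occurrences(sets)
    pstats = interaction.pair_statistics(singles, pair_counts, n_runs=n_runs)

    focal = pair_names[0]
    s200, p200 = interaction.count_occurrences(sets[:n_focal_runs])
    pstats200 = interaction.pair_statistics(s200, p200, n_runs=n_focal_runs)
    focal_row = pstats200[
        (pstats200["gene_i"] == focal[0]) & (pstats200["gene_j"] == focal[1])
    ]

    # accuracy of all significant pairs on one shared 10-fold split
    _, y, _ = prepare_inputs(expr.iloc[:1], ann)
    shared = _svm.stratified_folds(y, 10, np.random.default_rng(stage_seed(seed, "synergy-cv")))
    sig = pstats[pstats["significant"] & pstats["valid"]]
    accuracies = {}
    for gi, gj in zip(sig["gene_i"], sig["gene_j"]):
        accuracies[(gi, gj)] = interaction.pair_svm_accuracy(expr, ann, gi, gj, folds=shared)
    accum = interaction.accumulate_top_pairs(pstats, accuracies)
    over = accum[accum["direction"] == interaction.OVER].set_index("size")
    under = accum[accum["direction"] == interaction.UNDER].set_index("size")
    common = over.index.intersection(under.index)
    diffs = (over.loc[common, "mean_gain_mean"] - under.loc[common, "mean_gain_mean"]).to_numpy()
    # one-sided sign test: direction (over > under) fixed in advance
    n_pos = int((diffs > 0).sum())
    sign_p = float(sstats.binom.sf(n_pos - 1, len(diffs), 0.5)) if len(diffs) else float("nan")

    over_gains = np.array([accuracies[k].gain_mean for k in zip(sig["gene_i"], sig["gene_j"])
                           if sig.set_index(["gene_i", "gene_j"]).loc[k, "direction"] == interaction.OVER])
    under_gains = np.array([accuracies[k].gain_mean for k in zip(sig["gene_i"], sig["gene_j"])
                            if sig.set_index(["gene_i", "gene_j"]).loc[k, "direction"] == interaction.UNDER])
    welch_p = (
        interaction.compare_gain_distributions(over_gains, under_gains)
        if len(over_gains) > 1 and len(under_gains) > 1
        else float("nan")
    )

    focal_acc = interaction.pair_svm_accuracy(expr, ann, focal[0], focal[1], folds=shared)
    return {
        "focal_pair": focal,
        "focal_significant": bool(focal_row["significant"].iloc[0]) if len(focal_row) else False,
        "focal_direction": focal_row["direction"].iloc[0] if len(focal_row) else None,
        "focal_importance": float(focal_row["importance_jo"].iloc[0]) if len(focal_row) else float("nan"),
        "focal_gain_min": focal_acc.gain_min,
        "n_over_significant": int((sig["direction"] == interaction.OVER).sum()),
        "n_under_significant": int((sig["direction"] == interaction.UNDER).sum()),
        "n_common_sizes": int(len(diffs)),
        "n_sizes_over_wins": n_pos,
        "sign_test_p": sign_p,
        "welch_gain_p": welch_p,
        "accumulation": accum,
        "pair_stats": pstats,
        "sets": sets,
    }


def statistical_control_study(seed: int = 1) -> dict:
    """Error rates of the inferential machinery on null inputs.

    (a) 3,000 gene sets filled by independent uniform sampling (no
    interaction structure): fraction of FDR-significant pairs among
    valid ones. (b) Welch filter on effect-free, subject-effect-free
    data: pooled KS test of p-value uniformity over 20 generator seeds.
    (c) ORA of 1,000 random selections: fraction significant.
    """
    rng = np.random.default_rng(stage_seed(seed, "null-sets"))
    n_genes, n_runs, set_size = 300, 3000, 15
    genes = [f"G{i:04d}" for i in range(n_genes)]
    sets = [
        tuple(np.array(genes)[rng.choice(n_genes, size=set_size, replace=False)])
        for _ in range(n_runs)
    ]
    singles, pair_counts = interaction.count_occurrences(sets)
    pstats = interaction.pair_statistics(singles, pair_counts, n_runs=n_runs)
    valid = pstats[pstats["valid"]]
    frac_sig = float(valid["significant"].mean()) if len(valid) else 0.0
    se_sig = float(np.sqrt(0.05 * 0.95 / max(len(valid), 1)))

    pvals = []
    for i in range(20):
        cfg = synthetic_data.SynthConfig(
            n_genes=200,
            n_subjects=30,
            samples_per_subject=2,
            n_informative=0,
            effect_size=0.0,
            n_redundancy_blocks=0,
            block_size=0,
            subject_effect_sd=0.0,
            seed=stage_seed(seed, f"null-expr{i}"),
        )
        expr, ann, _ = synthetic_data.generate_dataset(cfg)
        filt = preprocess.welch_fdr_filter(expr, ann)
        pvals.append(filt["p"].to_numpy())
    ks_p = float(sstats.kstest(np.concatenate(pvals), "uniform").pvalue)

    rng2 = np.random.default_rng(stage_seed(seed, "null-ora"))
    universe = [f"U{i:04d}" for i in range(1000)]
    reference = list(rng2.choice(universe, size=50, replace=False))
    n_sig = 0
    n_draws = 1000
    for _ in range(n_draws):
        selected = rng2.choice(universe, size=30, replace=False)
        if hypergeometric_ora(set(selected), reference, universe).status == "significant":
            n_sig += 1
    ora_rate = n_sig / n_draws
    ora_se = float(np.sqrt(0.05 * 0.95 / n_draws))
    return {
        "pair_fraction_significant": frac_sig,
        "pair_fraction_bound": 0.05 + 3 * se_sig,
        "n_valid_pairs": int(len(valid)),
        "ks_uniform_p": ks_p,
        "ora_significant_rate": ora_rate,
        "ora_rate_bound": 0.05 + 3 * ora_se,
    }


def leakage_canary_study(seed: int = 1) -> dict:
    """Grouped folds versus a deliberately leaked ranking.

    Weak-signal data (0.5 sigma markers among 400 genes) where
    selection overfitting is visible: rankings computed on *all*
    samples — test subjects included, the classic feature-selection
    leak — must yield higher apparent test accuracy than leak-free
    rankings computed on each fold's training samples alone. Also
    re-checks the no-straddling invariant of the fold plans across
    100 seeds.
    """
    cfg = synthetic_data.SynthConfig(
        n_genes=400,
        n_subjects=24,
        samples_per_subject=3,
        n_informative=8,
        effect_size=0.5,
        n_redundancy_blocks=0,
        block_size=0,
        subject_effect_sd=0.5,
        class_balance=0.5,
        seed=stage_seed(seed, "leak-data"),
    )
    expr, ann, _ = synthetic_data.generate_dataset(cfg)
    plan = preprocess.make_grouped_folds(ann, n_folds=3, seed=stage_seed(seed, "leak-folds"))

    leaked = information_gain_rank(expr, ann)  # selection saw the test subjects
    clean_rankings, leaked_rankings = [], []
    for train, _test in plan.folds:
        ann_tr = ann[ann["sample_id"].isin(train)]
        clean_rankings.append(information_gain_rank(expr.loc[:, list(train)], ann_tr))
        leaked_rankings.append(leaked)
    k_values = (5, 10, 20)
    clean = evaluation.accuracy_topk(
        clean_rankings, expr, ann, plan, k_values=k_values, classifiers=("svm_rbf",)
    )
    leaked = evaluation.accuracy_topk(
        leaked_rankings, expr, ann, plan, k_values=k_values, classifiers=("svm_rbf",)
    )

    ann_all = ann
    straddle = 0
    for s in range(100):
        p = preprocess.make_grouped_folds(ann_all, n_folds=3, seed=s)
        subj = ann_all.set_index("sample_id")["subject_id"]
        for train, test in p.folds:
            straddle += len(set(subj.loc[list(train)]) & set(subj.loc[list(test)]))
    return {
        "clean_accuracy": float(clean["accuracy"].mean()),
        "leaked_accuracy": float(leaked["accuracy"].mean()),
        "n_straddling_subjects": straddle,
    }
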