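"""End-to-end orchestration of the synthetic biomarker-discovery study.

Stages run in dependency order: simulate -> filter -> folds -> ga ->
rank -> evaluate -> pairs -> enrich. Every artifact is written under the
output directory and recorded in a manifest (file, stage, seed), and a
re-run with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from biomarker_ga import (
    _svm,
    enrichment,
    evaluation,
    ga_svm,
    interaction,
    preprocess,
    rankers,
    synthetic_data,
)
from biomarker_ga.config import PipelineConfig, stage_seed

logger = logging.getLogger(__name__)


class MissingStageError(RuntimeError):
    """An upstream artifact required by a stage is absent."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, files: list[Path], seed: int | None) -> None:
        manifest["stages"][stage] = {
            "files": [str(f.relative_to(out)) for f in files],
            "seed": seed,
        }

    # -- simulate -----------------------------------------------------------
    seed_sim = stage_seed(config.seed, "simulate")
    synth = synthetic_data.SynthConfig(
        **{**synthetic_data.config_to_dict(config.synthetic), "seed": seed_sim}
    )
    expr, ann, truth = synthetic_data.generate_dataset(synth)
    files = [out / "expression.tsv", out / "annotation.tsv", out / "truth.json"]
    synthetic_data.write_expression_tsv(expr, files[0])
    synthetic_data.write_annotation_tsv(ann, files[1])
    synthetic_data.write_truth_json(truth, files[2])
    record("simulate", files, seed_sim)

    # -- filter (whole-data track, for final biomarker ranking) -------------
    filt = preprocess.welch_fdr_filter(expr, ann, fdr_cutoff=config.filter.fdr_cutoff)
    _, reduced, filt = preprocess.rank_by_fold_change(
        filt, expr, top_k=config.filter.top_k, signed=config.filter.signed_fold_change
    )
    files = [out / "filter.tsv", out / "reduced_expression.tsv"]
    preprocess.write_filter_tsv(filt, files[0])
    synthetic_data.write_expression_tsv(reduced, files[1])
    record("filter", files, None)

    # -- folds --------------------------------------------------------------
    seed_folds = stage_seed(config.seed, "folds")
    plan = preprocess.make_grouped_folds(ann, n_folds=config.folds.n_folds, seed=seed_folds)
    files = [out / "folds.json"]
    plan.to_json(files[0])
    record("folds", files, seed_folds)

    # -- ga (whole-data runs) ------------------------------------------------
    sets: list[tuple[str, ...]] = []
    ga_ranking = None
    if config.run_ga:
        seed_ga = stage_seed(config.seed, "ga")
        sets, freq = ga_svm.run_many(
            reduced, ann, config.ga.ga, n_runs=config.ga.n_runs, base_seed=seed_ga
        )
        files = [out / "ga_sets.txt", out / "ga_frequency.tsv"]
        ga_svm.write_gene_sets(sets, files[0])
        freq.to_csv(files[1], sep="\t", index=False)
        record("ga", files, seed_ga)
        ga_ranking = rankers.frequency_rank(sets)

    # -- rank (baselines + aggregation) --------------------------------------
    seed_rank = stage_seed(config.seed, "rank")
    ig = rankers.information_gain_rank(reduced, ann, method=config.rankers.ig_method)
    rf = rankers.rf_importance_rank(reduced, ann, config.rankers.rf, seed=seed_rank)
    base_lists = ([ga_ranking] if ga_ranking is not None else []) + [ig, rf]
    combined = rankers.combine_ranks(base_lists, top_n=config.rankers.combine_top_n)
    files = [out / "rank_ig.tsv", out / "rank_rf.tsv", out / "rank_combined.tsv"]
    ig.to_tsv(files[0])
    rf.to_tsv(files[1])
    combined.to_tsv(files[2])
    if ga_ranking is not None:
        files.append(out / "rank_ga_freq.tsv")
        ga_ranking.to_tsv(files[-1])
    record("rank", files, seed_rank)

    # -- evaluate (cross-validated track + MI profile) ------------------------
    if config.run_evaluation:
        seed_eval = stage_seed(config.seed, "evaluate")
        fold_rankings = []
        fold_sets = []
        for f, (train, _test) in enumerate(plan.folds):
            sub_ann = ann[ann["sample_id"].isin(train)]
            sub_filt = preprocess.welch_fdr_filter(
                expr.loc[:, list(train)], sub_ann, fdr_cutoff=config.filter.fdr_cutoff
            )
            _, sub_reduced, _ = preprocess.rank_by_fold_change(
                sub_filt, expr.loc[:, list(train)], top_k=config.filter.top_k
            )
            fold_rankings.append(rankers.information_gain_rank(sub_reduced, sub_ann))
            if config.run_ga and config.ga.per_fold_runs > 0:
                fsets, _ = ga_svm.run_many(
                    sub_reduced,
                    sub_ann,
                    config.ga.ga,
                    n_runs=config.ga.per_fold_runs,
                    base_seed=stage_seed(config.seed, f"evaluate-fold{f}"),
                )
                fold_sets.append(fsets)
        k_values = tuple(
            k for k in config.evaluate.k_values if k <= len(fold_rankings[0].table)
        )
        topk = evaluation.accuracy_topk(
            fold_rankings,
            expr,
            ann,
            plan,
            k_values=k_values,
            classifiers=config.evaluate.classifiers,
            n_rf_trees=config.evaluate.n_rf_trees,
            seed=seed_eval,
        )
        files = [out / "evaluate_topk.tsv"]
        topk.to_csv(files[0], sep="\t", index=False)
        if fold_sets:
            small = evaluation.small_set_accuracy(fold_sets, expr, ann, plan)
            files.append(out / "evaluate_small_sets.tsv")
            small.to_csv(files[-1], sep="\t", index=False)
        mi_ranking = ga_ranking if ga_ranking is not None else ig
        mi_top = min(config.evaluate.mi_top, len(mi_ranking.table))
        mi = evaluation.pairwise_mutual_information(
            reduced, mi_ranking.top(mi_top), n_bins=config.evaluate.mi_bins
        )
        files.append(out / "evaluate_mi_ga_top.tsv")
        mi.to_csv(files[-1], sep="\t", index=False)
        record("evaluate", files, seed_eval)

    # -- pairs ---------------------------------------------------------------
    if not sets:
        raise MissingStageError("pairs stage requires GA gene sets; enable the ga stage")
    seed_pairs = stage_seed(config.seed, "pairs")
    singles, pair_counts = interaction.count_occurrences(sets)
    stats = interaction.pair_statistics(
        singles,
        pair_counts,
        n_runs=len(sets),
        fdr_cutoff=config.pairs.fdr_cutoff,
        min_expected=config.pairs.min_expected,
    )
    sig = stats[stats["significant"]].copy()
    accuracies: dict[tuple[str, str], interaction.PairAccuracy] = {}
    _, y_all, _ = ga_svm.prepare_inputs(reduced.iloc[:1], ann)
    shared_folds = _svm.stratified_folds(y_all, 10, np.random.default_rng(seed_pairs))
    for direction in (interaction.OVER, interaction.UNDER):
        sub = sig[sig["direction"] == direction].sort_values(
            "importance_jo", ascending=(direction == interaction.UNDER)
        )
        for gi, gj in list(zip(sub["gene_i"], sub["gene_j"]))[: config.pairs.max_accuracy_pairs]:
            accuracies[(gi, gj)] = interaction.pair_svm_accuracy(
                reduced, ann, gi, gj, folds=shared_folds
            )
    table = interaction.pairs_table_with_accuracy(stats, accuracies)
    sizes = tuple(
        range(config.pairs.accumulation_step, config.pairs.accumulation_max + 1, config.pairs.accumulation_step)
    )
    # accumulate only over the significant pairs whose accuracy was measured
    measured = stats.merge(
        pd.DataFrame([{"gene_i": gi, "gene_j": gj} for gi, gj in accuracies]),
        on=["gene_i", "gene_j"],
    ) if accuracies else stats.iloc[0:0]
    accum = interaction.accumulate_top_pairs(measured, accuracies, sizes=sizes)
    files = [out / "pairs.tsv", out / "pairs_accumulation.tsv"]
    table.to_csv(files[0], sep="\t", index=False)
    accum.to_csv(files[1], sep="\t", index=False)
    record("pairs", files, seed_pairs)

    # -- enrich --------------------------------------------------------------
    seed_enrich = stage_seed(config.seed, "enrich")
    lists = synthetic_data.generate_reference_lists(
        truth,
        expr.index,
        fraction=config.enrich.reference_fraction,
        n_fillers=config.enrich.reference_fillers,
        decoy_size=min(config.enrich.decoy_size, max(1, len(expr.index) // 4)),
        seed=seed_enrich,
    )
    enr_ranking = ga_ranking if ga_ranking is not None else ig
    sizes = tuple(s for s in config.enrich.sizes if s <= len(enr_ranking.table))
    table_enr, matrix = enrichment.enrichment_sweep(
        enr_ranking, lists, set(expr.index), sizes=sizes, alpha=config.enrich.alpha
    )
    files = [out / "enrichment.tsv", out / "enrichment_matrix.tsv"]
    table_enr.to_csv(files[0], sep="\t", index=False)
    matrix.to_csv(files[1], sep="\t")
    record("enrich", files, seed_enrich)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
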