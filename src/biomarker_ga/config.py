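"""Pipeline configuration and per-stage seed derivation.

Every stochastic stage derives its RNG stream from the global seed and
its own stage name, so adding or re-running one stage never perturbs
another stage's randomness.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from biomarker_ga.ga_svm import GAConfig
from biomarker_ga.rankers import RFImportanceConfig
from biomarker_ga.synthetic_data import SynthConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class FilterParams:
    fdr_cutoff: float = 0.1
    top_k: int = 1000
    signed_fold_change: bool = False


@dataclass(frozen=True)
class FoldParams:
    n_folds: int = 3


@dataclass(frozen=True)
class GAStageParams:
    ga: GAConfig = field(default_factory=GAConfig)
    n_runs: int = 500
    per_fold_runs: int = 50


@dataclass(frozen=True)
class RankerParams:
    rf: RFImportanceConfig = field(default_factory=RFImportanceConfig)
    ig_method: str = "mdl"
    combine_top_n: int = 20


@dataclass(frozen=True)
class EvaluateParams:
    k_values: tuple[int, ...] = (50, 40, 30, 20, 15, 10, 5, 3, 2, 1)
    classifiers: tuple[str, ...] = ("svm_linear", "svm_rbf", "random_forest")
    n_rf_trees: int = 1000
    mi_top: int = 50
    mi_bins: int = 10


@dataclass(frozen=True)
class PairParams:
    fdr_cutoff: float = 0.05
    min_expected: float = 5.0
    accumulation_step: int = 3
    accumulation_max: int = 75
    max_accuracy_pairs: int = 50  # per direction, most extreme first


@dataclass(frozen=True)
class EnrichParams:
    sizes: tuple[int, ...] = tuple(range(40, 201, 20))
    alpha: float = 0.05
    reference_fraction: float = 0.8
    reference_fillers: int = 10
    decoy_size: int = 50


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration for the end-to-end synthetic pipeline."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    folds: FoldParams = field(default_factory=FoldParams)
    ga: GAStageParams = field(default_factory=GAStageParams)
    rankers: RankerParams = field(default_factory=RankerParams)
    evaluate: EvaluateParams = field(default_factory=EvaluateParams)
    pairs: PairParams = field(default_factory=PairParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    run_evaluation: bool = True
    run_ga: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _build(cls, data: dict):
    fields = {f: data[f] for f in data}
    return cls(**fields)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration.

    Nested sections mirror the stage dataclasses field-for-field;
    omitted keys keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return pipeline_config_from_dict(raw)


def pipeline_config_from_dict(raw: dict) -> PipelineConfig:
    kwargs: dict = {}
    for key in ("seed", "out_dir", "run_evaluation", "run_ga"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw:
        kwargs["synthetic"] = _build(SynthConfig, raw["synthetic"])
    if "filter" in raw:
        kwargs["filter"] = _build(FilterParams, raw["filter"])
    if "folds" in raw:
        kwargs["folds"] = _build(FoldParams, raw["folds"])
    if "ga" in raw:
        section = dict(raw["ga"])
        ga_cfg = _build(GAConfig, section.pop("ga", {}))
        kwargs["ga"] = GAStageParams(ga=ga_cfg, **section)
    if "rankers" in raw:
        section = dict(raw["rankers"])
        rf_cfg = _build(RFImportanceConfig, section.pop("rf", {}))
        kwargs["rankers"] = RankerParams(rf=rf_cfg, **section)
    if "evaluate" in raw:
        section = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw["evaluate"].items()
        }
        kwargs["evaluate"] = _build(EvaluateParams, section)
    if "pairs" in raw:
        kwargs["pairs"] = _build(PairParams, raw["pairs"])
    if "enrich" in raw:
        section = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw["enrich"].items()
        }
        kwargs["enrich"] = _build(EnrichParams, section)
    return PipelineConfig(**kwargs)
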