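"""Synthetic two-class expression data with planted structure.

Generates log-scale expression matrices that emulate the structure of a
two-class brain microarray study: a minority of truly informative genes
(class-shifted), blocks of mutually redundant genes driven by a shared
latent signal, and repeated measurements per subject (one sample per
"brain region", all samples of a subject sharing the subject's class and
an additive subject effect). Every downstream stage of the package is
testable against the planted ground truth without any external data.

Signal model for gene g in sample s (all on the log2 scale)::

    x[g, s] = baseline
            + delta[g] * 1{class(s) = affected}     (informative genes)
            + w_b * L_b[s]                          (members of block b)
            + u[g, subject(s)]                      (subject effect)
            + e[g, s]                               (iid Gaussian noise)

with e ~ N(0, noise_sd^2), u ~ N(0, subject_effect_sd^2), L_b ~ N(0, 1)
per sample, and the block mixing weight w_b solved so that the expected
pairwise Pearson correlation between two block members equals
``block_correlation``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AFFECTED = "affected"
CONTROL = "control"


class ConfigurationError(ValueError):
    """Raised when a synthesis configuration violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic expression study.

    Defaults emulate a candidate pool after differential-expression
    filtering: 1,000 genes, 28 subjects each measured in 6 strata
    (a brain-region analog), with a slight excess of affected subjects.

    Parameters
    ----------
    effect_size
        Class-mean shift of informative genes, in units of ``noise_sd``.
    block_correlation
        Target pairwise Pearson correlation between members of one
        redundancy block.
    subject_effect_sd
        SD of the per-(gene, subject) random intercept shared by all
        samples of a subject.
    class_balance
        Fraction of subjects assigned to the affected class.
    """

    n_genes: int = 1000
    n_subjects: int = 28
    samples_per_subject: int = 6
    n_informative: int = 30
    effect_size: float = 1.0
    n_redundancy_blocks: int = 5
    block_size: int = 5
    block_correlation: float = 0.8
    subject_effect_sd: float = 0.5
    noise_sd: float = 1.0
    class_balance: float = 0.54
    baseline: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_subjects <= 1 or self.samples_per_subject <= 0:
            raise ConfigurationError("n_genes, n_subjects, samples_per_subject must be positive")
        if self.n_informative < 0 or self.n_redundancy_blocks < 0 or self.block_size < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_informative + self.n_redundancy_blocks * self.block_size > self.n_genes:
            raise ConfigurationError(
                "n_informative + n_redundancy_blocks * block_size exceeds n_genes"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.subject_effect_sd < 0:
            raise ConfigurationError("subject_effect_sd must be >= 0")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigurationError("block_correlation must be in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must be in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of one synthetic dataset.

    ``effect_sizes`` maps each informative gene to its signed class
    shift on the log2 scale (affected minus control).
    """

    informative_genes: tuple[str, ...]
    redundancy_blocks: tuple[tuple[str, ...], ...] = ()
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flat = [g for b in self.redundancy_blocks for g in b]
        if len(flat) != len(set(flat)):
            raise ValueError("redundancy blocks must be disjoint")

    @property
    def background_free(self) -> set[str]:
        """Genes carrying any planted signal (informative or block member)."""
        return set(self.informative_genes) | {g for b in self.redundancy_blocks for g in b}


def validate_dataset(expression: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Check the expression-matrix and annotation invariants.

    Expression: genes x samples, finite, unique axes. Annotation: one row
    per sample with ``sample_id``, binary ``class_label``, ``subject_id``,
    ``stratum``; both classes non-empty.
    """
    if expression.index.has_duplicates or expression.columns.has_duplicates:
        raise ValueError("gene and sample axes must be unique")
    if not np.isfinite(expression.to_numpy()).all():
        raise ValueError("expression values must be finite")
    required = {"sample_id", "class_label", "subject_id", "stratum"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    ann = annotation.set_index("sample_id")
    missing = set(expression.columns) - set(ann.index)
    if missing:
        raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
    classes = set(ann.loc[list(expression.columns), "class_label"])
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {sorted(classes)}")


def _block_weight(rho: float, subject_sd: float, noise_sd: float) -> float:
    # corr(two members) = w^2 / (w^2 + subject_sd^2 + noise_sd^2)
    resid_var = subject_sd**2 + noise_sd**2
    return float(np.sqrt(rho / (1.0 - rho) * resid_var))


def generate_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns
    -------
    expression : DataFrame, genes x samples (log2 units)
    annotation : DataFrame with sample_id, class_label, subject_id, stratum
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_subjects * config.samples_per_subject
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]

    # subject-level design: class assigned per subject, samples = strata
    n_affected = int(round(config.n_subjects * config.class_balance))
    n_affected = min(max(n_affected, 1), config.n_subjects - 1)
    subject_class = np.array([AFFECTED] * n_affected + [CONTROL] * (config.n_subjects - n_affected))
    rng.shuffle(subject_class)

    subjects = [f"subj{i:03d}" for i in range(config.n_subjects)]
    rows = []
    for i, subj in enumerate(subjects):
        for r in range(config.samples_per_subject):
            rows.append(
                {
                    "sample_id": f"{subj}_r{r + 1}",
                    "class_label": subject_class[i],
                    "subject_id": subj,
                    "stratum": f"region_{r + 1}",
                }
            )
    annotation = pd.DataFrame(rows)
    affected_mask = (annotation["class_label"] == AFFECTED).to_numpy()
    subject_of_sample = np.repeat(np.arange(config.n_subjects), config.samples_per_subject)

    # role assignment over a shuffled gene order, so planted genes are not
    # clustered at the top of the matrix
    order = rng.permutation(config.n_genes)
    informative_idx = order[: config.n_informative]
    block_idx = [
        order[
            config.n_informative + b * config.block_size :
            config.n_informative + (b + 1) * config.block_size
        ]
        for b in range(config.n_redundancy_blocks)
    ]

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    if config.subject_effect_sd > 0:
        u = rng.normal(0.0, config.subject_effect_sd, size=(config.n_genes, config.n_subjects))
        values += u[:, subject_of_sample]

    # alternate up-/down-regulation among informative genes
    shift = config.effect_size * config.noise_sd
    signs = np.where(np.arange(config.n_informative) % 2 == 0, 1.0, -1.0)
    effect_sizes: dict[str, float] = {}
    for j, gi in enumerate(informative_idx):
        values[gi, affected_mask] += signs[j] * shift
        effect_sizes[genes[gi]] = float(signs[j] * shift)

    w = _block_weight(config.block_correlation, config.subject_effect_sd, config.noise_sd)
    for idx in block_idx:
        latent = rng.normal(0.0, 1.0, size=n_samples)
        values[idx, :] += w * latent

    values += config.baseline
    expression = pd.DataFrame(values, index=genes, columns=annotation["sample_id"].to_list())

    truth = GroundTruth(
        informative_genes=tuple(genes[i] for i in informative_idx),
        redundancy_blocks=tuple(tuple(genes[i] for i in idx) for idx in block_idx),
        effect_sizes=effect_sizes,
    )
    return expression, annotation, truth


def generate_reference_lists(
    truth: GroundTruth,
    all_genes: list[str] | pd.Index,
    fraction: float = 0.8,
    n_fillers: int = 10,
    n_decoys: int = 1,
    decoy_size: int = 50,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Build reference gene lists for over-representation tests.

    One list ("informative") contains ``fraction`` of the planted
    informative genes plus ``n_fillers`` random background genes; each
    decoy list ("decoy_k") is drawn uniformly from background genes.
    """
    rng = np.random.default_rng(seed)
    all_genes = list(all_genes)
    background = sorted(set(all_genes) - truth.background_free)
    n_take = int(round(fraction * len(truth.informative_genes)))
    if n_fillers > len(background):
        raise ValueError("more fillers requested than background genes available")
    if decoy_size > len(background):
        raise ValueError("decoy list larger than the background gene universe")

    taken = list(rng.choice(list(truth.informative_genes), size=n_take, replace=False))
    fillers = list(rng.choice(background, size=n_fillers, replace=False))
    lists = {"informative": sorted(taken + fillers)}
    for k in range(n_decoys):
        lists[f"decoy_{k + 1}"] = sorted(rng.choice(background, size=decoy_size, replace=False))
    return lists


def add_duplicates(
    expression: pd.DataFrame,
    gene: str,
    n_copies: int,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Append near-exact copies of one gene (measurement-noise jitter only).

    Models fully redundant probes of a single transcript; used to probe
    how selection methods treat redundancy.
    """
    if gene not in expression.index:
        raise KeyError(gene)
    rng = np.random.default_rng(seed)
    base = expression.loc[gene].to_numpy()
    names = [f"{gene}_dup{k + 1}" for k in range(n_copies)]
    copies = pd.DataFrame(
        base[None, :] + rng.normal(0.0, jitter_sd, size=(n_copies, base.size)),
        index=names,
        columns=expression.columns,
    )
    return pd.concat([expression, copies]), names


def add_informative_gene(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    name: str,
    effect: float,
    noise_sd: float = 1.0,
    baseline: float = 7.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Append one extra class-shifted gene (affected minus control = ``effect``)."""
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("sample_id").loc[list(expression.columns)]
    affected = (ann["class_label"].to_numpy() == AFFECTED).astype(float)
    row = baseline + rng.normal(0.0, noise_sd, size=len(affected)) + effect * affected
    extra = pd.DataFrame([row], index=[name], columns=expression.columns)
    return pd.concat([expression, extra])


def add_synergy_pair(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    names: tuple[str, str] = ("SYNA", "SYNB"),
    separation: float = 1.0,
    shared_sd: float = 1.0,
    jitter_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[str, str]]:
    """Append a pair of genes separable only jointly.

    Both genes ride a common per-sample level with SD ``shared_sd`` (so
    each is marginally weak), while their *difference* encodes the class:
    affected samples have gene A above gene B by ``separation`` on
    average, control samples the reverse. The class is therefore read off
    from which of the two genes is larger.
    """
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("sample_id").loc[list(expression.columns)]
    sign = np.where(ann["class_label"].to_numpy() == AFFECTED, 1.0, -1.0)
    n = len(expression.columns)
    shared = rng.normal(0.0, shared_sd, size=n)
    base = float(expression.to_numpy().mean())
    a = base + shared + sign * separation / 2 + rng.normal(0.0, jitter_sd, size=n)
    b = base + shared - sign * separation / 2 + rng.normal(0.0, jitter_sd, size=n)
    pair = pd.DataFrame([a, b], index=list(names), columns=expression.columns)
    return pd.concat([expression, pair]), names


# ---------------------------------------------------------------------------
# on-disk formats: expression TSV, annotation TSV, ground-truth JSON

def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "informative_genes": list(truth.informative_genes),
        "redundancy_blocks": [list(b) for b in truth.redundancy_blocks],
        "effect_sizes": truth.effect_sizes,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        informative_genes=tuple(payload["informative_genes"]),
        redundancy_blocks=tuple(tuple(b) for b in payload["redundancy_blocks"]),
        effect_sizes=payload["effect_sizes"],
    )


def config_to_dict(config: SynthConfig) -> dict:
    return asdict(config)
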