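import numpy as np
import pandas as pd
import pytest

from biomarker_ga import synthetic_data


@pytest.fixture(scope="session")
def demo_dataset():
    """Moderate two-class dataset with planted markers and blocks."""
    cfg = synthetic_data.SynthConfig(
        n_genes=120,
        n_subjects=24,
        samples_per_subject=3,
        n_informative=10,
        effect_size=1.5,
        n_redundancy_blocks=2,
        block_size=4,
        block_correlation=0.8,
        subject_effect_sd=0.5,
        class_balance=0.5,
        seed=11,
    )
    expr, ann, truth = synthetic_data.generate_dataset(cfg)
    return cfg, expr, ann, truth


@pytest.fixture(scope="session")
def separable_dataset():
    """Tiny dataset where one gene separates the classes perfectly."""
    rng = np.random.default_rng(5)
    n = 40
    labels = np.array(["affected"] * 20 + ["control"] * 20)
    ann = pd.DataFrame(
        {
            "sample_id": [f"s{i:02d}" for i in range(n)],
            "class_label": labels,
            "subject_id": [f"p{i:02d}" for i in range(n)],
            "stratum": ["r1"] * n,
        }
    )
    values = rng.normal(7.0, 1.0, size=(30, n))
    values[0] = np.where(labels == "affected", 12.0, 2.0) + rng.normal(0, 0.1, n)
    genes = ["SEP"] + [f"N{i:03d}" for i in range(1, 30)]
    expr = pd.DataFrame(values, index=genes, columns=ann["sample_id"])
    return expr, ann
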