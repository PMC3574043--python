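import math

import numpy as np
import pandas as pd
import pytest

from biomarker_ga import preprocess as pp


def _toy_annotation(labels):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(labels))],
            "class_label": labels,
            "subject_id": [f"p{i}" for i in range(len(labels))],
            "stratum": ["r1"] * len(labels),
        }
    )


# ---------------------------------------------------------------------------
# probe aggregation

def test_aggregate_probes_mean_and_identity():
    probes = pd.DataFrame(
        [[1.0, 3.0], [3.0, 5.0], [2.0, 2.0]],
        index=["p1", "p2", "p3"],
        columns=["s0", "s1"],
    )
    mapping = pd.DataFrame(
        {"probe_id": ["p1", "p2", "p3"], "gene_symbol": ["G", "G", "H"]}
    )
    out = pp.aggregate_probes(probes, mapping)
    np.testing.assert_allclose(out.loc["G"], [2.0, 4.0])
    np.testing.assert_allclose(out.loc["H"], [2.0, 2.0])

    one_to_one = mapping.assign(gene_symbol=["A", "B", "C"])
    out2 = pp.aggregate_probes(probes, one_to_one)
    np.testing.assert_allclose(np.sort(out2.to_numpy(), axis=0), np.sort(probes.to_numpy(), axis=0))


def test_aggregate_probes_matches_per_gene_loop():
    rng = np.random.default_rng(0)
    probes = pd.DataFrame(
        rng.normal(size=(10, 6)), index=[f"p{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(6)],
    )
    genes = rng.choice(["A", "B", "C"], size=10)
    mapping = pd.DataFrame({"probe_id": probes.index, "gene_symbol": genes})
    out = pp.aggregate_probes(probes, mapping)
    for g in "ABC":
        members = [p for p, gg in zip(probes.index, genes) if gg == g]
        expected = probes.loc[members].to_numpy().mean(axis=0)
        np.testing.assert_allclose(out.loc[g].to_numpy(), expected, atol=1e-12)


def test_aggregate_probes_rejects_empty_mapping():
    probes = pd.DataFrame([[1.0]], index=["p1"], columns=["s0"])
    with pytest.raises(ValueError):
        pp.aggregate_probes(probes, pd.DataFrame(columns=["probe_id", "gene_symbol"]))


# ---------------------------------------------------------------------------
# Welch + BH filter

def _welch_by_hand(a, b):
    """Textbook Welch t-test, written independently of scipy."""
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, p


def _bh_by_hand(pvals):
    """Step-up BH q-values, written independently of statsmodels."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


def test_welch_and_bh_match_hand_computation():
    rng = np.random.default_rng(1)
    n_genes = 50
    labels = ["affected"] * 12 + ["control"] * 9
    ann = _toy_annotation(labels)
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, len(labels))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=ann["sample_id"],
    )
    result = pp.welch_fdr_filter(expr, ann)
    aff = np.array(labels) == "affected"
    hand_p = []
    for i in range(n_genes):
        t, p = _welch_by_hand(expr.iloc[i].to_numpy()[aff], expr.iloc[i].to_numpy()[~aff])
        hand_p.append(p)
        assert result["t"].iloc[i] == pytest.approx(t, abs=1e-10)
        assert result["p"].iloc[i] == pytest.approx(p, abs=1e-10)
    np.testing.assert_allclose(result["q"].to_numpy(), _bh_by_hand(np.array(hand_p)), atol=1e-10)


def test_constant_gene_gets_p_one():
    labels = ["affected"] * 4 + ["control"] * 4
    ann = _toy_annotation(labels)
    expr = pd.DataFrame(
        [[5.0] * 8, [1, 2, 3, 4, 1, 2, 3, 4]],
        index=["flat", "varies"],
        columns=ann["sample_id"],
    )
    result = pp.welch_fdr_filter(expr, ann, fdr_cutoff=0.1)
    assert result.loc["flat", "p"] == 1.0
    assert not result.loc["flat", "retained"]


def test_cutoff_one_retains_everything(demo_dataset):
    _, expr, ann, _ = demo_dataset
    result = pp.welch_fdr_filter(expr, ann, fdr_cutoff=1.0)
    assert result["retained"].all()


# ---------------------------------------------------------------------------
# fold-change ranking

def _fc_frame(fcs, qs=None):
    genes = [f"g{i}" for i in range(len(fcs))]
    return pd.DataFrame(
        {
            "t": 0.0,
            "p": 0.01,
            "q": qs if qs is not None else 0.01,
            "fold_change": fcs,
            "retained": True,
            "rank": np.nan,
        },
        index=genes,
    )


def _matrix_for(frame):
    return pd.DataFrame(
        np.zeros((len(frame), 2)), index=frame.index, columns=["s0", "s1"]
    )


def test_absolute_fold_change_ordering():
    """A strongly down-regulated gene outranks a weaker up-regulated one."""
    frame = _fc_frame([0.9, -0.96, 0.04])
    ranked, reduced, out = pp.rank_by_fold_change(frame, _matrix_for(frame), top_k=2)
    assert ranked == ["g1", "g0"]
    assert list(reduced.index) == ranked
    assert out.loc["g1", "rank"] == 1 and np.isnan(out.loc["g2", "rank"])


def test_signed_ordering_flag():
    frame = _fc_frame([0.9, -0.96, 0.04])
    ranked, _, _ = pp.rank_by_fold_change(frame, _matrix_for(frame), top_k=3, signed=True)
    assert ranked == ["g0", "g2", "g1"]


def test_topk_beyond_pool_is_permutation():
    frame = _fc_frame(list(np.linspace(-1, 1, 7)))
    ranked, _, _ = pp.rank_by_fold_change(frame, _matrix_for(frame), top_k=100)
    assert sorted(ranked) == sorted(frame.index)


def test_ties_break_by_q_then_symbol():
    frame = _fc_frame([0.5, -0.5, 0.5], qs=[0.04, 0.02, 0.02])
    ranked, _, _ = pp.rank_by_fold_change(frame, _matrix_for(frame), top_k=3)
    assert ranked == ["g1", "g2", "g0"]


def test_empty_filter_raises():
    frame = _fc_frame([0.5])
    frame["retained"] = False
    with pytest.raises(pp.EmptyFilterError):
        pp.rank_by_fold_change(frame, _matrix_for(frame))


def test_filter_then_rank_idempotent(demo_dataset):
    """Re-filtering the reduced matrix at cutoff 1.0 preserves the order."""
    _, expr, ann, _ = demo_dataset
    first = pp.welch_fdr_filter(expr, ann, fdr_cutoff=0.2)
    ranked, reduced, _ = pp.rank_by_fold_change(first, expr, top_k=50)
    second = pp.welch_fdr_filter(reduced, ann, fdr_cutoff=1.0)
    ranked2, _, _ = pp.rank_by_fold_change(second, reduced, top_k=50)
    assert ranked2 == ranked


# ---------------------------------------------------------------------------
# grouped folds

def _grouped_annotation(n_subjects, samples_per_subject, n_affected, n_strata=None):
    n_strata = n_strata or samples_per_subject
    rows = []
    for i in range(n_subjects):
        cls = "affected" if i < n_affected else "control"
        for r in range(samples_per_subject):
            rows.append(
                {
                    "sample_id": f"p{i:02d}_r{r}",
                    "class_label": cls,
                    "subject_id": f"p{i:02d}",
                    "stratum": f"r{r % n_strata}",
                }
            )
    return pd.DataFrame(rows)


def test_six_subjects_three_folds():
    ann = _grouped_annotation(6, 2, 3)
    plan = pp.make_grouped_folds(ann, n_folds=3, seed=0)
    for (train, test), subjects in zip(plan.folds, plan.test_subjects):
        assert len(subjects) == 2
        assert len(test) == 4 and len(train) == 8


def test_no_subject_straddles_any_fold():
    ann = _grouped_annotation(10, 3, 5)
    subj = ann.set_index("sample_id")["subject_id"]
    for seed in range(20):
        plan = pp.make_grouped_folds(ann, n_folds=3, seed=seed)
        all_test = []
        for train, test in plan.folds:
            assert not set(subj.loc[list(train)]) & set(subj.loc[list(test)])
            all_test.extend(test)
        assert sorted(all_test) == sorted(ann["sample_id"])


def test_balanced_thirty_subjects():
    ann = _grouped_annotation(30, 2, 15)
    plan = pp.make_grouped_folds(ann, n_folds=3, seed=1)
    cls = ann.drop_duplicates("subject_id").set_index("subject_id")["class_label"]
    for subjects in plan.test_subjects:
        counts = cls.loc[list(subjects)].value_counts()
        assert counts["affected"] == 5 and counts["control"] == 5


def test_too_few_subjects_rejected():
    ann = _grouped_annotation(4, 2, 2)
    with pytest.raises(ValueError):
        pp.make_grouped_folds(ann, n_folds=3, seed=0)


def test_foldplan_json_round_trip(tmp_path):
    ann = _grouped_annotation(9, 2, 4)
    plan = pp.make_grouped_folds(ann, n_folds=3, seed=3)
    plan.to_json(tmp_path / "folds.json")
    back = pp.FoldPlan.from_json(tmp_path / "folds.json")
    assert back == plan
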