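"""Ligand-receptor permutation scoring, networks and stratification."""

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import stromascape as ss
from stromascape.crosstalk import InteractionResult, LRPair


def _adata(X, genes, obs=None):
    n = len(X)
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n)])
    return ad.AnnData(X=np.asarray(X, dtype=float), obs=obs,
                      var=pd.DataFrame(index=genes))


@pytest.fixture(scope="module")
def toy_clusters():
    rng = np.random.default_rng(0)
    X = rng.gamma(2, 1, size=(60, 6))
    X[:, 3] = 0.0  # ligand L0 absent everywhere
    genes = ["La", "Ra", "Rb", "L0", "G1", "G2"]
    labels = pd.Series(["send"] * 30 + ["recv"] * 30,
                       index=[f"c{i}" for i in range(60)])
    return _adata(X, genes), labels


def test_absent_ligand_scores_zero_p_one(toy_clusters):
    adata, labels = toy_clusters
    res = ss.interaction_score(
        adata, labels, LRPair("p", "L0", ("Ra",)), "send", "recv",
        n_perm=100, seed=1,
    )
    assert res.score == 0.0
    assert res.p_value == 1.0


def test_missing_gene_flagged(toy_clusters):
    adata, labels = toy_clusters
    res = ss.interaction_score(
        adata, labels, LRPair("p", "NOPE", ("Ra",)), "send", "recv",
        n_perm=100, seed=1,
    )
    assert (res.score, res.p_value, res.note) == (0.0, 1.0, "gene absent")


def test_permutation_p_never_zero(toy_clusters):
    adata, labels = toy_clusters
    strong = adata.copy()
    X = np.array(strong.X)
    X[:30, 0] += 100  # overwhelming ligand signal in senders
    strong.X = X
    res = ss.interaction_score(
        strong, labels, LRPair("p", "La", ("Ra",)), "send", "recv",
        n_perm=200, seed=2,
    )
    assert res.p_value >= 1.0 / 201


def test_score_uses_subunit_minimum(toy_clusters):
    adata, labels = toy_clusters
    X = np.array(adata.X)
    recv = labels.to_numpy() == "recv"
    send = labels.to_numpy() == "send"
    expected = X[send, 0].mean() * min(X[recv, 1].mean(), X[recv, 2].mean())
    res = ss.interaction_score(
        adata, labels, LRPair("p", "La", ("Ra", "Rb")), "send", "recv",
        n_perm=50, seed=3,
    )
    assert res.score == pytest.approx(expected)


def test_score_invariant_to_receiver_cell_order(toy_clusters):
    adata, labels = toy_clusters
    perm = np.r_[np.arange(30), 30 + np.random.default_rng(4).permutation(30)]
    res1 = ss.interaction_score(adata, labels, LRPair("p", "La", ("Ra",)),
                                "send", "recv", n_perm=100, seed=5)
    res2 = ss.interaction_score(adata[perm].copy(), labels.iloc[perm],
                                LRPair("p", "La", ("Ra",)),
                                "send", "recv", n_perm=100, seed=5)
    assert res1.score == pytest.approx(res2.score)


def test_small_cluster_rejected(toy_clusters):
    adata, labels = toy_clusters
    tiny = labels.copy()
    tiny.iloc[:55] = "send"
    tiny.iloc[55:] = "recv"
    with pytest.raises(ValueError, match=">= 10 cells"):
        ss.interaction_score(adata, tiny, LRPair("p", "La", ("Ra",)),
                             "send", "recv")


def _result(pair_id, sender, receiver, score, p):
    return InteractionResult(LRPair(pair_id, "L", ("R",)), sender, receiver, score, p)


def test_build_network_counting():
    res = [
        _result("a", "f", "e", 2.0, 0.01),
        _result("b", "f", "e", 3.0, 0.20),  # not significant
        _result("c", "e", "f", 1.0, 0.04),
    ]
    net = ss.build_network(res, alpha=0.05)
    assert net.counts.loc["f", "e"] == 1
    assert net.strengths.loc["f", "e"] == 2.0
    assert net.counts.loc["e", "f"] == 1
    # adding one more significant pair increments count and strength
    net2 = ss.build_network(res + [_result("d", "f", "e", 5.0, 0.001)], alpha=0.05)
    assert net2.counts.loc["f", "e"] == 2
    assert net2.strengths.loc["f", "e"] == 7.0
    # strength >= count x smallest significant score on the edge
    assert net2.strengths.loc["f", "e"] >= net2.counts.loc["f", "e"] * 2.0


def test_build_network_empty_and_zero_invariant():
    net = ss.build_network([_result("a", "f", "e", 2.0, 0.5)], alpha=0.05)
    assert (net.counts.to_numpy() == 0).all()
    assert (net.strengths.to_numpy() == 0).all()
    net.check()


def test_diff_network_antisymmetry():
    a = ss.build_network([_result("a", "f", "e", 2.0, 0.01)], alpha=0.05,
                         clusters=["f", "e"])
    b = ss.build_network([_result("b", "e", "f", 1.0, 0.01)], alpha=0.05,
                         clusters=["f", "e"])
    d_ab = ss.diff_network(a, b)
    d_ba = ss.diff_network(b, a)
    assert (d_ab["counts"] + d_ba["counts"]).to_numpy().sum() == 0
    assert np.allclose(d_ab["strengths"].to_numpy(), -d_ba["strengths"].to_numpy())
    # identical networks difference is zero
    assert (ss.diff_network(a, a)["counts"].to_numpy() == 0).all()
    with pytest.raises(ValueError, match="universe"):
        ss.diff_network(a, ss.build_network([], clusters=["x", "y"]))


def test_malignant_vs_nonmalignant_differential_is_positive():
    """A planted fibroblast->epithelial axis in malignant samples yields a
    positive malignant-minus-non-malignant delta on that edge."""
    axis = ss.LrAxisSpec(ligand_gene="G00050", receptor_genes=("G00060",), effect=4.0)
    cfg = ss.SyntheticConfig(n_samples=6, cells_per_sample=250, n_genes=500,
                             base_mean=0.5, seed=31, lr_axis=axis)
    adata, _ = ss.generate_cohort(cfg)
    norm = ss.normalize_log(adata)
    pairs = [ss.LRPair("planted", "G00050", ("G00060",))]
    nets = {}
    for cond in ("malignant", "non_malignant"):
        sub = norm[(norm.obs["condition"] == cond).to_numpy()]
        res = ss.score_all_triples(sub, sub.obs["cell_type"], pairs,
                                   senders=["fibroblast_ECM"],
                                   receivers=["epithelial"],
                                   n_perm=500, seed=32)
        nets[cond] = ss.build_network(
            res, clusters=["fibroblast_ECM", "epithelial"])
    diff = ss.diff_network(nets["malignant"], nets["non_malignant"])
    assert diff["counts"].loc["fibroblast_ECM", "epithelial"] > 0
    assert diff["strengths"].loc["fibroblast_ECM", "epithelial"] > 0


def test_stratify_by_sender_ligand_oracle():
    """Per-sample value equals the hand-summed sender-type counts."""
    genes = ["POSTN", "OTHER"]
    counts = np.array([
        [5, 1], [3, 1],   # s1 fibroblasts: POSTN sum 8
        [2, 1],           # s1 epithelial (excluded)
        [1, 1], [0, 1],   # s2 fibroblasts: 1
        [7, 1], [2, 1],   # s3 fibroblasts: 9
        [4, 1], [2, 1],   # s4 fibroblasts: 6
    ])
    obs = pd.DataFrame({
        "sample": ["s1", "s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
        "cell_type": ["fib", "fib", "epi", "fib", "fib", "fib", "fib", "fib", "fib"],
    }, index=[f"c{i}" for i in range(9)])
    adata = _adata(counts, genes, obs)
    vals, groups = ss.stratify_by_sender_ligand(adata, "POSTN", "fib", q=75)
    assert vals.to_dict() == {"s1": 8.0, "s2": 1.0, "s3": 9.0, "s4": 6.0}
    assert groups.to_dict() == {"s1": "low", "s2": "low", "s3": "high", "s4": "low"}


def test_stratify_eight_distinct_samples_two_high():
    rng = np.random.default_rng(7)
    obs = pd.DataFrame({
        "sample": np.repeat([f"s{i}" for i in range(8)], 3),
        "cell_type": ["fib"] * 24,
    }, index=[f"c{i}" for i in range(24)])
    counts = np.column_stack([np.repeat(np.arange(1, 9), 3), np.ones(24)])
    adata = _adata(counts, ["L", "O"], obs)
    _, groups = ss.stratify_by_sender_ligand(adata, "L", "fib", q=75)
    assert (groups == "high").sum() == 2


def test_stratify_missing_sender_type_warns_zero():
    obs = pd.DataFrame({
        "sample": ["s1", "s2", "s3", "s4"],
        "cell_type": ["fib", "fib", "fib", "epi"],
    }, index=[f"c{i}" for i in range(4)])
    adata = _adata(np.ones((4, 2)), ["L", "O"], obs)
    with pytest.warns(UserWarning, match="no 'fib' cells"):
        vals, _ = ss.stratify_by_sender_ligand(adata, "L", "fib", q=75)
    assert vals["s4"] == 0.0
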