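"""Pseudobulk aggregation, differential expression and enrichment.

Raw counts of a chosen cell type are summed per sample into a pseudobulk
matrix; lowly-covered genes (total count <= 1, or detected in fewer than
two samples) are excluded; and two sample groups are compared with an
unequal-variance two-sample test on log2(CPM + 1), with fold changes
log2((mean CPM_a + 1) / (mean CPM_b + 1)).  A gene is flagged as a DEG
when |log2 fold change| >= 1 and P < 0.05.  Preranked gene-set
enrichment uses the weighted Kolmogorov-Smirnov running sum with a
random-gene-set null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "aggregate_pseudobulk",
    "filter_pseudobulk_genes",
    "de_test",
    "preranked_enrichment",
    "EnrichmentResult",
]

DEG_LFC_MIN = 1.0
DEG_P_MAX = 0.05


def aggregate_pseudobulk(
    adata_counts: ad.AnnData,
    cell_type: str,
    sample_key: str = "sample",
    type_key: str = "cell_type",
) -> pd.DataFrame:
    """Sum raw counts of ``cell_type`` cells per sample.

    Returns a samples x genes integer DataFrame; samples without any
    subset cells are dropped with a warning.  Requires subset cells in
    at least two samples.
    """
    X = adata_counts.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X)
    samples = adata_counts.obs[sample_key].astype(str)
    is_type = (adata_counts.obs[type_key].astype(str) == cell_type).to_numpy()

    rows = {}
    for s in dict.fromkeys(samples):
        mask = (samples == s).to_numpy() & is_type
        if not mask.any():
            warnings.warn(f"sample {s} has no {cell_type!r} cells; row dropped")
            continue
        rows[s] = X[mask].sum(axis=0)
    if len(rows) < 2:
        raise ValueError(f"{cell_type!r} cells present in fewer than two samples")
    return pd.DataFrame(rows, index=adata_counts.var_names).T.astype(np.int64)


def filter_pseudobulk_genes(pb: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with total count >= 2 detected in >= 2 samples."""
    total = pb.sum(axis=0)
    detected = (pb > 0).sum(axis=0)
    return pb.loc[:, (total >= 2) & (detected >= 2)]


def de_test(
    pb: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Welch test on log2(CPM+1) with pseudocount-1 fold changes.

    ``groups`` maps sample -> label; samples of ``group_a`` are the
    numerator.  Returns a DataFrame with ``log2_fc``, ``p_value``, a
    Benjamini-Hochberg ``padj`` column (informational) and ``deg_flag``
    per the |log2FC| >= 1 and P < 0.05 rule.
    """
    groups = pd.Series(groups).astype(str)
    a_samples = groups.index[groups == group_a]
    b_samples = groups.index[groups == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs >= 2 samples")

    cpm = pb.div(pb.sum(axis=1), axis=0) * 1e6
    log2cpm = np.log2(cpm + 1.0)
    mean_a = cpm.loc[a_samples].mean(axis=0)
    mean_b = cpm.loc[b_samples].mean(axis=0)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.ttest_ind(
            log2cpm.loc[a_samples], log2cpm.loc[b_samples], equal_var=False, axis=0
        )
    p = pd.Series(p, index=pb.columns)
    finite = p.notna()
    padj = pd.Series(np.nan, index=pb.columns)
    if finite.any():
        padj[finite] = stats.false_discovery_control(p[finite].to_numpy())
    deg = (log2_fc.abs() >= DEG_LFC_MIN) & (p < DEG_P_MAX)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "padj": padj,
            "deg_flag": deg.fillna(False),
        }
    )


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_set_in_ranking: int


def _enrichment_score(
    in_set: np.ndarray, weights: np.ndarray, sum_w: float
) -> float:
    """Signed max deviation of the weighted KS running sum; in [-1, 1]."""
    n = len(in_set)
    n_miss = n - int(in_set.sum())
    p_hit = np.cumsum(np.where(in_set, weights, 0.0)) / sum_w
    p_miss = np.cumsum(~in_set) / max(n_miss, 1)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def preranked_enrichment(
    ranking: pd.Series,
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted KS preranked enrichment with a gene-permutation null.

    ``ranking`` maps gene -> ranking metric (e.g. log2 fold change) and
    is sorted descending internally; hit increments are |metric|^weight.
    The null redraws same-size gene sets uniformly from the ranking;
    NES = ES / mean |null ES of the same sign| and
    p = (1 + #{same-sign null ES at least as extreme}) / (1 + #same-sign null).
    """
    ranking = pd.Series(ranking).astype(float).sort_values(ascending=False, kind="mergesort")
    genes = ranking.index
    set_genes = {g for g in gene_set if g in genes}
    if not set_genes:
        raise ValueError("no gene-set genes present in the ranking")
    m = len(set_genes)
    n = len(genes)
    in_set = np.asarray(genes.isin(list(set_genes)))
    weights = np.abs(ranking.to_numpy()) ** weight
    weights = np.maximum(weights, 1e-12)

    sum_w = weights[in_set].sum()
    es = _enrichment_score(in_set, weights, sum_w)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        perm = np.zeros(n, dtype=bool)
        perm[idx] = True
        null[i] = _enrichment_score(perm, weights, weights[perm].sum())

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        nes, p = np.sign(es), 1.0 / (1.0 + n_perm)
    else:
        nes = es / np.abs(same).mean()
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
    return EnrichmentResult(es=es, nes=float(nes), p_value=float(p), n_set_in_ranking=m)
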