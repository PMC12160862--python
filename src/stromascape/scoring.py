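"""Gene-set scoring of cells and subjects, and score-based stratification.

``module_score`` follows the expression-bin control-gene convention used
for per-cell signature scoring in single-cell toolkits: the mean
expression of the set genes minus the mean of control genes drawn from
the same average-expression bins, so the score is centered at zero for a
random set.  ``rank_set_score`` is a single-sample, rank-based set score
for bulk profiles (a transparent stand-in for sample-wise enrichment
methods): the centered mean rank of the set genes, invariant to monotone
transformations of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["ScoreParams", "module_score", "rank_set_score", "stratify_by_score"]


@dataclass(frozen=True)
class ScoreParams:
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")


def module_score(
    adata_norm: ad.AnnData,
    gene_set: Iterable[str],
    params: ScoreParams = ScoreParams(),
) -> pd.Series:
    """Per-cell module score against expression-bin-matched controls.

    Genes are binned into ``n_bins`` equal-occupancy bins of average
    expression; for each set gene, up to ``n_ctrl_per_gene`` control
    genes are sampled without replacement from its bin (set genes
    excluded).  Score = mean expression over set genes minus mean over
    the pooled control genes.
    """
    X = adata_norm.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    genes = pd.Index(adata_norm.var_names)
    set_genes = [g for g in dict.fromkeys(gene_set) if g in genes]
    if not set_genes:
        raise ValueError("no gene-set genes present in the matrix")

    avg = X.mean(axis=0)
    order = pd.Series(avg, index=genes).rank(method="first").astype(int) - 1
    bins = (order * params.n_bins // len(genes)).clip(upper=params.n_bins - 1)

    rng = np.random.default_rng(params.seed)
    set_idx = genes.get_indexer(set_genes)
    in_set = np.zeros(len(genes), dtype=bool)
    in_set[set_idx] = True

    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero((bins.to_numpy() == bins.iloc[gi]) & ~in_set)
        if len(pool) == 0:
            continue
        take = min(params.n_ctrl_per_gene, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        # every bin gene is a set gene; controls degenerate to the set itself
        ctrl = set(set_idx.tolist())
    ctrl_idx = np.array(sorted(ctrl))

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata_norm.obs_names, name="module_score")


def rank_set_score(profile: pd.Series, gene_set: Iterable[str]) -> float:
    """Centered mean-rank score of a gene set in one subject's profile.

    Ranks (average method for ties) run 1..G; the score is the set's
    mean rank centered at (G+1)/2 and scaled by (G-1)/2, so it lies in
    [-1, 1], has expectation 0 for random sets, and is invariant to any
    strictly increasing transformation of the profile.
    """
    profile = pd.Series(profile).astype(float)
    set_genes = [g for g in dict.fromkeys(gene_set) if g in profile.index]
    if not set_genes:
        raise ValueError("profile covers no gene-set genes")
    g = len(profile)
    if g < 2:
        return 0.0
    ranks = profile.rank(method="average")
    return float((ranks.loc[set_genes].mean() - (g + 1) / 2) / ((g - 1) / 2))


def stratify_by_score(
    scores: pd.Series | Sequence[float],
    rule: str = "median",
    q: float | None = None,
) -> pd.Series:
    """Split subjects into "high" (strictly above cutoff) and "low".

    ``rule`` is ``"median"`` or ``"percentile"`` (with ``q`` in (0,100)).
    Ties at the cutoff go to "low".  All-equal scores raise a degenerate
    cutoff error.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 4:
        raise ValueError("need >= 4 subjects to stratify")
    if rule == "median":
        cutoff = float(np.median(s))
    elif rule == "percentile":
        if q is None or not 0 < q < 100:
            raise ValueError("percentile rule needs q in (0, 100)")
        cutoff = float(np.percentile(s, q))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if s.nunique() == 1:
        raise ValueError("degenerate cutoff: all scores identical")
    labels = np.where(s > cutoff, "high", "low")
    return pd.Series(labels, index=s.index, name="group")
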