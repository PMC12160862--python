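"""Per-sample NMF program extraction and meta-program discovery.

Each sample's epithelial expression matrix is factorized with NMF over a
sweep of ranks (K = 3..10); every factor is reduced to its 50 top-loading
genes, yielding a pool of candidate *gene programs*.  Programs that are
stable within a sample (recur across K values), recurrent across samples,
and non-redundant are retained and hierarchically clustered on Jaccard
distance of their gene sets.  Each sufficiently large cluster becomes a
*meta-program* (MP) with a 50-gene consensus list — a recurrent, stable
expression pattern shared across the cohort.

Expression is made non-negative for NMF by centering each gene within the
sample and clipping negatives to zero, so factors capture above-average
co-expression rather than absolute abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

__all__ = [
    "GeneProgram",
    "RobustnessParams",
    "MetaProgram",
    "fit_sample_nmf",
    "select_robust_programs",
    "jaccard_index",
    "cluster_meta_programs",
    "consensus_gene_list",
    "discover_meta_programs",
]

N_TOP_GENES = 50


@dataclass(frozen=True)
class GeneProgram:
    """One NMF factor reduced to its 50 top-loading genes."""

    sample_id: str
    rank_k: int
    factor_index: int
    top_genes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.top_genes)) != len(self.top_genes):
            raise ValueError("top_genes must be distinct")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if any(a < b for a, b in zip(self.weights, self.weights[1:])):
            raise ValueError("weights must be sorted non-increasing")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.top_genes)


@dataclass(frozen=True)
class RobustnessParams:
    """Thresholds (in genes, out of 50) for program selection.

    ``intra_min_overlap``: minimum overlap with a program of a different
    K in the same sample (stability).  ``inter_min_overlap``: minimum
    overlap with programs of other samples (recurrence), required for at
    least ``min_samples_recurrent - 1`` other samples.
    ``intra_redundancy_cap``: two retained in-sample programs sharing
    more than ``50 - cap`` genes are considered redundant and only the
    more recurrent one is kept.
    """

    intra_min_overlap: int = 35
    intra_redundancy_cap: int = 10
    inter_min_overlap: int = 10
    min_samples_recurrent: int = 2

    def __post_init__(self) -> None:
        for v in (
            self.intra_min_overlap,
            self.intra_redundancy_cap,
            self.inter_min_overlap,
        ):
            if not 0 <= v <= N_TOP_GENES:
                raise ValueError("overlap thresholds must be in [0, 50]")


@dataclass(frozen=True)
class MetaProgram:
    mp_id: str
    member_programs: tuple[GeneProgram, ...]
    consensus_genes: tuple[str, ...]
    n_samples: int


def _nonneg(X: np.ndarray) -> np.ndarray:
    """Center each gene (column) and clip negatives to zero."""
    return np.clip(X - X.mean(axis=0, keepdims=True), 0.0, None)


def fit_sample_nmf(
    X: np.ndarray | ad.AnnData,
    gene_names: Sequence[str] | None = None,
    sample_id: str = "sample",
    k_min: int = 3,
    k_max: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> list[GeneProgram]:
    """Extract K programs for every K in ``[k_min, k_max]`` from one sample.

    ``X`` is a cells x genes normalized matrix (or an AnnData, in which
    case ``gene_names`` defaults to its var_names).  Returns
    ``k_min + ... + k_max`` programs, each carrying its 50 top genes
    ordered by non-increasing loading (ties broken by gene name).
    """
    if isinstance(X, ad.AnnData):
        gene_names = list(X.var_names) if gene_names is None else gene_names
        X = X.X
    from scipy import sparse as _sp

    if _sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=np.float64)
    if gene_names is None:
        raise ValueError("gene_names required with an array input")
    if X.shape[0] < k_max:
        raise ValueError(f"sample needs >= {k_max} cells for NMF up to K={k_max}")
    Xn = _nonneg(X)
    if not Xn.any():
        raise ValueError("degenerate all-zero matrix after non-negativity step")
    gene_names = np.asarray(gene_names)

    programs: list[GeneProgram] = []
    for k in range(k_min, k_max + 1):
        model = NMF(
            n_components=k,
            init="random",
            random_state=(seed * 131 + k) % (2**31),
            max_iter=max_iter,
            tol=tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at capped iters
            model.fit(Xn)
        H = model.components_  # k x genes
        for f in range(k):
            load = H[f]
            order = np.lexsort((gene_names, -load))[:N_TOP_GENES]
            programs.append(
                GeneProgram(
                    sample_id=sample_id,
                    rank_k=k,
                    factor_index=f,
                    top_genes=tuple(gene_names[order]),
                    weights=tuple(float(load[i]) for i in order),
                )
            )
    return programs


def _overlap(a: GeneProgram, b: GeneProgram) -> int:
    return len(a.gene_set & b.gene_set)


def select_robust_programs(
    programs: Sequence[GeneProgram],
    params: RobustnessParams = RobustnessParams(),
) -> list[GeneProgram]:
    """Keep stable, recurrent, non-redundant programs.

    A program survives iff (a) it overlaps >= ``intra_min_overlap`` genes
    with some program of a *different* K in the same sample, and (b) its
    gene set overlaps >= ``inter_min_overlap`` genes with programs from
    at least ``min_samples_recurrent - 1`` other samples.  Near-duplicate
    retained programs within a sample (> ``50 - intra_redundancy_cap``
    shared genes) are collapsed to the one with the highest cross-sample
    recurrence, ties resolved toward lower K then lower factor index.
    """
    progs = list(programs)
    by_sample: dict[str, list[GeneProgram]] = {}
    for p in progs:
        by_sample.setdefault(p.sample_id, []).append(p)

    def recurrence(p: GeneProgram) -> int:
        other = {
            q.sample_id
            for q in progs
            if q.sample_id != p.sample_id and _overlap(p, q) >= params.inter_min_overlap
        }
        return len(other)

    rec = {id(p): recurrence(p) for p in progs}

    retained: list[GeneProgram] = []
    for p in progs:
        stable = any(
            q.rank_k != p.rank_k and _overlap(p, q) >= params.intra_min_overlap
            for q in by_sample[p.sample_id]
            if q is not p
        )
        if stable and rec[id(p)] >= params.min_samples_recurrent - 1:
            retained.append(p)

    # non-redundancy within sample
    cap = N_TOP_GENES - params.intra_redundancy_cap
    final: list[GeneProgram] = []
    for sample in sorted({p.sample_id for p in retained}):
        group = [p for p in retained if p.sample_id == sample]
        group.sort(key=lambda p: (-rec[id(p)], p.rank_k, p.factor_index))
        kept: list[GeneProgram] = []
        for p in group:
            if all(_overlap(p, q) <= cap for q in kept):
                kept.append(p)
        final.extend(sorted(kept, key=lambda p: (p.rank_k, p.factor_index)))
    return final


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """|a & b| / |a | b|, with 0 for two empty sets by convention."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def consensus_gene_list(members: Sequence[GeneProgram]) -> tuple[str, ...]:
    """Rank member genes by (frequency, mean loading, name); take top 50.

    If the member-gene union holds fewer than 50 genes the full union is
    returned with a warning.
    """
    if not members:
        raise ValueError("meta-program needs >= 1 member")
    freq: dict[str, int] = {}
    loads: dict[str, list[float]] = {}
    for p in members:
        for g, w in zip(p.top_genes, p.weights):
            freq[g] = freq.get(g, 0) + 1
            loads.setdefault(g, []).append(w)
    genes = sorted(
        freq, key=lambda g: (-freq[g], -float(np.mean(loads[g])), g)
    )
    if len(genes) < N_TOP_GENES:
        warnings.warn(
            f"member-gene union has only {len(genes)} genes; returning it all",
            stacklevel=2,
        )
        return tuple(genes)
    return tuple(genes[:N_TOP_GENES])


def cluster_meta_programs(
    programs: Sequence[GeneProgram],
    linkage: str = "average",
    min_cluster_size: int = 3,
    cut: float = 0.75,
    n_clusters: int | None = None,
    min_samples: int = 2,
) -> list[MetaProgram]:
    """Hierarchically cluster programs on 1 - Jaccard into meta-programs.

    The dendrogram is cut at distance ``cut`` (or into ``n_clusters``
    flat clusters when given); clusters smaller than
    ``min_cluster_size``, or drawing on fewer than ``min_samples``
    distinct samples (a meta-program is by definition recurrent across
    samples), are discarded.  MPs are ordered by decreasing member
    count and labelled MP1, MP2, ...
    """
    progs = list(programs)
    if len(progs) < 2:
        warnings.warn("need >= 2 programs to cluster; returning no meta-programs")
        return []
    n = len(progs)
    dist = np.zeros((n, n))
    sets = [p.gene_set for p in progs]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard_index(sets[i], sets[j])
            dist[i, j] = dist[j, i] = d
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")

    clusters: dict[int, list[GeneProgram]] = {}
    for lab, p in zip(labels, progs):
        clusters.setdefault(int(lab), []).append(p)
    kept = [
        ms
        for ms in clusters.values()
        if len(ms) >= min_cluster_size
        and len({p.sample_id for p in ms}) >= min_samples
    ]
    kept.sort(key=lambda ms: (-len(ms), ms[0].sample_id, ms[0].rank_k, ms[0].factor_index))

    mps = []
    for i, members in enumerate(kept, start=1):
        members = tuple(
            sorted(members, key=lambda p: (p.sample_id, p.rank_k, p.factor_index))
        )
        mps.append(
            MetaProgram(
                mp_id=f"MP{i}",
                member_programs=members,
                consensus_genes=consensus_gene_list(members),
                n_samples=len({p.sample_id for p in members}),
            )
        )
    return mps


def discover_meta_programs(
    adata_norm: ad.AnnData,
    sample_key: str = "sample",
    cell_type: str | None = "epithelial",
    type_key: str = "cell_type",
    genes: Sequence[str] | None = None,
    k_min: int = 3,
    k_max: int = 10,
    seed: int = 0,
    params: RobustnessParams = RobustnessParams(),
    min_cluster_size: int = 3,
    cut: float = 0.75,
    n_clusters: int | None = None,
    min_samples: int = 2,
    max_iter: int = 200,
) -> dict:
    """End-to-end meta-program discovery on a normalized cohort.

    Runs per-sample NMF on the (optionally cell-type-restricted,
    gene-restricted) matrix, selects robust programs and clusters them.
    Samples with fewer than ``k_max`` cells are skipped with a warning.
    Returns a dict with ``programs``, ``robust_programs`` and
    ``meta_programs``.
    """
    sub = adata_norm
    if cell_type is not None:
        sub = sub[sub.obs[type_key] == cell_type]
    if genes is not None:
        sub = sub[:, list(genes)]
    programs: list[GeneProgram] = []
    for sample in sub.obs[sample_key].astype(str).unique():
        block = sub[sub.obs[sample_key].astype(str) == sample]
        if block.n_obs < k_max:
            warnings.warn(f"sample {sample} has < {k_max} cells; skipped")
            continue
        programs.extend(
            fit_sample_nmf(
                block,
                sample_id=sample,
                k_min=k_min,
                k_max=k_max,
                seed=seed + hash_sample(sample),
                max_iter=max_iter,
            )
        )
    robust = select_robust_programs(programs, params)
    mps = cluster_meta_programs(
        robust,
        min_cluster_size=min_cluster_size,
        cut=cut,
        n_clusters=n_clusters,
        min_samples=min_samples,
    )
    return {"programs": programs, "robust_programs": robust, "meta_programs": mps}


def hash_sample(sample: str) -> int:
    """Stable small integer derived from a sample name (not ``hash``,
    which is salted per process)."""
    h = 0
    for ch in sample:
        h = (h * 31 + ord(ch)) % 100003
    return h
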