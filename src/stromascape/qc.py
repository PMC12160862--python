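"""Cell and sample quality control, depth normalization and HVG selection.

Filtering mirrors the standard tumor scRNA-seq recipe: cells are kept
when they show 300-8,000 detected genes, fewer than 40,000 UMIs, under
10% mitochondrial and under 1% hemoglobin counts; samples retaining
fewer than 500 cells are then dropped entirely.  Normalization scales
every cell to a common depth (10,000 by default) followed by log1p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

__all__ = ["QcThresholds", "QcReport", "qc_filter", "normalize_log", "select_hvg"]

# genes that start with "HB" but are not hemoglobins
HB_FALSE_PREFIXES = frozenset({"HBEGF", "HBS1L", "HBP1"})


def is_mito_gene(name: str) -> bool:
    return name.startswith("MT-")


def is_hemoglobin_gene(name: str) -> bool:
    return name.startswith("HB") and name not in HB_FALSE_PREFIXES


@dataclass(frozen=True)
class QcThresholds:
    min_genes: int = 300
    max_genes: int = 8000
    max_umi: int = 40000
    max_mito_pct: float = 10.0
    max_hb_pct: float = 1.0
    min_cells_per_sample: int = 500

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for p in (self.max_mito_pct, self.max_hb_pct):
            if not 0 <= p <= 100:
                raise ValueError("percentages must be in [0, 100]")


@dataclass
class QcReport:
    cells_in: int
    cells_removed_by_rule: dict[str, int] = field(default_factory=dict)
    samples_dropped: list[str] = field(default_factory=list)
    cells_out: int = 0

    def check(self) -> None:
        if self.cells_in != self.cells_out + sum(self.cells_removed_by_rule.values()):
            raise AssertionError("QC report does not balance")


def _dense_counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def qc_filter(
    adata: ad.AnnData,
    thr: QcThresholds = QcThresholds(),
    sample_key: str = "sample",
) -> tuple[ad.AnnData, QcReport]:
    """Filter cells by the QC rules, then drop under-sized samples.

    Each removed cell is attributed to the first rule it violates, in
    the order: too few genes, too many genes, UMI cap, mitochondrial
    percentage, hemoglobin percentage; surviving cells of samples with
    fewer than ``min_cells_per_sample`` cells are then removed under the
    ``sample_min_cells`` rule.  A "detected" gene has count >= 1.
    """
    if sample_key not in adata.obs:
        raise ValueError(f"annotation lacks {sample_key!r} column")
    X = _dense_counts(adata)
    genes = adata.var_names
    mito = np.array([is_mito_gene(g) for g in genes])
    hb = np.array([is_hemoglobin_gene(g) for g in genes])

    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = 100.0 * np.asarray(X[:, mito].sum(axis=1)).ravel() / np.maximum(total, 1)
        hb_pct = 100.0 * np.asarray(X[:, hb].sum(axis=1)).ravel() / np.maximum(total, 1)

    rules = [
        ("min_genes", n_detected < thr.min_genes),
        ("max_genes", n_detected > thr.max_genes),
        ("max_umi", total >= thr.max_umi),
        ("max_mito_pct", mito_pct >= thr.max_mito_pct),
        ("max_hb_pct", hb_pct >= thr.max_hb_pct),
    ]
    removed: dict[str, int] = {}
    already = np.zeros(adata.n_obs, dtype=bool)
    for name, bad in rules:
        hit = bad & ~already
        removed[name] = int(hit.sum())
        already |= hit
    keep = ~already

    samples = adata.obs[sample_key].astype(str)
    surviving = samples[keep].value_counts()
    dropped_samples = sorted(
        set(samples.unique()) - set(surviving[surviving >= thr.min_cells_per_sample].index)
    )
    small = keep & samples.isin(dropped_samples).to_numpy()
    removed["sample_min_cells"] = int(small.sum())
    keep &= ~small

    if not keep.any():
        raise ValueError("no cells survive QC")
    out = adata[keep].copy()
    report = QcReport(
        cells_in=adata.n_obs,
        cells_removed_by_rule=removed,
        samples_dropped=dropped_samples,
        cells_out=int(keep.sum()),
    )
    report.check()
    return out, report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` counts, then log1p."""
    total = np.asarray(_dense_counts(adata).sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError("all-zero cell encountered; run qc_filter first")
    out = adata.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["normalized"] = True
    return out


def select_hvg(adata_norm: ad.AnnData, n: int = 2000, n_bins: int = 20) -> pd.Index:
    """Top-``n`` highly variable genes by binned, z-scored dispersion.

    Per-gene dispersion (variance / mean of the normalized values) is
    z-scored within ``n_bins`` equal-occupancy mean-expression bins;
    genes are ranked by that score with ties broken by gene name.
    Constant genes are never selected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = adata_norm.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    df = pd.DataFrame({"mean": mean, "disp": disp}, index=adata_norm.var_names)
    # equal-occupancy bins on mean expression (rank-based, stable)
    order = df["mean"].rank(method="first").astype(int) - 1
    df["bin"] = (order * n_bins // len(df)).clip(upper=n_bins - 1)
    grp = df.groupby("bin")["disp"]
    mu = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    df["z"] = np.where(sd > 0, (df["disp"] - mu) / sd, 0.0)
    df = df[var > 0]  # a constant gene is never variable
    # rank by z descending, deterministic tie-break by gene name
    order = np.lexsort((df.index.to_numpy(), -df["z"].to_numpy()))
    return df.index[order][: min(n, len(df))]
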