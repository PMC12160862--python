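"""Readers and writers for the package's on-disk formats.

Cohorts travel as a 10x-style directory (matrix.mtx + features.tsv +
barcodes.tsv) with an annotation CSV and genome-map CSV alongside; gene
sets use the GMT convention (tab-separated: name, description, genes).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_gmt",
    "read_gmt",
    "write_genome_map",
    "read_genome_map",
]


def write_cohort(path: str | Path, adata: ad.AnnData, ground_truth=None) -> None:
    """Write counts as MTX (genes x cells) with TSV sidecars and CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(path / "matrix.mtx", X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        path / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(path / "annotation.csv")
    if {"chromosome", "chr_rank"} <= set(adata.var.columns):
        gmap = pd.DataFrame(
            {
                "gene": adata.var_names,
                "chromosome": adata.var["chromosome"].to_numpy(),
                "chr_rank": adata.var["chr_rank"].to_numpy(),
            }
        )
        write_genome_map(path / "genome_map.csv", gmap)
    if ground_truth is not None:
        payload = {
            "program_gene_sets": [list(s) for s in ground_truth.program_gene_sets],
            "malignant_cells": ground_truth.malignant[
                ground_truth.malignant
            ].index.tolist(),
            "sample_condition": ground_truth.sample_condition.to_dict(),
            "config": _config_dict(ground_truth.config),
        }
        (path / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def _config_dict(cfg) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, (list, tuple)):
            return [enc(x) for x in v]
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return {k: enc(v) for k, v in dataclasses.asdict(cfg).items()}


def read_cohort(path: str | Path) -> ad.AnnData:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    X = sparse.csr_matrix(spio.mmread(path / "matrix.mtx").T)
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.read_csv(path / "annotation.csv", index_col=0)
    obs = obs.loc[cells]
    var = pd.DataFrame(index=genes)
    gmap_file = path / "genome_map.csv"
    if gmap_file.exists():
        gmap = read_genome_map(gmap_file).set_index("gene")
        var["chromosome"] = gmap.loc[genes, "chromosome"].to_numpy()
        var["chr_rank"] = gmap.loc[genes, "chr_rank"].to_numpy()
    return ad.AnnData(X=X, obs=obs, var=var)


def write_gmt(path: str | Path, gene_sets: dict[str, list[str]]) -> None:
    lines = [
        "\t".join([name, name, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_genome_map(path: str | Path, genome: pd.DataFrame) -> None:
    genome[["gene", "chromosome", "chr_rank"]].to_csv(path, index=False)


def read_genome_map(path: str | Path) -> pd.DataFrame:
    gmap = pd.read_csv(path)
    missing = {"gene", "chromosome", "chr_rank"} - set(gmap.columns)
    if missing:
        raise ValueError(f"genome map lacks columns: {sorted(missing)}")
    return gmap
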