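"""Synthetic multi-sample single-cell cohorts with planted ground truth.

The generator emulates the structure of an integrated pancreatic-tumor
scRNA-seq cohort: several samples (tumor and non-malignant), each a mix of
epithelial cells, reference (normal) epithelial cells and fibroblast
subtypes.  Signal can be planted at three levels —

* shared expression *programs* (50-gene modules switched on in a fraction
  of epithelial cells of the samples where they are active),
* copy-number *segments* (multiplicative fold over a contiguous block of
  genome-ordered genes in an affected cell subset), and
* a *ligand-receptor axis* (a secreted ligand elevated in a sender cell
  type and its receptor subunits in a receiver type, in malignant samples
  only).

Counts are negative-binomial around a mean that composes a per-gene
baseline rate, a per-cell log-normal depth factor, and the planted
multiplicative effects, so every planted effect is recoverable as a ratio
of group means.  A fixed seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ProgramSpec",
    "CnvSegmentSpec",
    "LrAxisSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_genome_map",
    "generate_cohort",
    "plant_cnv_segments",
    "plant_lr_axis",
    "generate_survival",
]

EPITHELIAL = "epithelial"
REFERENCE = "reference"
FIB_ECM = "fibroblast_ECM"
FIB_OTHER = "fibroblast_other"

MEAN_LAYER = "mean"


@dataclass(frozen=True)
class ProgramSpec:
    """A planted 50-gene expression program.

    ``gene_ids`` are integer gene indices; the program multiplies the
    baseline rate of those genes by ``effect`` in the epithelial cells
    that are "on" (a Bernoulli(``fraction_cells_on``) draw per cell) in
    the samples listed in ``samples_active``.
    """

    gene_ids: tuple[int, ...]
    samples_active: tuple[int, ...]
    fraction_cells_on: float = 0.3
    effect: float = 4.0

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("program gene_ids must be distinct")
        if not 0 < self.fraction_cells_on <= 1:
            raise ValueError("fraction_cells_on must be in (0, 1]")
        if self.effect < 1:
            raise ValueError("program effect must be >= 1")


@dataclass(frozen=True)
class CnvSegmentSpec:
    """A copy-number segment over ``[start_gene_rank, end_gene_rank)``.

    Ranks are 0-based half-open gene-order indices *within* the named
    chromosome.  ``affected_cells`` names the cells carrying the event;
    ``None`` means the generator's default (all epithelial cells of
    malignant samples).  ``fold == 1`` is a no-op.
    """

    chromosome: str
    start_gene_rank: int
    end_gene_rank: int
    fold: float
    affected_cells: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if not 0 <= self.start_gene_rank < self.end_gene_rank:
            raise ValueError("need 0 <= start_gene_rank < end_gene_rank")


@dataclass(frozen=True)
class LrAxisSpec:
    """A ligand-receptor axis planted between two cell types.

    In malignant samples the ligand is elevated ``effect``-fold in
    ``sender_type`` cells and every receptor subunit ``effect``-fold in
    ``receiver_type`` cells.
    """

    ligand_gene: str
    receptor_genes: tuple[str, ...]
    sender_type: str = FIB_ECM
    receiver_type: str = EPITHELIAL
    effect: float = 4.0

    def __post_init__(self) -> None:
        if self.sender_type == self.receiver_type:
            raise ValueError("sender and receiver types must differ")
        if not 1 <= len(self.receptor_genes) <= 2:
            raise ValueError("receptor complex has one or two subunits")
        if self.effect < 1:
            raise ValueError("axis effect must be >= 1")


def _default_fractions() -> dict[str, float]:
    return {EPITHELIAL: 0.45, REFERENCE: 0.15, FIB_ECM: 0.2, FIB_OTHER: 0.2}


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort.

    Parameters
    ----------
    n_samples, cells_per_sample, n_genes
        Cohort dimensions.  Mitochondrial ("MT-") and hemoglobin ("HB")
        genes occupy the last ``n_mito_genes + n_hb_genes`` indices.
    base_mean
        Expected counts per gene per cell before per-gene variation
        (log-normal, ``gene_mean_sigma``) and planted effects.
    dispersion
        Negative-binomial overdispersion ``a`` with Var = mu + a * mu^2.
    malignant_fraction
        Fraction of samples labelled "malignant"; the remaining samples
        are "non_malignant" and contain no CNV / ligand-axis signal by
        default.
    mito_fraction, hb_fraction
        Expected fraction of total counts landing on MT- / HB genes, so
        QC filters on those fractions are exercised.
    """

    n_samples: int = 6
    cells_per_sample: int = 300
    n_genes: int = 2000
    base_mean: float = 0.5
    dispersion: float = 0.5
    programs: Sequence[ProgramSpec] = ()
    cnv_segments: Sequence[CnvSegmentSpec] = ()
    lr_axis: LrAxisSpec | None = None
    seed: int = 0
    malignant_fraction: float = 0.5
    cell_type_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    n_mito_genes: int = 13
    n_hb_genes: int = 6
    mito_fraction: float = 0.05
    hb_fraction: float = 0.005
    gene_mean_sigma: float = 0.5
    depth_sigma: float = 0.3
    n_chromosomes: int = 22
    allow_program_overlap: bool = False

    def validate(self) -> None:
        if self.n_samples < 1 or self.cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        n_regular = self.n_genes - self.n_mito_genes - self.n_hb_genes
        seen: set[int] = set()
        for prog in self.programs:
            ids = set(prog.gene_ids)
            if max(ids, default=-1) >= n_regular or min(ids, default=0) < 0:
                raise ValueError(
                    "program gene ids must index regular genes "
                    f"(0..{n_regular - 1})"
                )
            if not self.allow_program_overlap and seen & ids:
                raise ValueError(
                    "program gene sets overlap; set allow_program_overlap=True "
                    "to permit this"
                )
            seen |= ids
            for s in prog.samples_active:
                if not 0 <= s < self.n_samples:
                    raise ValueError("samples_active out of range")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a cohort, aligned to its cells."""

    program_on: np.ndarray  # (n_cells, n_programs) bool
    program_gene_sets: list[tuple[str, ...]]
    malignant: pd.Series  # bool per cell
    sample_condition: pd.Series  # condition per sample
    config: SyntheticConfig


def default_genome_map(gene_names: Sequence[str], n_chromosomes: int = 22) -> pd.DataFrame:
    """Assign genes to pseudo-chromosomes in index order.

    Coordinates are gene-order ranks (0-based, half-open when used as
    segment bounds), not base pairs: downstream CNV smoothing operates
    on gene order only.
    """
    n = len(gene_names)
    bounds = np.linspace(0, n, n_chromosomes + 1).astype(int)
    chrom = np.empty(n, dtype=object)
    chr_rank = np.empty(n, dtype=int)
    for i in range(n_chromosomes):
        lo, hi = bounds[i], bounds[i + 1]
        chrom[lo:hi] = f"chr{i + 1}"
        chr_rank[lo:hi] = np.arange(hi - lo)
    return pd.DataFrame(
        {"gene": list(gene_names), "chromosome": chrom, "chr_rank": chr_rank}
    )


def _gene_names(cfg: SyntheticConfig) -> list[str]:
    n_regular = cfg.n_genes - cfg.n_mito_genes - cfg.n_hb_genes
    names = [f"G{i:05d}" for i in range(n_regular)]
    names += [f"MT-G{i}" for i in range(cfg.n_mito_genes)]
    # "HB" prefix without colliding with the HBEGF/HBS1L-style exclusions
    names += [f"HBG{i}" for i in range(cfg.n_hb_genes)]
    return names


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(cfg: SyntheticConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cohort as an :class:`anndata.AnnData` plus ground truth.

    The returned object holds raw counts in ``X`` (CSR), the generating
    mean in ``layers["mean"]`` (used by the ``plant_*`` helpers to
    resample after rescaling), per-cell ``obs`` columns ``sample``,
    ``cell_type`` and ``condition``, and a genome map in ``var``
    (``chromosome``, ``chr_rank``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_names(cfg)
    n_genes = cfg.n_genes
    n_regular = n_genes - cfg.n_mito_genes - cfg.n_hb_genes

    # per-gene baseline rates; MT/HB blocks rescaled to target count fractions
    rates = cfg.base_mean * rng.lognormal(0.0, cfg.gene_mean_sigma, n_genes)
    if cfg.lr_axis is not None:
        # axis genes emulate a well-expressed secreted ligand/receptor:
        # pin their baseline to base_mean so the planted effect, not the
        # baseline lottery, sets their level
        gidx0 = {g: i for i, g in enumerate(genes)}
        for g in (cfg.lr_axis.ligand_gene, *cfg.lr_axis.receptor_genes):
            if g not in gidx0:
                raise ValueError(f"lr_axis gene {g!r} not in cohort")
            rates[gidx0[g]] = cfg.base_mean
    reg = slice(0, n_regular)
    mt = slice(n_regular, n_regular + cfg.n_mito_genes)
    hb = slice(n_regular + cfg.n_mito_genes, n_genes)
    t_reg = rates[reg].sum()
    total = t_reg / max(1e-12, 1.0 - cfg.mito_fraction - cfg.hb_fraction)
    if cfg.n_mito_genes:
        rates[mt] *= cfg.mito_fraction * total / rates[mt].sum()
    if cfg.n_hb_genes:
        rates[hb] *= cfg.hb_fraction * total / rates[hb].sum()

    # samples and conditions
    sample_names = [f"S{i:02d}" for i in range(cfg.n_samples)]
    n_mal = int(round(cfg.malignant_fraction * cfg.n_samples))
    if 0 < cfg.malignant_fraction < 1:
        n_mal = min(max(n_mal, 1), cfg.n_samples - 1)
    condition = ["non_malignant"] * (cfg.n_samples - n_mal) + ["malignant"] * n_mal
    sample_condition = pd.Series(condition, index=sample_names, name="condition")

    # cells: deterministic type counts per sample (largest remainder)
    types = list(cfg.cell_type_fractions)
    fracs = np.array([cfg.cell_type_fractions[t] for t in types], dtype=float)
    fracs = fracs / fracs.sum()
    counts_per_type = np.floor(fracs * cfg.cells_per_sample).astype(int)
    rem = cfg.cells_per_sample - counts_per_type.sum()
    order = np.argsort(-(fracs * cfg.cells_per_sample - counts_per_type))
    counts_per_type[order[:rem]] += 1

    cell_sample: list[str] = []
    cell_type: list[str] = []
    cell_names: list[str] = []
    for s in sample_names:
        j = 0
        for t, c in zip(types, counts_per_type):
            for _ in range(c):
                cell_names.append(f"{s}_C{j:04d}")
                cell_sample.append(s)
                cell_type.append(t)
                j += 1
    n_cells = len(cell_names)
    obs = pd.DataFrame(
        {
            "sample": pd.Categorical(cell_sample, categories=sample_names),
            "cell_type": pd.Categorical(cell_type),
        },
        index=cell_names,
    )
    obs["condition"] = sample_condition.loc[obs["sample"]].to_numpy()

    depth = rng.lognormal(0.0, cfg.depth_sigma, n_cells)
    mean = np.outer(depth, rates).astype(np.float64)

    sample_arr = np.asarray(cell_sample)
    type_arr = np.asarray(cell_type)
    is_epi = type_arr == EPITHELIAL

    # planted programs
    program_on = np.zeros((n_cells, len(cfg.programs)), dtype=bool)
    program_gene_sets: list[tuple[str, ...]] = []
    for pi, prog in enumerate(cfg.programs):
        active_samples = {sample_names[s] for s in prog.samples_active}
        eligible = is_epi & np.isin(sample_arr, list(active_samples))
        on = eligible & (rng.random(n_cells) < prog.fraction_cells_on)
        program_on[:, pi] = on
        gid = np.asarray(prog.gene_ids, dtype=int)
        mean[np.ix_(on, gid)] *= prog.effect
        program_gene_sets.append(tuple(genes[g] for g in gid))

    genome = default_genome_map(genes, cfg.n_chromosomes)
    chrom_of = genome.set_index("gene")

    # CNV segments
    malignant = np.zeros(n_cells, dtype=bool)
    is_mal_sample = obs["condition"].to_numpy() == "malignant"
    name_to_idx = {c: i for i, c in enumerate(cell_names)}
    for seg in cfg.cnv_segments:
        gmask = _segment_gene_mask(genome, seg)
        if seg.affected_cells is None:
            cmask = is_epi & is_mal_sample
        else:
            idx = [name_to_idx[c] for c in seg.affected_cells]
            cmask = np.zeros(n_cells, dtype=bool)
            cmask[idx] = True
        mean[np.ix_(cmask, np.flatnonzero(gmask))] *= seg.fold
        if seg.fold != 1.0:
            malignant |= cmask

    # ligand-receptor axis
    if cfg.lr_axis is not None:
        axis = cfg.lr_axis
        for t in (axis.sender_type, axis.receiver_type):
            if t not in types:
                raise ValueError(f"lr_axis cell type {t!r} not in cohort")
        gidx = {g: i for i, g in enumerate(genes)}
        lig = gidx[axis.ligand_gene]
        send = (type_arr == axis.sender_type) & is_mal_sample
        recv = (type_arr == axis.receiver_type) & is_mal_sample
        mean[np.ix_(send, [lig])] *= axis.effect
        for r in axis.receptor_genes:
            mean[np.ix_(recv, [gidx[r]])] *= axis.effect

    counts = _sample_nb(rng, mean, cfg.dispersion)

    var = pd.DataFrame(
        {
            "chromosome": chrom_of.loc[genes, "chromosome"].to_numpy(),
            "chr_rank": chrom_of.loc[genes, "chr_rank"].to_numpy(),
            "is_mito": [g.startswith("MT-") for g in genes],
            "is_hb": [g.startswith("HB") for g in genes],
        },
        index=genes,
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=var,
        layers={MEAN_LAYER: mean.astype(np.float32)},
    )
    adata.uns["dispersion"] = cfg.dispersion
    adata.uns["seed"] = cfg.seed

    truth = GroundTruth(
        program_on=program_on,
        program_gene_sets=program_gene_sets,
        malignant=pd.Series(malignant, index=cell_names, name="malignant"),
        sample_condition=sample_condition,
        config=cfg,
    )
    return adata, truth


def _segment_gene_mask(genome: pd.DataFrame, seg: CnvSegmentSpec) -> np.ndarray:
    on_chr = genome["chromosome"].to_numpy() == seg.chromosome
    if not on_chr.any():
        raise ValueError(f"chromosome {seg.chromosome!r} not in genome map")
    size = int(on_chr.sum())
    if seg.end_gene_rank > size:
        raise ValueError(
            f"segment [{seg.start_gene_rank}, {seg.end_gene_rank}) exceeds "
            f"{seg.chromosome} size {size}"
        )
    rank = genome["chr_rank"].to_numpy()
    return on_chr & (rank >= seg.start_gene_rank) & (rank < seg.end_gene_rank)


def _resample_block(
    adata: ad.AnnData,
    cell_mask: np.ndarray,
    gene_idx: np.ndarray,
    factor: float,
    seed: int,
) -> None:
    """Rescale the generating mean of a (cells x genes) block and redraw
    its counts from the negative binomial, in place."""
    if MEAN_LAYER not in adata.layers:
        raise ValueError(
            "cohort lacks the generating-mean layer; plant_* helpers only "
            "apply to cohorts produced by generate_cohort"
        )
    dispersion = float(adata.uns.get("dispersion", 0.5))
    rng = np.random.default_rng(seed)
    rows = np.flatnonzero(cell_mask)
    mean = adata.layers[MEAN_LAYER]
    block = mean[np.ix_(rows, gene_idx)].astype(np.float64) * factor
    mean[np.ix_(rows, gene_idx)] = block.astype(np.float32)
    new_counts = _sample_nb(rng, block, dispersion)
    dense = np.asarray(adata.X.todense()) if sparse.issparse(adata.X) else np.array(adata.X)
    dense[np.ix_(rows, gene_idx)] = new_counts
    adata.X = sparse.csr_matrix(dense.astype(np.int64))


def plant_cnv_segments(
    adata: ad.AnnData,
    genome: pd.DataFrame,
    segments: Sequence[CnvSegmentSpec],
    seed: int = 0,
) -> ad.AnnData:
    """Return a copy of ``adata`` with CNV segments planted.

    Counts of segment genes in affected cells are redrawn from the
    negative binomial around ``fold`` times their previous mean.  An
    empty segment list or ``fold == 1`` leaves the counts distribution
    unchanged (fold-1 blocks are still resampled, which is
    distributionally a no-op).
    """
    out = adata.copy()
    name_to_idx = {c: i for i, c in enumerate(out.obs_names)}
    gene_pos = {g: i for i, g in enumerate(out.var_names)}
    for k, seg in enumerate(segments):
        gmask = _segment_gene_mask(genome, seg)
        seg_genes = genome.loc[gmask, "gene"]
        missing = [g for g in seg_genes if g not in gene_pos]
        if missing:
            raise ValueError(f"segment genes absent from matrix: {missing[:3]}...")
        gidx = np.array([gene_pos[g] for g in seg_genes], dtype=int)
        if seg.affected_cells is None:
            cmask = (
                (out.obs["cell_type"].to_numpy() == EPITHELIAL)
                & (out.obs["condition"].to_numpy() == "malignant")
            )
        else:
            cmask = np.zeros(out.n_obs, dtype=bool)
            for c in seg.affected_cells:
                if c not in name_to_idx:
                    raise ValueError(f"affected cell {c!r} not in cohort")
                cmask[name_to_idx[c]] = True
        if cmask.any():
            _resample_block(out, cmask, gidx, seg.fold, seed + 7919 * (k + 1))
    return out


def plant_lr_axis(adata: ad.AnnData, axis: LrAxisSpec, seed: int = 0) -> ad.AnnData:
    """Return a copy of ``adata`` with a ligand-receptor axis planted.

    The ligand is elevated in sender-type cells of malignant samples and
    every receptor subunit in receiver-type cells of malignant samples.
    """
    out = adata.copy()
    type_arr = out.obs["cell_type"].to_numpy()
    for t in (axis.sender_type, axis.receiver_type):
        if not (type_arr == t).any():
            raise ValueError(f"cell type {t!r} not present in cohort")
    gene_pos = {g: i for i, g in enumerate(out.var_names)}
    for g in (axis.ligand_gene, *axis.receptor_genes):
        if g not in gene_pos:
            raise ValueError(f"gene {g!r} not in cohort")
    is_mal = out.obs["condition"].to_numpy() == "malignant"
    send = (type_arr == axis.sender_type) & is_mal
    recv = (type_arr == axis.receiver_type) & is_mal
    _resample_block(out, send, np.array([gene_pos[axis.ligand_gene]]), axis.effect, seed + 1)
    ridx = np.array([gene_pos[r] for r in axis.receptor_genes])
    _resample_block(out, recv, ridx, axis.effect, seed + 2)
    return out


def generate_survival(
    covariate: Sequence[float] | np.ndarray | pd.Series,
    beta: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival times with log-hazard linear in a covariate.

    Event time T_i ~ Exponential(h0 * exp(beta * x_i)); censoring times
    are independent exponentials whose rate is matched to the cohort's
    average hazard so the expected censored fraction is approximately
    ``censor_rate``.  ``censor_rate = 0`` yields all-event records.
    """
    x = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(beta * x)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate == 0:
        time, event = t_event, np.ones(len(x), dtype=bool)
    else:
        c_rate = hazard.mean() * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(x))
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {"time": time, "event": event, "covariate": x},
        index=[f"subj{i:04d}" for i in range(len(x))],
    )
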