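"""End-to-end benchmark runs on synthetic cohorts and in-paper tables.

Cohort-level results from the original study (hundreds of thousands of
cells across public accessions, patient-level clinical records) are not
reproducible at desk scale, so the pipeline is exercised on synthetic
cohorts whose planted ground truth plays the role of the unknown
biology: meta-program recovery, CNV-classifier operating
characteristics, permutation-test calibration, survival-machinery
calibration and pseudobulk DE power.  The printed clinicopathological
contingency table ships with the cohort's publication and is used
directly as input for the chi-square layer.

Every function takes a seed and returns a small dict of summary numbers;
``tests/test_acceptance.py`` asserts on them and
``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clinical, cnv, crosstalk, metaprograms, pseudobulk, qc, synthetic

__all__ = [
    "TABLE1_COUNTS",
    "table1_pvalues",
    "ihc_scheme_summary",
    "mp_recovery",
    "cnv_classifier_metrics",
    "crosstalk_calibration",
    "survival_calibration",
    "pseudobulk_de_power",
]

# Stromal-marker high/low counts per clinicopathological characteristic
# (rows: characteristic levels; columns: high, low), as published for the
# 173-patient IHC cohort.
TABLE1_COUNTS: dict[str, list[list[int]]] = {
    "age": [[51, 24], [60, 38]],
    "gender": [[58, 33], [53, 29]],
    "tnm_stage": [[10, 18], [64, 39], [12, 1], [25, 3]],
    "lymph_node_metastasis": [[32, 42], [79, 20]],
    "nervous_invasion": [[10, 8], [101, 54]],
    "vascular_invasion": [[53, 44], [58, 18]],
    "distant_metastasis": [[86, 59], [25, 3]],
}


def table1_pvalues() -> dict[str, float]:
    """Uncorrected Pearson chi-square p-value per characteristic."""
    return {
        name: clinical.pearson_chi_square(tab)[2]
        for name, tab in TABLE1_COUNTS.items()
    }


def ihc_scheme_summary() -> dict[str, float]:
    """Exercise the composite-score map over its full input grid."""
    composites = [
        clinical.ihc_composite_score(area, grade).composite
        for area in np.linspace(0, 100, 41)
        for grade in range(4)
    ]
    max_case = clinical.ihc_composite_score(80, 3)
    boundary = clinical.ihc_composite_score(30, 1)  # composite 2 -> negative
    low_case = clinical.ihc_composite_score(30, 2)  # composite 4 -> low
    high_case = clinical.ihc_composite_score(55, 2)  # composite 6 -> high
    assert (max_case.category, boundary.category) == ("high", "negative")
    assert (low_case.category, high_case.category) == ("low", "high")
    return {"max_composite": float(max(composites))}


def mp_recovery(
    seed: int,
    n_samples: int = 10,
    cells_per_sample: int = 500,
    n_genes: int = 1500,
    n_programs: int = 5,
    effect: float = 4.0,
) -> dict[str, float]:
    """Recover planted shared programs through the full MP pipeline.

    Plants ``n_programs`` disjoint 50-gene programs active in every
    sample, runs normalization, HVG selection, per-sample NMF (K=3-10),
    robustness selection and Jaccard clustering, and reports how many
    planted programs are matched by a meta-program consensus list at
    Jaccard >= 0.8.
    """
    gene_ids = [tuple(range(i * 50, (i + 1) * 50)) for i in range(n_programs)]
    progs = [
        synthetic.ProgramSpec(
            g, tuple(range(n_samples)), fraction_cells_on=0.25, effect=effect
        )
        for g in gene_ids
    ]
    cfg = synthetic.SyntheticConfig(
        n_samples=n_samples,
        cells_per_sample=cells_per_sample,
        n_genes=n_genes,
        base_mean=0.5,
        seed=seed,
        programs=progs,
        cell_type_fractions={synthetic.EPITHELIAL: 1.0},
    )
    adata, truth = synthetic.generate_cohort(cfg)
    norm = qc.normalize_log(adata)
    hvg = qc.select_hvg(norm, n=1000)
    out = metaprograms.discover_meta_programs(norm, genes=hvg, seed=seed)
    best_j = []
    for planted in truth.program_gene_sets:
        best = max(
            (
                metaprograms.jaccard_index(mp.consensus_genes, planted)
                for mp in out["meta_programs"]
            ),
            default=0.0,
        )
        best_j.append(best)
    return {
        "n_planted": float(n_programs),
        "n_recovered": float(sum(j >= 0.8 for j in best_j)),
        "mean_truth_jaccard": float(np.mean(best_j)),
        "n_meta_programs": float(len(out["meta_programs"])),
    }


def cnv_classifier_metrics(
    seed: int,
    n_samples: int = 4,
    cells_per_sample: int = 500,
    n_genes: int = 2200,
    fold: float = 2.0,
    n_segments: int = 3,
    segment_genes: int = 150,
    malignant_cell_fraction: float = 0.3,
) -> dict[str, float]:
    """Sensitivity/specificity of the malignancy call on planted CNVs.

    A cohort with fold-``fold`` gains over ``n_segments`` 150-gene
    segments carried by 30% of epithelial cells; reference cells set the
    score threshold (90th percentile).
    """
    rng = np.random.default_rng(seed)
    cfg = synthetic.SyntheticConfig(
        n_samples=n_samples,
        cells_per_sample=cells_per_sample,
        n_genes=n_genes,
        n_chromosomes=10,
        base_mean=0.5,
        seed=seed,
    )
    adata, _ = synthetic.generate_cohort(cfg)
    epi_cells = adata.obs_names[
        (adata.obs["cell_type"] == synthetic.EPITHELIAL).to_numpy()
    ]
    affected = tuple(
        rng.choice(
            epi_cells,
            size=int(malignant_cell_fraction * len(epi_cells)),
            replace=False,
        )
    )
    genome = synthetic.default_genome_map(list(adata.var_names), 10)
    segments = [
        synthetic.CnvSegmentSpec(
            f"chr{2 * k + 1}", 30, 30 + segment_genes, fold, affected_cells=affected
        )
        for k in range(n_segments)
    ]
    adata = synthetic.plant_cnv_segments(adata, genome, segments, seed=seed + 1)
    norm = qc.normalize_log(adata)
    calls = cnv.cnv_malignancy(norm, genome)

    epi_mask = (adata.obs["cell_type"] == synthetic.EPITHELIAL).to_numpy()
    truth = pd.Series(False, index=adata.obs_names)
    truth[list(affected)] = True
    pred = calls["malignant"][epi_mask]
    tr = truth[epi_mask]
    sens = float((pred & tr).sum() / tr.sum())
    spec = float(((~pred) & (~tr)).sum() / (~tr).sum())
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_epithelial": float(epi_mask.sum()),
    }


def crosstalk_calibration(
    seed: int,
    n_null_pairs: int = 500,
    n_perm: int = 1000,
) -> dict[str, float]:
    """Type-I error of the permutation test and planted-axis ranking.

    The null uses a cohort with no planted effects: random gene pairs
    scored fibroblast -> epithelial should reject at the nominal 5%.
    The planted check scores a POSTN-like axis (effect 4) against decoy
    pairs over every (pair, sender, receiver) triple.
    """
    rng = np.random.default_rng(seed)

    cfg0 = synthetic.SyntheticConfig(
        n_samples=4, cells_per_sample=400, n_genes=600, base_mean=0.5, seed=seed
    )
    a0, _ = synthetic.generate_cohort(cfg0)
    n0 = qc.normalize_log(a0)
    lab0 = n0.obs["cell_type"].astype(str).to_numpy()
    rejections = 0
    for i in range(n_null_pairs):
        g1, g2 = rng.integers(0, 500, 2)
        # fully label-permuted data: random labels sever any chance
        # association between cluster membership and cell covariates
        perm_labels = pd.Series(rng.permutation(lab0), index=n0.obs_names)
        res = crosstalk.interaction_score(
            n0,
            perm_labels,
            crosstalk.LRPair(f"null{i}", f"G{g1:05d}", (f"G{g2:05d}",)),
            synthetic.FIB_ECM,
            synthetic.EPITHELIAL,
            n_perm=n_perm,
            seed=seed + 17 * i,
        )
        rejections += res.p_value < 0.05

    axis = synthetic.LrAxisSpec(
        ligand_gene="G00100", receptor_genes=("G00200", "G00300"), effect=4.0
    )
    cfg1 = synthetic.SyntheticConfig(
        n_samples=6,
        cells_per_sample=300,
        n_genes=800,
        base_mean=0.5,
        seed=seed + 1,
        lr_axis=axis,
    )
    a1, _ = synthetic.generate_cohort(cfg1)
    n1 = qc.normalize_log(a1)
    mal = n1[(n1.obs["condition"] == "malignant").to_numpy()]
    decoys = [
        crosstalk.LRPair(
            f"decoy{i}", f"G{rng.integers(0, 700):05d}", (f"G{rng.integers(0, 700):05d}",)
        )
        for i in range(14)
    ]
    pairs = [crosstalk.LRPair("planted", "G00100", ("G00200", "G00300"))] + decoys
    results = crosstalk.score_all_triples(
        mal, mal.obs["cell_type"], pairs, n_perm=200, seed=seed + 2
    )
    results.sort(key=lambda r: -r.score)
    planted_rank = next(
        k + 1
        for k, r in enumerate(results)
        if r.pair.pair_id == "planted"
        and r.sender == synthetic.FIB_ECM
        and r.receiver == synthetic.EPITHELIAL
    )
    return {
        "null_rejection_rate": rejections / n_null_pairs,
        "planted_axis_rank": float(planted_rank),
        "n_scored_triples": float(len(results)),
    }


def survival_calibration(
    seed: int,
    n_logrank_reps: int = 1000,
    logrank_n: int = 200,
    n_cox_reps: int = 200,
    cox_n: int = 500,
) -> dict[str, float]:
    """Log-rank type-I error under the null and Cox CI coverage at HR=2."""
    groups = pd.Series(["a"] * (logrank_n // 2) + ["b"] * (logrank_n // 2))
    rejections = 0
    for i in range(n_logrank_reps):
        rec = synthetic.generate_survival(
            np.zeros(logrank_n), beta=0.0, censor_rate=0.1, seed=seed + i
        )
        rejections += clinical.km_logrank(rec, groups).p_value < 0.05

    covered = 0
    x = np.repeat([0.0, 1.0], cox_n // 2)
    for i in range(n_cox_reps):
        rec = synthetic.generate_survival(
            x, beta=np.log(2.0), censor_rate=0.2, seed=seed + 100000 + i
        )
        fit = clinical.cox_ph(rec, ["covariate"])
        lo, hi = fit.loc["covariate", ["ci_low", "ci_high"]]
        covered += bool(lo <= 2.0 <= hi)
    return {
        "logrank_type1_rate": rejections / n_logrank_reps,
        "cox_hr2_ci_coverage": covered / n_cox_reps,
    }


def pseudobulk_de_power(
    seed: int,
    n_reps: int = 3,
    n_genes: int = 1000,
    n_planted: int = 60,
    effect: float = 4.0,
) -> dict[str, float]:
    """Power of the DEG rule for planted 4-fold genes at 6 vs 6 samples.

    Each replicate plants ``n_planted`` genes at ``effect``-fold in the
    epithelial cells of the 6 "high" samples, aggregates epithelial
    pseudobulk, applies the gene filters and the |log2FC| >= 1, P < 0.05
    rule, and counts recovered planted genes.
    """
    hits = total = 0
    for rep in range(n_reps):
        prog = synthetic.ProgramSpec(
            tuple(range(n_planted)),
            samples_active=tuple(range(6, 12)),
            fraction_cells_on=1.0,
            effect=effect,
        )
        cfg = synthetic.SyntheticConfig(
            n_samples=12,
            cells_per_sample=150,
            n_genes=n_genes,
            base_mean=0.5,
            seed=seed + 31 * rep,
            programs=[prog],
            cell_type_fractions={synthetic.EPITHELIAL: 1.0},
        )
        adata, truth = synthetic.generate_cohort(cfg)
        pb = pseudobulk.aggregate_pseudobulk(adata, synthetic.EPITHELIAL)
        pb = pseudobulk.filter_pseudobulk_genes(pb)
        groups = pd.Series(
            ["low"] * 6 + ["high"] * 6, index=[f"S{i:02d}" for i in range(12)]
        )
        de = pseudobulk.de_test(pb, groups, "high", "low")
        planted = [g for g in truth.program_gene_sets[0] if g in de.index]
        hits += int(de.loc[planted, "deg_flag"].sum())
        total += len(planted)
    return {"power": hits / total, "n_planted_tested": float(total)}
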