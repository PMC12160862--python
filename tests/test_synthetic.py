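"""Generator contracts: dimensions, determinism, planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stromascape as ss


def test_cohort_dimensions_and_annotation():
    cfg = ss.SyntheticConfig(n_samples=6, cells_per_sample=300, n_genes=500, seed=0)
    adata, truth = ss.generate_cohort(cfg)
    assert adata.shape == (1800, 500)
    assert list(adata.obs.columns[:3]) == ["sample", "cell_type", "condition"]
    assert adata.obs["sample"].nunique() == 6
    assert (adata.obs.groupby("sample", observed=True).size() == 300).all()
    # every cell annotated, truth aligned
    assert truth.malignant.index.equals(adata.obs_names)


def test_same_seed_identical_output():
    cfg = ss.SyntheticConfig(n_samples=3, cells_per_sample=100, n_genes=300, seed=11)
    a1, t1 = ss.generate_cohort(cfg)
    a2, t2 = ss.generate_cohort(cfg)
    assert (a1.X != a2.X).nnz == 0
    assert np.array_equal(t1.program_on, t2.program_on)
    assert a1.obs.equals(a2.obs)


def test_unit_effect_program_is_null():
    """With effect=1, program genes are indistinguishable between on/off
    cells: two-sample p-values behave uniformly across replicates."""
    pvals = []
    for rep in range(8):
        prog = ss.ProgramSpec(
            tuple(range(20)), samples_active=(0, 1), fraction_cells_on=0.5, effect=1.0
        )
        cfg = ss.SyntheticConfig(
            n_samples=2,
            cells_per_sample=300,
            n_genes=200,
            base_mean=2.0,
            seed=100 + rep,
            programs=[prog],
            cell_type_fractions={"epithelial": 1.0},
        )
        adata, truth = ss.generate_cohort(cfg)
        X = np.asarray(adata.X.todense())
        on = truth.program_on[:, 0]
        sig = X[:, :20].sum(axis=1)
        pvals.append(stats.mannwhitneyu(sig[on], sig[~on]).pvalue)
    # no systematic signal: not all replicates can be significant
    assert np.mean(np.array(pvals) < 0.05) <= 0.25
    assert np.median(pvals) > 0.1


def test_overlapping_programs_rejected_unless_permitted():
    progs = [
        ss.ProgramSpec(tuple(range(50)), (0,)),
        ss.ProgramSpec(tuple(range(25, 75)), (0,)),
    ]
    cfg = ss.SyntheticConfig(n_samples=2, cells_per_sample=50, n_genes=300, programs=progs)
    with pytest.raises(ValueError, match="overlap"):
        cfg.validate()
    cfg.allow_program_overlap = True
    cfg.validate()


@pytest.fixture(scope="module")
def base_cohort():
    cfg = ss.SyntheticConfig(
        n_samples=2,
        cells_per_sample=400,
        n_genes=400,
        base_mean=2.0,
        seed=5,
        malignant_fraction=0.5,
    )
    return ss.generate_cohort(cfg)[0]


def test_plant_cnv_fold_two_doubles_block_mean(base_cohort):
    genome = ss.default_genome_map(list(base_cohort.var_names), 4)
    seg = ss.CnvSegmentSpec("chr1", 0, 100, 2.0)
    planted = ss.plant_cnv_segments(base_cohort, genome, [seg], seed=1)
    epi = (base_cohort.obs["cell_type"] == "epithelial").to_numpy()
    mal = (base_cohort.obs["condition"] == "malignant").to_numpy()
    block = np.asarray(planted.X[:, :100].todense())
    affected_mean = block[epi & mal].mean()
    ref_mean = block[epi & ~mal].mean()
    assert affected_mean / ref_mean == pytest.approx(2.0, rel=0.1)


def test_plant_cnv_noops(base_cohort):
    genome = ss.default_genome_map(list(base_cohort.var_names), 4)
    unchanged = ss.plant_cnv_segments(base_cohort, genome, [], seed=1)
    assert (unchanged.X != base_cohort.X).nnz == 0
    # fold 1 resamples but keeps the generating mean: block means agree
    fold1 = ss.plant_cnv_segments(
        base_cohort, genome, [ss.CnvSegmentSpec("chr1", 0, 100, 1.0)], seed=1
    )
    a = np.asarray(fold1.X[:, :100].todense()).mean()
    b = np.asarray(base_cohort.X[:, :100].todense()).mean()
    assert a == pytest.approx(b, rel=0.05)


def test_plant_cnv_out_of_range_rank(base_cohort):
    genome = ss.default_genome_map(list(base_cohort.var_names), 4)
    with pytest.raises(ValueError, match="exceeds"):
        ss.plant_cnv_segments(
            base_cohort, genome, [ss.CnvSegmentSpec("chr1", 0, 9999, 2.0)]
        )


def test_plant_lr_axis_elevates_sender_and_receiver(base_cohort):
    axis = ss.LrAxisSpec(
        ligand_gene="G00010", receptor_genes=("G00020", "G00030"), effect=4.0
    )
    planted = ss.plant_lr_axis(base_cohort, axis, seed=2)
    mal = (planted.obs["condition"] == "malignant").to_numpy()
    types = planted.obs["cell_type"].astype(str).to_numpy()
    lig = np.asarray(planted[:, "G00010"].X.todense()).ravel()
    sender_mean = lig[mal & (types == axis.sender_type)].mean()
    other_means = [
        lig[mal & (types == t)].mean()
        for t in np.unique(types)
        if t != axis.sender_type
    ]
    assert all(sender_mean > m for m in other_means)
    for sub in axis.receptor_genes:  # both subunits elevated in receiver
        v = np.asarray(planted[:, sub].X.todense()).ravel()
        v0 = np.asarray(base_cohort[:, sub].X.todense()).ravel()
        recv = mal & (types == axis.receiver_type)
        assert v[recv].mean() > 2 * v0[recv].mean()


def test_plant_lr_axis_missing_type(base_cohort):
    axis = ss.LrAxisSpec(
        ligand_gene="G00010", receptor_genes=("G00020",), sender_type="nonexistent"
    )
    with pytest.raises(ValueError, match="not present"):
        ss.plant_lr_axis(base_cohort, axis)


def test_ground_truth_malignant_matches_affected_sets():
    segs = [ss.CnvSegmentSpec("chr1", 0, 30, 2.0), ss.CnvSegmentSpec("chr2", 0, 30, 2.0)]
    cfg = ss.SyntheticConfig(
        n_samples=4, cells_per_sample=100, n_genes=440, n_chromosomes=4,
        seed=3, cnv_segments=segs,
    )
    adata, truth = ss.generate_cohort(cfg)
    expected = (
        (adata.obs["cell_type"] == "epithelial")
        & (adata.obs["condition"] == "malignant")
    ).to_numpy()
    assert np.array_equal(truth.malignant.to_numpy(), expected)


def test_survival_no_censoring_all_events():
    rec = ss.generate_survival(np.zeros(50), beta=0.0, censor_rate=0.0, seed=1)
    assert rec["event"].all()
    assert (rec["time"] >= 0).all()


def test_survival_null_beta_hazard_ratio_near_one():
    """beta=0: the fitted 95% CI covers HR=1 in nearly all replicates."""
    x = np.repeat([0.0, 1.0], 250)
    covered = 0
    for i in range(30):
        rec = ss.generate_survival(x, beta=0.0, censor_rate=0.1, seed=400 + i)
        fit = ss.cox_ph(rec, ["covariate"])
        covered += bool(fit["ci_low"].iloc[0] <= 1.0 <= fit["ci_high"].iloc[0])
    assert covered >= 27


def test_survival_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ss.generate_survival([np.nan, 1.0], beta=0.0)
    with pytest.raises(ValueError):
        ss.generate_survival([0.0, 1.0], beta=0.0, censor_rate=1.0)
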