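"""Generate a small synthetic cohort and write it to disk.

Builds a 6-sample cohort with one planted 50-gene epithelial program and
a fold-2 copy-number gain, runs QC, and writes the MTX/CSV bundle.  The
printed numbers are the cohort dimensions, the per-rule QC removals and
the fraction of cells carrying the planted CNV.
"""

from pathlib import Path

import stromascape as ss

program = ss.ProgramSpec(
    gene_ids=tuple(range(50)), samples_active=(0, 1, 2, 3, 4, 5),
    fraction_cells_on=0.3, effect=4.0,
)
segment = ss.CnvSegmentSpec("chr1", 0, 40, fold=2.0)
cfg = ss.SyntheticConfig(
    n_samples=6, cells_per_sample=300, n_genes=1000,
    programs=[program], cnv_segments=[segment], seed=0,
)
adata, truth = ss.generate_cohort(cfg)
print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, "
      f"{adata.obs['sample'].nunique()} samples")
print("cell types:", dict(adata.obs["cell_type"].value_counts()))
print(f"cells carrying the planted CNV: {truth.malignant.mean():.1%}")

filtered, report = ss.qc_filter(adata, ss.QcThresholds(min_genes=100,
                                                       min_cells_per_sample=100))
print("QC removals by rule:", report.cells_removed_by_rule)

out = Path("scratch/example_cohort")
ss.io.write_cohort(out, filtered, ground_truth=truth)
print(f"written to {out}/ (matrix.mtx, features.tsv, barcodes.tsv, "
      "annotation.csv, genome_map.csv, ground_truth.json)")
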