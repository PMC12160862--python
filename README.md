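# stromascape

Analysis toolkit for dissecting fibroblast-epithelial crosstalk in
multi-sample single-cell tumor cohorts, built around the workflow used
in integrative pancreatic-cancer (PDAC) studies: recurrent epithelial
expression programs, copy-number-based malignancy calling, ligand-
receptor communication (POSTN-ITGAV/ITGB5-style axes), pseudobulk
differential expression, and the clinical statistics that connect a
stromal marker to patient outcome.

It is a library, used from Python. `examples/` holds one short script
per capability; `anndata.AnnData` is the in-memory container
throughout.

## What it computes

- **Meta-programs (MPs).** Per sample, epithelial expression is
  factorized with NMF over ranks *K* = 3-10; each factor is reduced to
  its top-50 genes by loading. Programs that are stable across *K*
  within a sample, recurrent across samples, and non-redundant are
  hierarchically clustered on Jaccard distance *d* = 1 − |A∩B|/|A∪B|;
  each cluster of programs from ≥ 2 samples becomes an MP with a
  50-gene consensus list (ranked by member frequency, then mean
  loading).
- **CNV malignancy score.** Per cell, relative log-expression against
  reference cells is clipped to ±3, smoothed by a 101-gene centered
  moving average along genome order within each chromosome, and
  median-recentered. The CNV score is the mean squared smoothed
  deviation; a cell is malignant when its score exceeds the 90th
  percentile of the reference cells' scores.
- **Crosstalk.** For ligand *L*, receptor subunits *R₁..Rₖ*, sender
  cluster *S* and receiver *R*: score = mean(*L*|*S*) · minᵢ
  mean(*Rᵢ*|*R*), with p-values from permuting cluster labels
  (add-one corrected). Significant pairs aggregate into directed
  sender × receiver networks; condition differentials are edge-wise.
- **Pseudobulk DE.** Raw counts summed per sample for one cell type;
  genes with total count ≤ 1 or detected in < 2 samples are excluded; a
  Welch test on log2(CPM+1) with log2FC = log2((CPMₐ+1)/(CPM_b+1));
  DEG ⇔ |log2FC| ≥ 1 and *P* < 0.05. Preranked enrichment uses the
  weighted Kolmogorov-Smirnov running sum with a random-set null.
- **Clinical layer.** Composite IHC score = area bin (0-4) × intensity
  (0-3), categorized negative (0-2) / low (3-5) / high (≥ 6); Pearson
  chi-square without continuity correction; Kaplan-Meier with the
  log-rank test; Cox proportional hazards with Wald CIs.
- **Synthetic cohorts.** A generator plants shared expression programs,
  CNV segments, a ligand-receptor axis and survival outcomes into
  negative-binomial counts with known ground truth, so every stage can
  be validated by recovery.

## Worked example

```sh
python examples/discover_metaprograms.py
```

```
260 NMF programs -> 52 robust -> 3 meta-programs
MP1: 5 member programs from 5 samples, best truth Jaccard 1.00
MP2: 5 member programs from 5 samples, best truth Jaccard 0.96
MP3: 5 member programs from 5 samples, best truth Jaccard 0.96
```

Three 50-gene programs were planted into the epithelial cells of a
5-sample synthetic cohort; the pipeline extracts 260 NMF factors (52
per sample), keeps 52 robust programs, and clusters them into exactly 3
meta-programs whose consensus lists match the planted gene sets at
Jaccard 0.96-1.00 — i.e. 48-50 of 50 genes recovered.

Other examples print, for instance, the CNV classifier's operating
point (`examples/cnv_malignancy.py`: sensitivity 0.995, specificity
0.913 on planted fold-2 gains) and the planted POSTN-like axis ranking
first among all scored (pair, sender, receiver) triples
(`examples/crosstalk_network.py`).

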