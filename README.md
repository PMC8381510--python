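# panelforge

Minimal multi-omic marker panels for molecular subtype classification.

Glioblastoma (GBM) expression profiling distinguishes three transcriptomic
subtypes — Classical, Mesenchymal and Proneural — but genome-wide
signatures are impractical as clinical assays. `panelforge` implements a
pipeline that compresses genome-scale expression and DNA-methylation
profiles into **five-feature one-vs-rest panels** per subtype (and
ten-feature integrative panels combining both modalities), then applies
them to new bulk cohorts or single cells. The package is written for
computational biologists building or evaluating compact subtype
classifiers; everything runs on plain TSV matrices and a sample sheet.

## Method

For each subtype *k* (target vs the pooled rest as control):

1. **Screening.** Expression is filtered (lowest 25 % mean expression
   removed), z-scored per gene, and screened with the Z-Ratio
   `ZRatio_j = d_j / SD(d)` (difference of group mean z-scores, scaled by
   the SD of those differences over all genes), a pooled-variance
   Student t-test and Benjamini–Hochberg FDR; significant means
   |Z-Ratio| > 1.5 and q < 0.05. Methylation beta values are converted to
   M-values, `M = log2(β/(1−β))`, batch-corrected across sources with
   parametric empirical-Bayes ComBat, and screened with |ΔM| ≥ 1.0 and
   q < 0.05.
2. **Elimination.** A random forest (ntree = 1000, mtry = ⌊√p⌋) ranks the
   significant features by out-of-bag permutation importance; the 20 %
   least important are dropped repeatedly (refitting with 500 trees) and
   the set with the lowest OOB error is kept.
3. **Ranking.** Nearest shrunken centroids
   `d_jk = (x̄_jk − x̄_j) / (m_k (s_j + s0))`, soft-thresholded at a
   10-fold-CV-chosen Δ, rank the surviving features; the top five are
   taken under the constraint of at least two positively and two
   negatively associated markers.
4. **Consensus.** Steps 2–3 are repeated (300 replicates by default) and
   the most frequent five-feature set wins.
5. **Centroid estimation.** Panel centroids, scale terms, error rates and
   ROC AUCs are averaged over 300 subtype-balanced subcohorts
   (expression re-z-scored per subcohort), giving the final `Panel`.

New samples are scored by the standardized-distance discriminant
`δ_k(x) = Σ_j (x_j − x̄'_jk)²/(s_j+s0)² − 2 log π_k`; the subtype whose
panel gives the highest target-class posterior wins. Single cells are
classified cell-wise with the expression panels; per-patient subtype
fractions and pseudobulk (per-gene mean) assignments summarize intra-tumor
heterogeneity.

## Worked example

```python
import panelforge as pf

# synthetic three-subtype cohort: 43 patients/class, 2,000 genes and CpGs,
# 50 planted markers per subtype at 1.5-SD effects, 3 batches
expr, beta, sheet, truth = pf.simulate_multiomic(pf.SimConfig(n_per_subtype=43, seed=1))
train, val = pf.split_cohort(sheet, 0.7, seed=1)

z = pf.zscore_normalize(pf.filter_low_expression(expr.select_samples(train.sample_ids)))
deg = pf.select_deg(z, train, "Classical")
print(deg["significant"].sum())           # 46  significant genes

labels = train.subtype_of().where(lambda s: s == "Classical", "Control")
res = pf.consensus_panel(z.select_features(deg.loc[deg.significant, "feature_id"].tolist()),
                         labels, "Classical", n_replicates=50, ntree=100,
                         ntree_iterat=50, seed=1)
print(res.winning_set)                    # ('G00068', 'G00602', 'G01199', 'G01260', 'G01877')
print(len(set(res.winning_set) & truth.informative_ids("Classical", "expression")))  # 5
```

All five winning genes are planted Classical markers. `estimate_panel`
then turns the winning set into a `Panel` whose held-out AUC on the
validation cohort is ≈ 0.96 (see `scripts/acceptance.py` output).

A shell-level run of the same pipeline:

```sh
panelforge simulate --config sim.yaml --out data/
panelforge train --expr data/expression.tsv --meth data/beta.tsv \
    --sheet data/samples.tsv --out panels/
panelforge classify --panels panels/ --kind integrative \
    --expr newcohort_expression.tsv --meth newcohort_beta.tsv --out calls.tsv
panelforge evaluate --table calls.tsv --sheet newcohort_samples.tsv
```

`panelforge config --defaults` prints the documented default thresholds
and sizes.

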