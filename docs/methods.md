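# Methods

## Scope and model

`panelforge` builds compact one-vs-rest classifiers for the three
transcriptomic glioblastoma subtypes (Classical, Mesenchymal, Proneural)
from two array-like modalities: gene-expression intensities on a
log-intensity scale and DNA-methylation beta values. The statistical core
is the nearest-shrunken-centroid (NSC) model; feature selection wraps a
random-forest backward elimination and a consensus vote around it. All
estimation assumes feature × sample matrices with per-feature statistics
computed across samples, independent samples, and subtype labels known
for training.

## Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| gene filter | fraction removed | 0.25 | lowest-expressed quarter carries mostly noise; cut rounds up (`ceil(0.25 p)`), which on a 12,042-gene array removes 3,011 and keeps 9,031 |
| expression screen | Z-Ratio cut | > 1.5 (strict) | Z-Ratio = per-gene difference of group mean z-scores divided by the SD of those differences across genes |
| methylation screen | ΔM cut | ≥ 1.0 (inclusive) | difference of group mean M-values; M = log2(β/(1−β)) with β clipped to [1e-6, 1−1e-6] |
| both screens | q cut | < 0.05 (strict) | BH step-up on pooled-variance Student t p-values |
| elimination | ntree / ntreeIterat | 1000 / 500 | initial forest for the importance ranking; smaller refits per step |
| elimination | mtry factor, drop fraction | 1, 0.2 | mtry = ⌊√p⌋; 20 % (round half up, ≥1) of surviving features dropped per step down to 2 |
| consensus | replicates | 300 | modal unordered 5-set wins; ties by mean CV error then lexicographic |
| NSC | SE factor m_k | √(1/n_k + 1/n) | published descriptions differ on the sign of the 1/n term; the convention is a parameter (`se_convention`), and a single convention is used consistently everywhere including the test oracles |
| NSC CV | folds, grid | 10, 30 thresholds on [0, max\|d\|] | ties take the largest Δ (fewest features) |
| centroid estimation | iterations | 300 | subtype-balanced subcohorts (m = smallest subtype size), target m vs pooled control 2m, priors (1/3, 2/3) |
| batch correction | tol, max_iter | 1e-4, 500 | parametric EB ComBat without covariates |

## Numerical and design choices

* **Pooled t, not Welch.** The screen pairs an effect-size filter with a
  classical Student t-test; zero-pooled-variance features get p = 1
  (equal means) or a 1e-300 floor (unequal), documented degenerate rules.
* **Expression screening on z-scores, methylation on M-values.** Matching
  the transforms each modality needs (z-scores make array intensities
  comparable; the logit2 transform makes bimodal beta values
  near-normal). M-values are never re-scaled: their absolute scale
  carries the ΔM effect criterion, whereas expression is re-z-scored
  within every cohort it is used in (training subcohorts and cohorts
  being classified).
* **OOB permutation importance** (mean decrease in per-tree out-of-bag
  accuracy, unscaled) is computed once on the initial forest and the
  ranking is reused for all elimination steps; the selected set is the
  strictly-lowest-OOB one, with ties to the smaller set. The
  within-one-SE selection variant is deliberately not the default.
* **Quota-constrained top-5.** Candidates are ranked by |d′| for the
  target class; a greedy pass reserves slots so the final five contain at
  least two positive and two negative markers. If shrinkage leaves too
  few candidates the ranking falls back to unshrunken |d|; if the
  eliminated set itself is too small to satisfy the quota (strong, clean
  signal lets the OOB tie-break collapse to 2 features), the replicate
  re-ranks over the full screened candidate set with a fresh CV-chosen
  threshold instead of failing. Replicates that still cannot satisfy the
  quota are skipped and excluded from the consensus tally.
* **Δ = 0 for final centroid estimation.** Panel features are already
  selected; the balanced-resampling stage estimates plain centroids,
  scale terms (s_j + s0), 10-fold-CV error and AUC per iteration and
  averages them. Per-iteration error/AUC use cross-validated posteriors
  by default (honest estimates); resubstitution is available by flag.
* **Scoring ties** between subtype panels resolve in the fixed order
  Classical < Mesenchymal < Proneural, with a logged warning.
* **Kappa** is defined as 1 when both labelings are the same constant
  (observed and chance agreement both 1); AUC uses the rank statistic,
  exact under ties.
* **Cohort splitting** is stratified by subtype with per-subtype
  round-half-up training counts. Whether stratification was used
  upstream in comparable studies is not always stated; it is this
  package's choice.

## The synthetic generator

`simulate_multiomic` emulates the data structure the pipeline assumes:
three balanced subtypes; per-subtype disjoint sets of informative genes
(additive shifts of `gene_effect` within-class SDs, half up / half down)
and CpGs (shifts of `m_effect` on the M scale); a bimodal M-value
baseline (mixture of hypo- and hypermethylated sites at M ≈ ∓3) mapped to
beta via β = 2^M/(2^M+1); and several sources with per-(batch, feature)
additive shifts (SD `batch_shift_sd`) and multiplicative scales, balanced
over subtypes. Defaults are the package's reference study conditions:
30 training samples per class (43 per class before the 70/30 split),
2,000 genes and CpGs, 50 informative features per subtype and modality,
1.5-SD expression effects, ΔM = 2 methylation effects, three batches.

`simulate_cells` draws per-patient subtype mixtures from a concentrated
Dirichlet, gives every cell a latent subtype and Gaussian noise around
the subtype template, and optionally zeroes entries at a dropout rate.

What the generator does **not** emulate: probe-level noise models,
heavy-tailed intensity distributions, correlated gene modules,
copy-number or purity effects, batch–subtype confounding, and count-based
single-cell noise. Passing tests therefore demonstrate the pipeline's
internal correctness and its behavior under idealized planted signal, not
clinical-grade performance on real cohorts.

## Desk-scale configuration

Defaults match the reference procedure (forests of 1000/500 trees, 300
consensus replicates, 300 estimation iterations). The test suite and
`scripts/acceptance.py` run a desk-scale configuration chosen once for
single-CPU turnaround: forests of 100/50 trees, 50 consensus replicates
for expression (10 for methylation, whose planted signal is stronger),
15-point threshold grids, 20 estimation iterations, and 2–5 simulation
seeds per experiment. Recovery and AUC results were not sensitive to the
forest size at these problem sizes (a 100-tree forest on ≤ 90 samples
already stabilizes the OOB ranking).

## Known limitations

* Single-sample classification requires externally scaled expression
  input: the per-cohort z-scoring that the panels expect cannot be
  computed from one sample.
* ComBat is parametric-prior only; no reference-batch or nonparametric
  mode, and batch *detection* (e.g. by PCA) is out of scope — labels come
  from the sample sheet.
* The consensus varies only algorithmic randomness (forest bootstraps,
  CV folds) on a fixed training cohort; it does not resample patients.
* The combined 3-class model on all 15 features is provided for
  comparison only; on synthetic data its one-vs-rest AUCs do not exceed
  the dedicated panels'.
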