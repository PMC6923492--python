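# Methods

## Model

The combined essentiality score treats the CRISPR readout as the
regression target and everything else as predictors. For gene
*i = 1..M* and cell line *j = 1..N*,

CES_ij = β_j + θ_s·shRNA_ij + θ_m·MUT_ij + θ_c·CNV_ij +
θ_a·EXP.array_ij + θ_r·EXP.RNAseq_ij,

with coefficients minimizing Σ (CES_ij − CRISPR_ij)² over all complete
cells. The θ coefficients are shared across genes and cell lines; only
the intercept β_j is cell-line specific, so a single model is fitted
per dataset. The fitted value is algebraically identical to the
weighted average (1 − α_ij)·CRISPR_ij + α_ij·shRNA_ij with
α_ij = (CES_ij − CRISPR_ij)/(shRNA_ij − CRISPR_ij); α is reported
unclipped and left undefined where the two screens agree exactly,
since the weight is then indeterminate.

Assumptions worth stating plainly: the molecular features act linearly
and with the same weight for every gene; the CRISPR screen is the
anchor (the objective regresses toward it, so systematic CRISPR biases
propagate into CES); and inputs are z-scored within each cell line, so
all coefficients are on a common per-line standard-deviation scale.

## Normalization and missing data

Z-scoring uses the sample standard deviation (n − 1). A column with no
variation maps to all zeros — zero is the post-normalization mean, and
a globally constant column is subsequently dropped from the design as
exactly collinear. Columns with fewer than two observed values are an
error naming the cell line. The analysis is restricted to genes present
in both screens and all feature layers (see `io.align`); within that
set, any cell with a missing predictor is excluded from the objective
and receives a missing CES. Nothing is imputed: fabricating feature
values would feed invented signal into the score.

## Solver

The design matrix has one indicator column per cell line plus the five
slope columns; it is solved with a column-pivoted QR decomposition.
Rank is determined from the pivoted R diagonal with tolerance
`max(n, p)·eps·|R_00|`; exactly dependent columns are dropped in pivot
order, recorded in `dropped_columns`, and logged at warning level, so
degradation is reproducible and visible. The solver hard-errors only
when no complete cell exists; under- or barely-determined fits (fewer
observations than parameters) proceed with a warning because the
projection — the fitted values — is still unique even when individual
coefficients are not. Conventional OLS standard errors are attached to
the θ estimates for diagnostic use.

## Baselines

* **SA**: (CRISPR + shRNA)/2, the α = 0.5 reference.
* **Null model**: β_j + θ_s·shRNA_ij, molecular features removed.
* **Permutation model**: CES refitted after replacing the feature
  vector of every cell (i, j) with that of a different cell. The
  permutation is a single uniformly random cyclic derangement of the
  M·N cell indices (Sattolo's algorithm: guaranteed fixed-point free),
  applied jointly to all four layers so within-cell feature correlation
  survives while the link to the cell's own screens is broken. One
  global plan per fit, seeded (default 20191112).

## Evaluation

Genes are ranked within each cell line, rank 1 = most negative score;
ties receive the average rank, which preserves the rank-sum invariant.
The across-line mean of available ranks is the overall essentiality
score, reported with the number of lines used. ROC/AUC is oriented so
that positives scoring *lower* than negatives give AUC > 0.5
(implemented by negating scores before the standard ascending-score
AUC); tied pairs count one half. Method comparisons use the paired
DeLong test on the common labelled genes — placement values per class,
empirical covariance between methods, two-sided normal p-value — with a
degenerate-variance guard that reports p = 1 with a warning. SSMD is
(μ_pos − μ_neg)/√(σ²_pos + σ²_neg) with sample variances, per cell
line; under the sign convention better separation is more negative.
Hit-rate curves evaluate a single gene at integer rank thresholds
1..t_max (default 1000, the loosest cut-off of practical interest) and
normalize the area by t_max so it is a fraction in [0, 1].

Cell-specific essential genes are (gene, line) pairs with within-line
CES rank ≤ 100 while the gene's overall score is numerically > 5000 —
"average ranking below 5000" is read as *poorer* than 5000, since the
genes sought are specific, not common. A hit is flagged novel when the
gene's within-line rank is numerically > 2000 in both single-screen
rankings, i.e. neither technology alone would have called it. All three
cut-offs are configurable and validated against [1, M].

The between-screen consistency report gives per-line Pearson r and MSE
over shared genes, plus a permutation null: the shRNA column is
re-paired uniformly at random within the line (default 100 replicates,
seeded) and the mean permuted MSE reported. For independent z-scored
columns this concentrates at Var₁ + Var₂ = 2.

The per-gene biomarker regression fits OLS of one gene's CES across
cell lines on its four z-scored features plus an intercept (included
although the upstream model has per-line intercepts, because a single
gene's CES row need not be centred). P-values are nominal two-sided
t-tests on n − p degrees of freedom; no multiplicity correction is
applied inside the operation — a Benjamini–Hochberg helper
(`bh_adjust`) is provided for callers screening many genes. Zero-
variance features are dropped with a note; fewer than 8 usable cell
lines is an error.

## Synthetic data generator

The generator emulates the data-fusion setting, not any real release's
marginal distributions. Latent essentiality is a per-gene effect
g_i ~ N(0, 0.2²); a planted 20% of genes get a −1 shift (commonly
essential), 10% are labelled as the non-essential reference set (no
shift — they are ordinary genes that serve as gold-standard negatives),
and by default 5 genes are cell-specific. Both screens observe the
latent surface through independent noise of SD 1.3 plus a per-line
bias (SD 0.2, removed by z-scoring); with the latent spread this puts
the per-line between-screen Pearson r near 0.1, the weak-concordance
regime that motivates integration, and raising the noise SDs lowers r
monotonically. An optional shared-noise component
(`noise_correlation`) can correlate the two screens' errors.

Gaussian feature layers have mean w·(−E) with weights 0.5 (CNV), 0.6
(array), 0.45 (RNA-seq) and noise SD 0.2, so amplified/highly expressed
genes are the essential ones; mutation counts are Poisson with rate
0.15·exp(0.1·(−E)), a deliberately weak count-valued signal matching
mutation's minor role among essentiality biomarkers. The feature noise
is chosen small relative to the weights so that the features carry
decisive essentiality information — this is what makes the planted
cell-specific genes recoverable and the full model clearly separable
from its baselines at the default sizes; real feature panels are far
weaker predictors, so passing benchmarks here demonstrates correctness
of the machinery, not expected real-data effect sizes.

Cell-specific genes model the screen-specific false negative the
feature-aware score can rescue: their base effect is folded to the
non-essential side (|g_i|), the target line's latent value is shifted
by −3 — visible to the features — while both screens instead read the
gene near +3 in that line (clearly non-essential), mimicking reported
cases where a gene essential in one line carried positive scores in
both assays. Without the anti-essential screen readout the novelty flag
would be a coin flip: with ~20% of ranks inside a top-2000 cut-off, a
truly "null" readout lands inside it too often for a 5-gene recovery
check to be stable.

All randomness derives from one `SeedSequence` split deterministically
per matrix, so the same seed reproduces every matrix bit for bit and
regenerating one component does not disturb the others.

## Problem sizes and numerical choices in the test-suite

The reference conditions are 2000 genes × 20 cell lines (fit takes
well under a second); the cell-specific recovery scenario uses 10 000
genes so the default rank thresholds (100/5000/2000) are meaningful;
the permutation-MSE panel uses 5000 genes × 42 cell lines with 100
permutations per line. Replicate-based checks use 50 seeded replicates
(model-vs-baseline AUC, null-feature indistinguishability) or 1000
(DeLong type-I error). Oracle comparisons pin the QR solution to an
explicit normal-equations solve at 1e-8, the weighted-average
reconstruction at 1e-9 relative, and AUC to exhaustive pair counting
at 1e-12.

## Known limitations

* Global θ cannot express gene-specific feature effects; the per-gene
  biomarker regression is a post-hoc diagnostic, not a refit.
* Regressing toward CRISPR makes the integration asymmetric by design;
  datasets where shRNA is the more trustworthy assay would need the
  roles swapped.
* The generator's features are strong, conditionally independent
  Gaussian/Poisson signals; real molecular panels are correlated,
  heavy-tailed and far less informative, so synthetic benchmark
  numbers (AUCs near 1) do not forecast real-data performance.
* α is undefined where the screens agree exactly and unbounded where
  they nearly agree; downstream consumers should use the CES values,
  not α, for ranking.
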