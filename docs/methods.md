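# Methods

This note documents the statistical models implemented in `msmark`, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Proteomics preprocessing

NPX values are log2-scale relative protein abundances. Censoring below the
per-protein limit of detection (LOD) is handled by substituting LOD/√2, the
conventional imputation for left-censored log-scale assays; the operation is
idempotent and leaves detected values untouched. The detection filter keeps
proteins detected in **strictly more than** 25% of samples (a protein seen
in exactly 25/100 samples is dropped); the rate is evaluated on the matrix
passed in, so callers apply it per compartment and cohort stratum.

**Bridging harmonization.** When two panel runs are pooled, bridging
samples measured on both runs identify per-protein between-run offsets.
Per shared protein we compute the Pearson correlation *r* over bridging
samples (on the NPX scale) and, when *r* > 0.7 strictly, shift every run-2
value by Δ = median over bridging samples of (run1 − run2). The median is
translation-equivariant, so the post-correction median bridging difference
is exactly zero. Choices made here:

* offset statistic = **median** of paired differences (robust; the mean is
  available via `offset_stat="mean"`);
* correction is **additive on NPX** (equivalently multiplicative on the
  linear scale, since NPX is log2);
* proteins failing the gate are excluded from *pooled* matrices only; they
  remain available to per-cohort analyses and hence to the meta-analysis,
  which never mixes raw values across runs;
* fewer than 3 bridging samples is an error — a correlation gate on 2
  points is meaningless.

## miRNA QC and normalization

Serum libraries pass QC when they contain more than 100 distinct miRNAs
with count > 1 (diversity) and more than 1000 total counts; CSF libraries,
which are intrinsically less diverse, use a diversity gate of 50 with the
same size gate of 1000 (the size gate for CSF is config-exposed).
"Diversity" counts miRNAs with count **strictly greater than 1**.

Size factors are median-of-ratios: the reference profile is the per-miRNA
geometric mean over samples restricted to rows with no zeros; each sample's
factor is the median count/reference ratio, and factors are rescaled to
geometric mean 1. If no row is all-nonzero the method falls back to
total-count ratios (logged). The descriptive transform is
log2(count/s + 1); it feeds correlations, PCA and plots only — all
inference on counts uses the negative-binomial model, so this choice
cannot affect hit lists.

## Cross-sectional models

Two-group protein contrasts default to the Welch (unequal-variance) t-test;
k-group contrasts to one-way ANOVA. An optional Shapiro–Wilk gate at
α = 0.05 per group switches an analyte to the rank-based test
(Mann–Whitney / Kruskal–Wallis). Covariate-adjusted contrasts fit
`NPX ~ group + age + sex` by OLS and report the Wald test for the group
coefficient. Missing covariates cause listwise exclusion per analysis
(logged). BH-FDR is computed within one comparison family — one contrast ×
one compartment × one cohort — and the package-wide significance convention
is FDR < 0.1. Paired serum/CSF comparisons use the paired t-test on
per-individual differences and also report the cross-compartment Pearson
correlation per protein.

## Negative-binomial differential expression

Counts are modelled as NB with variance μ + αμ², log link, size-factor
offsets and fixed-effect covariates (technical batch as indicators, age
centred, sex). Dispersion estimation:

1. per-miRNA means from a Poisson GLM fit of the full design;
2. per-miRNA **Cox–Reid adjusted** ML dispersion (bounded scalar search in
   log α over [1e-8, 10]). The CR term −½ log|XᵀWX| compensates for the
   degrees of freedom absorbed by the mean fit; without it dispersions are
   biased low and the Wald test runs measurably anticonservative at the
   n ≈ 100 scale this package targets, which is why the adjustment is on;
3. a robust (soft-L1 in log space) fit of the parametric trend
   α(μ) = a₀ + a₁/μ across miRNAs;
4. log-normal shrinkage: MAP in log α with a normal prior centred at the
   trend, prior variance the MAD-based spread of gene-wise residuals
   floored at 0.25.

Inference is a Wald z-test on the contrast coefficient (converted to log2
units), BH across tested miRNAs. Deliberately **not** implemented, to keep
the tested set and the BH family transparent: outlier replacement, LFC
shrinkage, independent filtering. Only all-zero miRNAs are excluded. Exact
numerical parity with external DE packages is a non-goal; the model class
is the same.

## Meta-analysis

Candidates are analytes with nominal P below 0.1 in **at least one** cohort
(default; a both-cohorts rule is available — the selection wording is
ambiguous in this design and the choice is a flagged config entry; the
at-least-one rule yields candidate-set sizes in the expected range).
Fixed-effect combination is inverse-variance (w = 1/SE²); the
random-effects variant uses DerSimonian–Laird
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)). BH is applied across the selected
candidate set. 95% CIs are β ± 1.96·SE.

## Conversion-anchored trajectories

"Time from conversion" is (sample date − anchor)/365.25 where the anchor is
the individual's **first sample classified as secondary-progressive**;
status in the interaction model is derived from t (RR iff t < 0), not from
per-visit clinical labels. The slope model is `level ~ t (+ age + sex)`
over all converter samples; the interaction model adds status and t·status,
and a **peak call** requires a significant interaction (FDR < 0.1) together
with pre-slope > 0 and post-slope < 0. Markers with a significant slope
against time-since-first-sample in non-converting RR patients (nominal
P < 0.05) are flagged not conversion-specific. The anchor-correlation
filter keeps candidate miRNAs whose Pearson correlation with an anchor
protein (e.g. granzyme B) has two-sided nominal P < 0.05, sign reported.

Observations within an individual are treated as independent, matching the
model class being reimplemented; a cluster-robust SE option
(`cluster_robust=True`) is provided for sensitivity analyses. Whether
age/sex belong in the conversion models is not settled; they are included
by default and toggleable.

## Enrichment scoring

Signatures are the top-k (default 10) most highly expressed miRNAs per cell
type in an atlas table, ties at the boundary broken lexicographically (a
specificity-based z-score extraction would be a reasonable alternative;
the expression-based rule is the default because it is what a plain
"top expressed" reading implies). The single-sample score is the
ssGSEA-style weighted-KS statistic: rank miRNAs by expression (average
ranks on ties; the walk order breaks ties by name, deterministically), walk
down the list accumulating rank^w/Σrank^w for in-set miRNAs (w = 0.25)
against 1/(N−m) for out-set ones, and sum the in−out deviation over all
positions. The score is rank-based, hence invariant to monotone per-sample
transforms. Scores are normalized across samples by the global range.
GSVA's "gsva" kernel is a different statistic; matching both kernels at
once is impossible and the ssGSEA-style walk was chosen because it is fully
specified and oracle-testable by enumeration.

## Panel evaluation

Backward selection starts from the full logistic model and repeatedly drops
the feature whose removal most improves AIC (P-value-threshold elimination
was considered and rejected as less comparable across nested models).
Separation falls back to a ridge-stabilized fit (L2, α = 1e-3) with a
warning. CV uses stratified 10-fold splits with seed-reproducible
assignment; the reported AUC is mean ± SD across folds. By default
selection runs once on the full data — matching how such panels are
usually reported, at the cost of optimism — and an unbiased per-fold
selection mode is available (`select_per_fold=True`).

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study design: cohort I with 30 controls and 75 MS
patients (equal RR/SP/PP split — the subtype split is not fixed by the
design, equal was chosen once) with paired serum/CSF on panel run 1;
cohort II with 93 MS patients (26 non-converting RR, 12 converters, 35 SP,
20 PP) on run 2; 92 proteins; 11 bridging samples; converters with 7
six-monthly visits anchored at visit 5.

NPX values are Gaussian: protein baseline N(5, 1) + subtype effects
(1.0 NPX on 10 proteins, half MS-vs-control, half stage) + 0.01·age +
0.1·sex + compartment shift (serum − CSF = 1.0) + a per-sample biological
deviation (SD 1.0, shared by re-measurements of the same aliquot — this is
what makes bridging correlations informative) + technical noise (SD 0.5;
the assay's noise scale is a free choice, config-exposed). Run-2 offsets
are U(−1, 1) per protein. The LOD sits at the 5% quantile of the marginal
serum distribution and censored values are emitted as below-LOD flags, so
the imputation path is always exercised.

The converter peak is **piecewise-linear** ("tent"):
baseline + a·(1 − |t|/w)₊ with a = 1.5 NPX (3σ) and w = 2 years — chosen
over a Gaussian bump because the two-slope interaction analysis is then
analytically interpretable (true pre/post slopes ±a/w). Drift proteins
change linearly in everyone and exist to exercise the non-converter
control.

miRNA counts are NB (dispersion 0.2) with log-normal size factors
(σ = 0.4), per-miRNA batch/age/sex coefficients, SP fold changes (log2FC
±1 on 20 background miRNAs) and latent cell-type activities λ loading the
signature miRNAs: CSF samples load brain cell types (+1.5 log2), serum
samples mildly load immune types, and converter samples couple immune-type
λ to the tent peak and a pericyte-like λ to its negation.

Not emulated: raw reads and alignment, isomiRs, hemolysis and other
pre-analytical artefacts, plate/batch structure in the proteomics beyond
the run offset, informative dropout beyond LOD censoring, correlated
protein–protein structure, and real atlas content (the packaged atlas is a
small synthetic toy). Tests passing on these generators therefore
demonstrate correctness of the estimators under the assumed model class —
not robustness to every failure mode of real cohort data.

## Problem sizes used by the acceptance run

The acceptance script uses the full default cross-sectional design, a
1000-miRNA null with 50 samples per group for Wald calibration, 50
replicates of the 30-protein converter design for peak recovery, and 30
replicates of the 12-converter enrichment pipeline; these sizes give
stable Monte-Carlo estimates while keeping the whole run under a minute.

## Known limitations

* The NB Wald test is slightly liberal in small samples (z rather than t
  reference); at the package's target n it stays within [0.03, 0.07] at
  nominal 0.05, which is the calibration the test suite enforces.
* Median-of-ratios size factors absorb part of the signal when a large,
  direction-imbalanced fraction of a small panel is differential; with
  ≤5–10% differential miRNAs the log2FC bias is negligible, and the test
  suite documents the effect.
* Trajectory fits treat repeated samples of an individual as independent;
  the cluster-robust option quantifies the consequence but no mixed model
  is provided.
* Full-data backward selection before CV is optimistic; use
  `select_per_fold=True` for honest AUCs.
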