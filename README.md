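# msmark

Biomarker discovery for **multiple sclerosis (MS) stage** from two classes of
circulating analytes: inflammatory proteins measured by targeted proximity
extension assays (reported in NPX units, a log2-scale normalized protein
expression) and cell-free miRNAs measured by small-RNA sequencing, in serum
and cerebrospinal fluid (CSF).

The package is aimed at biostatisticians analysing case–control and
prospective MS cohorts. It covers the full analysis chain:

- **Proteomics QC** — below-LOD values replaced by LOD/√2, a strict >25%
  detection filter, and cross-run harmonization via bridging samples: for
  each protein shared by two panel runs, the Pearson correlation *r* over
  re-measured bridging samples gates (r > 0.7) an additive per-protein
  offset Δ = median(run1 − run2) applied to the second run.
- **miRNA library QC and normalization** — compartment-specific diversity
  gates (>100 distinct miRNAs with count >1 in serum, >50 in CSF; total
  counts >1000), DESeq2-style median-of-ratios size factors, and
  log2(count/s + 1) for descriptive use.
- **Cross-sectional statistics** — Welch t / ANOVA (optionally rank-based
  behind a Shapiro–Wilk gate), covariate-adjusted linear models
  `NPX ~ group + age + sex`, paired serum-vs-CSF comparisons, and
  Benjamini–Hochberg FDR within each comparison family (significance at
  FDR < 0.1 throughout).
- **Negative-binomial differential expression** for miRNA counts:
  `K_ij ~ NB(s_j q_ij, α_i)` with log link, covariates (batch, age, sex),
  Cox–Reid adjusted ML dispersions shrunk toward a parametric trend
  α(μ) = a₀ + a₁/μ, and Wald tests reported as log2 fold changes.
- **Cross-cohort meta-analysis** — candidates with nominal P < 0.1 per
  cohort combined by inverse-variance fixed effects
  (β = Σwβ/Σw, w = 1/SE²) with a DerSimonian–Laird random-effects variant.
- **Conversion-anchored trajectories** — "time from conversion" t (years)
  anchored at each converter's first secondary-progressive sample; slope
  models `level ~ t`, and interaction models `level ~ t + status + t·status`
  whose significant interaction with positive pre-slope and negative
  post-slope defines a *peak* call (the granzyme-B pattern around
  conversion); drifting markers are disqualified via non-converting
  relapsing–remitting patients.
- **Cell-type enrichment** — top-10 signature miRNAs per cell type from an
  expression atlas, scored per sample by an ssGSEA-style weighted
  Kolmogorov–Smirnov rank walk; scores associated with an anchor protein
  and with time from conversion.
- **Panel evaluation** — AIC backward selection over logistic models and
  stratified 10-fold cross-validated ROC/AUC.
- **Synthetic data** — generators that emulate the full study design
  (two cohorts, paired compartments, two panel runs with 11 bridging
  samples, NB counts with latent cell-type loadings, converters with a
  piecewise-linear "tent" peak) with truth tables for recovery scoring.

## Worked example

Recover the planted conversion peak from a synthetic longitudinal cohort
(12 converters, 7 visits each, peak amplitude 3σ):

```python
import msmark as mk

cfg = mk.SimConfig(n_proteins=12, seed=1)
npx, meta, truth = mk.simulate_converter_trajectories(cfg)

conv = meta.loc[meta["converter"]]
t = mk.time_from_conversion(conv)            # years from first SP sample
res = mk.interaction_model(npx.subset(samples=list(t.index)), meta, t)
print(res[["analyte_id", "pre_slope", "post_slope", "p", "fdr", "peak"]].head(6).round(4))
```

```
analyte_id  pre_slope  post_slope      p    fdr  peak
      P001     0.8863     -0.6663 0.0000 0.0000  True
      P002     0.8744     -0.8110 0.0000 0.0000  True
      P003     0.9321     -0.6635 0.0000 0.0000  True
      P004    -0.2096     -0.3691 0.5009 0.6679 False
      P005    -0.3942     -0.2701 0.5920 0.7104 False
      P006    -0.3712     -0.1414 0.3028 0.5192 False
```

The three proteins simulated with the tent peak (amplitude 1.5 NPX over a
2-year half-width, so a true pre-slope of +0.75 NPX/year and post-slope of
−0.75) are exactly the three *peak* calls; their estimated slopes bracket
the truth within sampling error, and the flat proteins stay null.

A command-line interface mirrors the library
(`msmark simulate|protqc|mirnaqc|crosssec|mirnade|meta|convert-assoc|enrich|panel`),
e.g.:

```bash
msmark simulate --seed 3 --out study/
msmark protqc --npx study/npx_run1.csv --lod study/lod.csv \
      --npx2 study/npx_run2.csv --lod2 study/lod_run2.csv \
      --bridging study/bridging_ids.txt --out study/qc/
```

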