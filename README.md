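# cafkit

Analysis toolkit for the tumor stroma of early luminal breast cancer:
quantitative immunohistochemistry (IHC) scoring, classification of
cancer-associated fibroblast (CAF) subsets from marker panels,
cellular-scale CAF-subset maps from serial sections, and the matched
case-control survival statistics linking the activated CAF-S1 subset to
distant relapse. It is written for computational pathology and
translational-oncology groups who quantify stromal heterogeneity from
IHC and need every stage — scoring, classification, mapping,
statistics — reproducible and testable, including on fully synthetic
data with known ground truth.

## The model

**H-score.** A marker's staining on a section is summarized as
H = Σᵢ i·pᵢ, where pᵢ is the percent of scored cells at intensity
i ∈ {0,1,2,3}; H ∈ [0, 300]. Cohort-level marker levels are
dichotomized at the median (low strictly below, high otherwise), and
FAP is optionally stratified into three groups (≤47 / 47–95 / >95).

**CAF subsets.** Four subsets are defined by quartile-level expression
of five stromal markers (FAP, αSMA, CD29, FSP1, PDGFRβ):

| subset | CD29 | FAP | FSP1 | αSMA | PDGFRβ |
|--------|------|-----|------|------|--------|
| CAF-S1 | Med | Hi | Low–Hi | Hi | Med–Hi |
| CAF-S2 | Low | Neg | Neg–Low | Neg | Neg |
| CAF-S3 | Med | Neg | Med–Hi | Neg–Low | Med |
| CAF-S4 | Hi | Neg–Low | Low–Med | Hi | Low–Med |

Each marker value is binned against the population quartiles
(Neg < Q1 ≤ Low < med ≤ Med < Q3 ≤ Hi) and the sample is assigned a
subset either by an ordered quartile decision tree (shipped as YAML
configuration, replaceable) or by nearest-archetype matching against
the profiles above.

**Subset maps.** Serial sections stained for CD29, FAP, SMA and FSP1
are registered onto a reference section via manually placed landmark
pairs (affine or thin-plate-spline warp), unmixed by color
deconvolution under the Beer–Lambert model (OD = −log₁₀ I/I₀), tiled
into 225 µm² tiles (≈ one fibroblast), and each stromal tile is
classified with the same decision tree on its mean DAB optical
densities; epithelial tiles are masked.

**Statistics.** Case-control contrasts use the two-sided Fisher exact
test (2×2), Shapiro-gated t / Wilcoxon comparisons, and Spearman
correlation. Distant progression-free survival (distant metastasis as
the event; local/regional relapse and death censor) is analyzed by
Kaplan-Meier with the log-rank test and Cox proportional-hazards
models; covariates entering the multivariate model must pass a
p < 0.20 univariate screen. Controls are matched 1:1 to cases by
greedy nearest-neighbor (exact grade; ±5 year age and ±10 point Ki67
calipers).

**Synthetic data.** `cafkit.synthetic` generates (a) cohorts with a
latent CAF subset per patient, profile-consistent marker H-scores, an
exponential proportional-hazards relapse model (CAF-S1 hazard ratio 5
by default) and case-depressed CD4 densities; and (b) serial-section
stacks with known subset territories, per-section smooth warps encoded
in landmark pairs, and a tile-aligned epithelium mask — so the full
pipeline can be validated against exact ground truth.

## Worked example

`examples/03_case_control_stats.py` generates the default synthetic
cohort (52 cases, a 500-patient control pool, CAF-S1 hazard ratio 5),
matches controls and runs the battery:

```
cohort: 552 patients, 52 cases
matched pairs: 49 (unmatched 3)
CAF-S1 enrichment: 38.5% of cases vs 10.1% of controls (Fisher p = 6.36e-07, OR = 5.58)
CD4 density medians: cases 11.5 vs controls 19.6 /mm^2 (wilcoxon p = 9e-05)
log-rank CAF-S1 vs rest: chi2 = 16.1, p = 6.1e-05

Cox table (multivariate after p < 0.20 univariate screen):
  caf_s1                   HR 2.38 [1.28-4.42] p=0.00607 (kept)
  cd4_density_high         HR 0.46 [0.25-0.86] p=0.0147 (kept)
  macrophage_density_high  HR 0.73 [0.41-1.30] p=0.285 (kept)
  vessel_fraction_high     HR 0.71 [0.41-1.25] p=0.24 (dropped by screen)
```

Cases are enriched in CAF-S1 and depleted in CD4⁺ T cells, and CAF-S1
enrichment stays associated with distant relapse in the multivariate
model — the qualitative structure the generator encodes. The other
examples cover scoring (`01`), classification (`02`) and the
serial-section subset map (`04`, which prints a tile-label accuracy of
1.000 against ground truth and writes the rendered map).

A thin CLI mirrors the stages:
`cafkit simulate|score|subtype|map|stats|run` (see `cafkit --help`).

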