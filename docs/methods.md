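# Methods

This note documents the models, conventions and design choices behind
cafkit, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## IHC scoring

The H-score of a marker is the intensity-weighted percentage of
stained cells, H = Σᵢ i·pᵢ with i ∈ {0..3}, so H ∈ [0, 300] and is
linear in the intensity histogram. The wording used in pathology
protocols is ambiguous between a full 0–3 histogram and a single
global intensity per sample; both are supported, the latter as the
degenerate histogram with all mass at one intensity, and both respect
the [0, 300] range.

Marker dichotomization uses the cohort median (linear-interpolation
quantile, the numpy default); a value strictly below the median is
"low", otherwise "high" — so an all-tied cohort is all "high". The
three-category FAP stratification uses H ≤ 47 / 47 < H ≤ 95 / H > 95.

Immune densities are counts divided by summed field area (default
field 1.65 mm² at ×10). The CD31 vessel fraction is the per-field
CD31⁺ area percent divided by the stromal proportion of the same
field, averaged over fields; a field with zero stroma is rejected by
index rather than silently dropped. The CD31 field area default is
1.596 mm² and configurable. The adiposity score bins the adipose
surface percent as [0,1) → 0, [1,10] → 1, (10,30] → 2, (30,100] → 3;
the published anchors leave (10, 11) unassigned, and the half-open
cover above is the unique exhaustive completion that keeps the stated
anchors ("less than 1%", "between 1 and 10", "superior to 30").

## Subset classification

Per marker, quartile thresholds (Q1, median, Q3; linear interpolation)
define four bins: Neg (< Q1), Low ([Q1, med)), Med ([med, Q3)), Hi
(≥ Q3). This is the only exhaustive four-bin reading of
"quartiles and median" and makes binning a total function on the
nonnegative reals, including degenerate (collapsed) thresholds.

Two classification modes operate on a `MarkerPanel`:

* **tree mode** — an ordered decision list, each rule comparing one
  marker value against one named threshold. The shipped default
  (`data/default_tree.yaml`) is FAP ≥ Q3 → CAF-S1; αSMA ≥ med →
  CAF-S4; CD29 ≥ med → CAF-S3; else CAF-S2. The published tree exists
  only as a figure whose node structure is not recoverable from text,
  so the default is *derived from the subset profiles*: it is the
  shallowest ordered list under which each subset's archetype
  bin-vector reaches its own leaf, and it deliberately references only
  FAP/αSMA/CD29 so the identical tree runs at tumor level (H-scores)
  and at tile level, where only CD29/FAP/SMA/FSP1 are imaged. The tree
  is configuration, not code: a user transcription of the original
  figure drops in without code changes, and the `provenance` field
  records which tree produced a result.
* **archetype mode** — the subset whose profile permits the most of
  the panel's bins wins; ties break by the fixed priority
  S1 > S4 > S3 > S2 (activated subsets first; configurable). Profile
  ranges such as "Low–Hi" are treated as the set {Low, Med, Hi}.

The two modes agree on every bin-vector that exactly matches a unique
profile (verified by exhaustive enumeration of all 4⁵ vectors).
Thresholds for tumor-level calls are fitted on the analyzed cohort by
default; external (learning-set or generator) thresholds can be
supplied, which matters for skewed cohorts (see below). PDGFRβ is
excluded from tile-level classification because the mapping protocol
images only CD29, FAP, SMA and FSP1.

Rendering colors are CAF-S1 red, CAF-S2 orange, CAF-S3 green, CAF-S4
blue; masked epithelium gray, discarded edge tiles black.

## Serial-section maps

Registration is landmark-driven: an affine fit (least squares, ≥ 3
non-collinear pairs) or a thin-plate spline (scipy RBF, smoothing λ,
default 0.1; λ = 0 interpolates the landmarks exactly, and the
landmark RMS residual is nondecreasing in λ). The original workflow
used a B-spline elastic tool; what is reproduced here is the contract
— landmark correspondence plus a smooth warp — not that tool. The
fitted transform is the backward map (reference → moving) and images
are resampled bilinearly; mapped coordinates within 1e-6 of an integer
are snapped so identity and integer-shift transforms reproduce pixel
values bitwise.

Color deconvolution follows Beer–Lambert: per channel
OD = −log₁₀(max(I, 1)/I₀), unmixed with the inverse stain matrix.
Default stain vectors are the standard H-DAB pair, hematoxylin
(0.650, 0.704, 0.286) and DAB (0.269, 0.568, 0.778), with the residual
channel their normalized cross product; all overridable. Negative
unmixed densities are clamped to zero and the clamp rate reported.
Densitometry uses OD, not raw intensity, because OD is linear in
chromogen concentration.

Tiles are 15 µm × 15 µm (225 µm², about one fibroblast), half-open,
row-major, 0-based, with the side required to be a whole number of
pixels. Full tiles with ≥ 50% epithelial pixels are masked; partial
edge tiles are discarded but counted, so stromal + masked + edge
equals the grid total. Tile thresholds are quartiles over the section
set's own stromal tiles — the tile-scale analogue of cohort-relative
thresholds; the reference population for tile-level calls is not
standardized anywhere, so the section set itself is the least
arbitrary choice and external thresholds remain possible.

## Case-control statistics

* **Fisher exact (2×2)**: two-sided by the "probability ≤ observed"
  rule over the hypergeometric support, with 1 + 1e-7 relative slack
  for float ties (the convention that reproduces the published
  contingency p-values after rounding). Implemented by explicit
  support enumeration; tests cross-check against an independent
  binomial-coefficient oracle and scipy. One published row (axillary
  relapse, printed 0.05) is *not* reproduced by this rule (enumeration
  gives ≈ 0.057); it is left as a documented discrepancy rather than
  forced.
* **Group comparisons**: Shapiro-Wilk gate at α = 0.05 per group; both
  normal → two-sample t, else Wilcoxon rank-sum (tie-corrected normal
  approximation). Constant samples are treated as failing the gate.
* **Survival**: the event is distant metastasis; local, contralateral
  and axillary relapse and death without distant metastasis censor
  (competing-risks treatment is out of scope). Kaplan-Meier and Cox
  (Efron ties) come from lifelines; the log-rank statistic is the
  standard observed-minus-expected form. Multivariate Cox models
  include only covariates with univariate p < 0.20. Continuous
  covariates can be reported per k-unit change (e.g. per decrease of
  50 H-score points: HR = exp(−50β)); the p-value is scale-invariant.
* **Matching**: greedy 1:1 nearest neighbor without replacement —
  exact on grade, calipers ±5 years age and ±10 points Ki67, distance
  caliper-normalized Euclidean; case order is id-sorted then
  seed-shuffled. The pairing is deterministic per seed and every
  emitted pair satisfies the matching rule by construction; the greedy
  match count is not guaranteed globally maximal.
* Two-sided α = 0.05 throughout; no multiplicity correction.

## Synthetic data: what it emulates and what it does not

**Cohorts.** Each patient draws a latent subset from a prevalence
vector (default 14.4 / 42.3 / 13.5 / 29.8 %, the reported luminal-BC
mix). Marker H-scores are sampled uniformly within the value interval
spanned by the subset profile's permitted quartile bands of a
*reference population* — an equal-weight four-component truncated
normal mixture on [0, 300] (means 40/115/185/260, SD 28, n = 2000 per
marker). Published data constrain only the quartile-level profiles,
not the marginal H-score distributions, so these marginals are
stipulated, not fitted. Because subset prevalence shifts the pooled
cohort distribution, the pooled cohort's own quartiles do not
reproduce the generating bands when the mix is skewed; classification
with the *generating* reference thresholds is exact, and that is what
the prevalence-recovery tests use. Survival is exponential
proportional hazards on the latent CAF-S1 indicator (default HR 5,
matching the magnitude of the reported multivariate association;
baseline 8·10⁻⁴ events/month; administrative censoring at 120
months). Cases are patients whose distant event is realized before
censoring, drawn until the requested count; controls come from the
event-free pool. CD4 density is log-normal with the case multiplier
11.2/18.2 (the ratio of the reported medians). Treatment effects on
hazard are deliberately not modeled.

**Sections.** The subset layout is generated at *tile resolution*
(compact nearest-seed territories) and upsampled, so every full tile
is pure — tile-level ground truth is then well defined and the ≥ 99%
noise-free map-accuracy oracle is meaningful. Subset tile quotas are
balanced up to a rounding that places each decision threshold's
below-gap tile count on a linear-interpolation quantile seam
(k − 1 < (n−1)p ≤ k), which is what makes section-set quartile
thresholds land in the gaps between the default per-subset mean DAB
ODs — the sense in which the default OD table "guarantees
recoverability". The epithelium is a tile-aligned disk. Non-reference
sections carry a rigid motion plus a one-period sinusoid, jointly
tapered to zero at the image boundary (so no out-of-frame tissue is
ever needed) and normalized to a peak displacement of
`warp_amplitude` pixels; the landmark pairs encode the warp exactly.
Measurement noise is `od_noise_sd` × a unit-variance field drawn
independently of the SD, so stacks at different noise levels from one
seed share their noise pattern (common random numbers) and per-tile
accuracy is monotone in the noise SD by construction. Images are
8-bit RGB, so the pipeline sees realistic quantization.

Not emulated: tissue texture, nucleus-level structure, scanner
intensity variation, stain cross-talk beyond the H-DAB matrix,
non-smooth (tearing/folding) deformations. Passing the synthetic
oracles therefore shows the pipeline's *algorithmic* correctness —
registration, unmixing, tiling, thresholding, classification — not
robustness to real-slide artifacts.

## Numerical choices and problem sizes

Quantiles are linear-interpolation order statistics everywhere, fixed
for reproducibility. All generators are pure functions of (params,
seed) via `numpy.random.default_rng`. Degenerate inputs fail loudly:
empty cohorts, < 4 values per marker, zero-stroma fields, singular
stain matrices, collinear landmarks, all-masked tile tables.

Validation sizes were chosen to make Monte-Carlo error small relative
to the tolerances they support: Cox recovery uses 200 replicates of
n = 2000 (log-HR bias < 5%, CI coverage ≥ 93%); null calibration uses
500 replicates (Kolmogorov–Smirnov uniformity at p > 0.01); the map
oracle uses 256×256 px stacks, four markers, 10 landmarks, warp peak
5 px, noise ladder 0 / 0.05 / 0.1 / 0.2 OD, averaged over 3 seeds.

## Known limitations

The default decision tree is a profile-consistent derivation, not a
transcription of the original figure; results driven by node order on
off-archetype panels may differ from the original tool (the YAML
provenance field makes this auditable). Epithelium masks are inputs;
the mapping pipeline does not segment epithelium (a hematoxylin-OD
threshold fallback would be possible but is not claimed to be
reliable). Greedy matching is order-dependent; competing-risks
survival, propensity matching and whole-slide pyramidal I/O are out of
scope.
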