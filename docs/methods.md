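# Methods

## The measurement

An H-score summarises IHC staining of one tissue region on a 0–300 scale.
Each cell (manual reading) or unit of area (digital reading) is graded into
four intensity classes — 0 none, 1 weak, 2 moderate ("mild" accepted as an
alias), 3 strong — and the class percentages are combined as
`H = 3·p₃ + 2·p₂ + 1·p₁`. Scores are kept as floats; rounding to report
precision happens only at table-formatting time. Scoring is over the whole
provided region: no hotspot or field selection is modelled.

## Synthetic cohorts

No patient-level data are public, so cohorts are simulated from the
reported group structure. Per (marker, diagnosis) group an H-score is drawn
from Normal(mean, sd); the defaults are the combined-analysis groups
(cirrhosis-only n=28: TGFBR1 196.1 ± 44.6, TGFBR2 145.2 ± 78.9; HCC n=53:
TGFBR1 174.6 ± 62.6, TGFBR2 113.7 ± 67.9) and, for the paired analysis,
the discovery-set tumor/TAT groups (TGFBR1 165.0 ± 56.6 vs 232.9 ± 36.6
over 69 pairs; TGFBR2 105.8 ± 56.9 vs 202.3 ± 55.5 over 67 pairs).

Choices that the source summaries do not determine:

- **Clipping.** `clip=False` by default: draws are not truncated to
  [0, 300], so sample moments converge exactly to the configured values
  (truncation would bias both mean and SD). `clip=True` is available where
  physical support matters. Consequently the [0, 300] scale is treated as
  nominal on records; tally- and fraction-derived scores are in range by
  construction.
- **Correlations.** No within-patient or cross-marker correlations are
  reported. Defaults: `cross_marker_rho = 0` (independence reproduces the
  published discrimination of the two-marker model well — the simulated
  AUROC is ≈ 0.66 against the published 0.67) and `paired_rho = 0.5`, a
  moderate within-patient correlation typical of repeated tissue
  measurements. Both are stated defaults, not estimates.
- **Exclusions.** Non-evaluable samples (mixed cholangiocarcinoma, damaged
  tissue) are simulated as a metadata flag with configurable prevalence
  (default 0) so the filter is exercisable.
- **Missing pair members** occur with a configurable per-pair rate, the
  missing side chosen at random.

The generator emulates group means, spreads, pairing and missingness — not
the skewness, site batch effects, or measurement granularity of real
pathologist scores. Tests passing under it show the *machinery* is correct
under the stated model, not that the biomarker performs as published on
new tissue.

The cell-tally generator inverts the H-score formula deterministically:
the target/100 value is split over the two adjacent intensity classes that
bracket it (the two-class solution with the smallest largest share), then
rounded to integer counts by largest remainder, giving a quantization
error of at most 300/n_cells.

Label-map slides allocate pixels to regions and intensity classes by
largest-remainder apportionment (realised area fractions exact to one
pixel) with classes scattered uniformly within each region; the stain
channel is Normal(mean_k, sd_k) per class, truncated at 0, and background
carries zero signal. Ground-truth layers are stored alongside the noisy
channel.

## Image quantification

The trained deep-learning segmentation of the original workflow is
deliberately replaced by fixed-threshold classification on the continuous
stain channel: three strictly ascending cut points, half-open intervals,
boundary values joining the upper class. Region H-scores are
area-weighted: intensity fractions among a parent class's pixels composed
with the H-score formula. Annotation error is the percentage of evaluated
pixels that disagree with ground truth; background is excluded from the
denominator by default. Error rates measured here are properties of the
synthetic fixture and are not comparable to the error rates of the
original trained models.

## Statistics

- Between-patient comparisons (HCC vs cirrhosis-only — different people)
  use Welch's unpaired t-test; within-patient comparisons (HCC vs TAT on
  the same slide) use the paired t-test on complete pairs. The source
  analyses do not state which variance treatment produced each printed
  p-value, so recomputed p-values are treated as order-of-magnitude
  bounds, not exact targets.
- Sample SD uses the n−1 denominator throughout; singleton groups report
  SD as missing.
- `pooled_mixture_summary` combines (n, mean, sd) triples exactly:
  `s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−M)²]/(n−1)`, identical to summarising the
  concatenated raw data (property-tested).
- Paired differences with zero variance have an unbounded t; the p-value
  is reported as the smallest positive float rather than 0.
- No multiple-testing correction is applied anywhere, matching the
  source analysis.

## Matched pairs

"TAT 10% higher" is read multiplicatively and strictly: `tat > 1.1·hcc`.
Under this reading the margin flag implies the plain lower-in-tumor flag
for non-negative scores, and both published percentage columns are
reproduced from the published counts. With `hcc = 0`, any positive TAT
counts as exceeding. Report percentages are rounded half-up to whole
numbers; zero denominators give missing percentages.

## Threshold diagnostics

HCC is the positive class, predicted when the H-score (or the modelled
probability of cirrhosis) is **strictly below** the threshold; ties
classify as cirrhosis-only. This orientation is fixed by the published
interval widths (sensitivity denominators of ~53 match the HCC group,
specificity of 1 at the lowest TGFBR1 cut is only possible with cirrhosis
as the negative class). Confidence intervals are Wald with z = 1.96, no
continuity correction and no truncation — degenerate proportions give
zero-width intervals and proportions near 1 at small n may have upper
bounds above 1, as in the published tables. Report cells round half-up to
2 decimals.

## Risk model

Event coding: cirrhosis-only = 1 (the model predicts Prob(cirrhosis));
the diagnostic positive class remains HCC via the probability threshold
rule. Fitting is Newton–Raphson/IRLS from a zero start, convergence when
the largest coefficient update is below 1e-8, capped at 50 iterations;
the covariance is the inverse observed information. Quasi-separated data
(no convergence, singular information, or fitted probabilities at machine
0/1) are returned flagged non-converged; odds ratios refuse non-converged
models. Odds-ratio intervals are Wald (`exp(β ± 1.96·SE)`); profile
likelihood is not implemented.

The published coefficient set ships frozen as `PUBLISHED_MODEL` (no
covariance, so its odds ratios carry no intervals) and is used for scoring
without refitting; refitting on data is a separate call.

AUROC is rank-based (Mann–Whitney with midranks), oriented so 1.0 means
every cirrhosis sample outranks every HCC sample; it is invariant to
monotone transforms, so linear risk and probability give the same value.
Calibration splits samples into 5 near-equal bins by ascending predicted
probability (stable sort, ties to the lower bin) and fits an ordinary
least-squares line through (mean predicted, observed incidence); constant
predictions make the slope undefined (reported missing). Under a
correctly specified simulation calibration is near-ideal (slope ≈ 1,
intercept ≈ 0); the flatter published calibration reflects the original
private data and is not a simulation target.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerance: moment recovery at n = 10⁴ (tolerance 3
standard errors), closed-form sensitivity recovery at n = 2×10⁵
(tolerance 0.005 against Φ((t−μ)/σ)), parameter recovery at n = 5,000
(within 3 reported SEs), Wald-CI coverage over 60 refits (binomial
3σ band), type-I error over 1,000 Welch tests (binomial 3σ band around
0.05), and headline recovery of the published simulated quantities at
n = 10⁵ per group within ±0.05 absolute. The full pipeline runs the
published group sizes (n = 81 model samples), where sampling noise in any
single run is expected and visible in the report tables.

## Known limitations

- Normal group distributions cannot capture floor/ceiling effects of real
  H-scores near 0 or 300; unclipped draws may slightly exceed the scale.
- The image stage models neither morphology, nuclei, stain deconvolution
  nor whole-slide formats; it quantifies given label maps only.
- Correlation defaults are assumptions; conclusions sensitive to
  within-patient correlation (e.g. paired-test power) should sweep
  `paired_rho`.
- Exact confusion counts behind the published sweep tables are not
  printed; only counts consistent with the printed proportions and group
  sizes can be reconstructed for verification.
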