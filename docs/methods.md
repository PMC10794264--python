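# Methods

## Delta calculus

All isotope arithmetic is anchored to R_VPDB = 0.0112372, the ¹³C/¹²C
ratio of the VPDB standard. Deltas are stored at full precision in mUr
(exactly synonymous with per mil; the unit is stored once and never
converted) and rounded to two decimals only at presentation. Atom
fractions ¹³C/(¹³C+¹²C) are stored as fractions and shown as %¹³C.
δ = −1000 mUr corresponds to R = 0 and is rejected as input; every
conversion is strictly monotone and round-trips to 1e−12 relative
tolerance, which the property tests assert over δ ∈ (−999, +1000).

## VPDB normalization

One ordinary-least-squares line per instrument sequence maps measured
CRM deltas to their certified values; the model (slope, intercept, R²,
n) is applied unchanged to unknowns in that sequence. We regress
certified on measured — the wording "measured vs. true" leaves the
regressor ambiguous, and at R² > 0.999 the two directions are
numerically indistinguishable, so the direction that applies directly
to unknowns was chosen and is documented here rather than inferred.
The R² gate (default 0.999) logs a warning instead of failing: it is a
QC observation, not an exclusion rule. The shipped certified values
for USGS70/71/72 (−30.53, −10.50, −1.54 mUr) are placeholders at the
public reference-sheet values; users should supply their own lot
certificates via configuration. Measurement SDs pass through the
normalization unchanged (the slope is ~1 at natural abundance, so the
scale distortion of the uncertainty is negligible).

## Methyl-carbon correction

The balance n_FAME·δ_FAME = δ_ME + n_FA·δ_FA carries an implicit
weight of one carbon on δ_ME; we encode n_ME = 1 explicitly for
dimensional consistency. δ_ME defaults to −41.56 mUr and is a
per-batch configurable; `methyl_delta` derives it from a measured
methylated/unmethylated 17:0 pair when one is available. The
correction is linear in δ_FAME with slope n_FAME/n_FA > 1, so
first-order SD propagation is exact, and the correction magnitude
shrinks with chain length (one methyl carbon diluted among more
fatty-acid carbons) — both property-tested for n_FA 12–24.

## Quantification

amount_i = (area_i / area_IS) × amount_IS, with response factors
defaulting to 1.0 for every FAME (a per-species table can override).
The 17:0 internal standard is exogenous and therefore excluded from
the relative-percent denominator; zero-area analytes are retained as
zeros so denominators stay comparable across samples. Relative
percents sum to 100 per sample to 1e−9 and all outputs are invariant
to a common scaling of areas.

## End-member signatures

Default pooling is "replicate" mode — the arithmetic mean of component
deltas with their n−1 sample SD — because with equal technical
replication per component that is the correct pooled estimate; it
yields −11.15 ± 0.65 mUr for the sucrose/cornstarch/maltodextrin
carbohydrate blend. Energy weighting is available as an option and
moves the mean by < 0.15 mUr (to ≈ −11.06) for this blend; the
difference is documented rather than hidden. Soybean-oil fatty acids
(1.2% energy, uncharacterized) are excluded from end-member
construction. Casein's −23.88 mUr is carried in the diet table for
completeness only: protein carbon routing into lipogenesis is not
modelled. The built-in diet table's listed components sum to 98.18%
energy (minor uncharacterized ingredients are unlisted), so validation
asserts per-macro-class totals rather than a 100% sum.

## Mixing model

Two-end-member linear mixing in δ space:
f = (δ_tissue − δ_fat)/(δ_sugar − δ_fat). An atom-fraction-space
variant is provided; at natural abundance the two differ by < 0.1% of
the fraction, so δ space is the default. This is a deliberate
simplification — no blood-pool correction, no third source — and its
output is interpreted as a bound on the sugar-derived contribution.
Raw fractions outside [0, 1] (tissue more depleted than the fat
end-member, e.g. when ketone bodies or amino acids feed the
acetyl-CoA pool) are clamped and flagged rather than silently
truncated. A diet with no palmitate has no fat end-member; the
substitute is the mean of the other diets' dietary-PAM deltas with
SDs pooled in quadrature, flagged `substituted_endmember`. End-member
separations below 1 mUr are rejected as degenerate. Uncertainty:
delta-method propagation (exact to first order for this ratio of
Gaussians) or Monte-Carlo with 10,000 draws, seed 20240117, clipped to
[0, 1]; the two agree to within 15% of interval width whenever all
input SDs are below 1 mUr, which a test asserts.

## Group statistics

α = 0.05 throughout. ROUT screening applies to the constant
(one-sample) model only: location is the median, scale the 68.27th
percentile of absolute residuals times N/(N−K) (K = 1), residual
t-scores (df = N−1) are tested outermost-first against
false-discovery-rate thresholds i·Q/N (step-down; Q = 1% by default)
and testing stops at the first retained point. Zero scale (all values
identical up to ties) is handled explicitly. Fewer than 3 values skips
the screen with a log notice.

The two-way diet × time ANOVA uses type-III sums of squares via
effect-coded (sum-to-zero) least squares — each effect's SS is the
residual-SS increase when its columns are dropped from the full
interaction model — which tolerates mild imbalance across cells and is
parity-tested against statsmodels `anova_lm(typ=3)` to 1e−8. Empty
cells raise with the missing cells listed. A residual SS at float-noise
level (constant response) reports F = 0, p = 1. Tukey HSD over the
diet × time cells is appended only when the interaction is significant.
Single-factor contrasts route through a per-group Shapiro–Wilk gate at
α = 0.05 to one-way ANOVA (all groups normal) or Kruskal–Wallis
(otherwise, or any group with n < 3); the route taken is recorded.

## Synthetic data generator

The generator emulates the three-diet (LP/MP/HP palmitate) development
study over P0/P10/P21/P35 with n = 6 per cell, male brain tissue by
default. Per sample: true fatty-acid δ = f·δ_sugar + (1−f)·δ_fat plus
biological noise (SD 0.5 mUr, between-animal); the forward methyl
balance with δ_ME = −41.56 gives the FAME δ; the inverse instrument
distortion (slope 1.02, intercept 0.8 mUr) plus instrument noise
(SD 0.3 mUr) gives the raw delta; CRMs pass through the same
distortion with 0.05 mUr repeatability, one sequence per
tissue-timepoint batch. Peak areas are constructed so quantification
recovers the configured compositions exactly; pre-weaning (P0/P10)
compositions track graded milk carryover (PAM 21–28 / 25–35 / 31–41%
for LP/MP/HP). Default true fractions are ordered f(LP) > f(MP) >
f(HP) in every cell (LP 0.84→0.90 rising, MP 0.80 flat, HP 0.76→0.70
falling over development) — generator parameters chosen to set the
qualitative dose-response shape, not estimates of any real cohort.
Biological and instrument SDs are kept separate so recovery-test
tolerances can be attributed. `generate_null` flattens every cell to
the profile mean for type-I-error calibration.

What the simulator does **not** emulate: chromatographic signal shape,
co-elution, per-litter random effects, sex differences, response-factor
drift, or any RNA-seq/behavioural readout. Passing recovery tests
therefore demonstrate correctness of the arithmetic chain under
Gaussian noise and affine drift, not robustness to those real-data
features.

## Problem sizes and numerical choices

The test suite calibrates stochastic properties at sizes chosen to
keep each suite fast while leaving comfortable Monte-Carlo margins:
1000 replicates for the calibration R² gate, ROUT false-positive rate
and ANOVA type-I error; 100–200 replicates for power, dose-response
detection and parameter-recovery checks. Parameter recovery asserts
the mean estimated fraction within 0.03 of truth for
f ∈ {0.3, 0.5, 0.7, 0.9} at the default noise with n = 6 per cell.
Seeds are fixed in every stochastic test; hypothesis property tests run
derandomized.

## Known limitations

* Two sources only; a third depleted acetyl-CoA source biases f
  downward, which is why the apportionment is read as a lower bound.
* The default δ_ME is a constant determined for one derivatization
  batch protocol; batches using different methanol lots should derive
  their own via `methyl_delta`.
* ROUT is implemented for the one-sample (constant) model, not for
  regression residuals.
* The pipeline's ANOVA treats litters as independent animals
  (fixed-effects, matching the analysis plan it mirrors); no
  random-intercept mixed models.
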