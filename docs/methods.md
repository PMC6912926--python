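# Methods

This note documents the models and procedures implemented in `finsex`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish about real photographs.

## Color representation

Images are 8-bit sRGB; the fin crop is converted to CIE L\*a\*b\* assuming
sRGB primaries, the D65 white point and the 2° standard observer — the
standard interpretation for consumer-camera images when no camera profile
is available. The conversion (delegated to scikit-image) is invertible to
within 8-bit quantization on the sRGB gamut and is cross-checked in the
test suite against an independent closed-form sRGB→XYZ→L\*a\*b\*
implementation using the standard published constants.

Features are per-channel histograms over fixed edges (L\* on [0, 100], a\*
and b\* on [−128, 127]) so histograms from different fish share bins.
**B = 64 bins per channel** is the default (feature dimension 192): full
8-bit resolution is supported but gives 768+ dimensions for cohorts of a
few hundred fish, with no measurable benefit on synthetic data. Histograms
are normalized per channel by default, which removes the dependence on fin
area and makes the feature invariant to image scale. Out-of-range values
are clipped into the edge bins so counts always conserve the pixel count.

## Fin-color SVM and the intensity score

A binary soft-margin SVM with Gaussian kernel exp(−γ‖x−y‖²) is trained on
the histogram features (scikit-learn's SVC under the hood; the fitted
model is stored as its support vectors, signed dual weights and bias, so
scoring is an explicit, JSON-serializable kernel sum). Defaults:
γ = 1/(d·Var(X)) and C = 1, both overridable; the problem is
well-separated enough on realistic color differences that the defaults are
not critical.

A binary SVM produces one signed decision value f(x). We expose the score
pair (s_male, s_female) = (f, −f); their difference — the per-fish
coloration signal d — is therefore f itself up to an immaterial factor of
two, which the subsequent z-transform removes. The cohort-level
**intensity score** is z = (d − mean d)/sd(d) with the population (n)
denominator (sample denominator by flag). Ties (d exactly 0) are
classified female and logged; the choice is arbitrary but deterministic.

Reported classifier performance uses stratified 5-fold cross-validation by
default; resubstitution (apparent) agreement is available by scoring the
training cohort, since field reports of agreement statistics do not always
distinguish the two.

## Residual CNN

The whole-body classifier is a residual convolutional network: 3×3 stem
(96 filters by default), batch-normalized ReLU stages widening 96→192→384
with stride-2 transitions (two blocks per stage), identity shortcuts where
shapes match and 1×1 projections where they do not, global mean pooling,
and a 2-unit softmax head. The default input is 255×255×3. Normalization
is batch normalization (selectable off). The stage/block schedule,
optimizer (Adam, lr 10⁻³), epochs and batch size are exposed in
`CnnConfig`.

The network is implemented directly in NumPy — convolution as an im2col
matrix product, hand-derived backward passes (verified against numerical
gradients in the tests), cross-entropy loss, Adam updates. A **reduced
geometry** (64×64 inputs, widths 16/32/64, one block per stage, first
stage downsampling) is the test-suite workhorse: it trains on a 200-fish
cohort in well under a minute per run while preserving every architectural
property of the full geometry (residual identity, pooling-induced
translation tolerance, softmax normalization). Training is seeded
(initialization and data order) and reproducible per device; no data
augmentation is applied by default.

## Agreement and sex-ratio model

Classifier-vs-truth agreement is the phi coefficient of the 2×2 table,
φ = (n₁₁n₂₂ − n₁₂n₂₁)/√(r₁r₂c₁c₂), which equals the Pearson correlation
of the two binary indicators. A zero margin raises an error rather than
returning 0 — silent zeros corrupt agreement summaries.

Sex ratios per treatment group are fit as a Bernoulli GLM with logit link
and a single fixed treatment factor (maximum likelihood via IRLS,
statsmodels). For this saturated model the back-transformed LS-mean equals
the group proportion and SE(η̂ᵢ) = √(1/(nᵢp̂ᵢ(1−p̂ᵢ))); the test suite
checks both against an independently coded Newton–Raphson oracle. Group
contrasts are tested on the logit scale with a Tukey–Kramer adjustment via
the studentized range distribution; with two groups this coincides with
the unadjusted two-sided test. Groups with p̂ ∈ {0, 1} are reported as
separated, with unbounded SE and a warning.

## Intensity ANCOVA

The full model for the intensity z is

y = μ + αᵢ + βⱼ + (αβ)ᵢⱼ + Σₖ bₖxᵏ + Σₖ cₖβⱼxᵏ + Σₖ dₖαᵢxᵏ + ε,  k ≤ 3,

with treatment α, sex β, and body weight (g) or total length (mm) as the
covariate x. Design choices:

* **Sum-to-zero factor coding** internally, so LS-means are estimable
  functions; the coding never appears in reported output.
* **Covariates are mean-centered before raising to powers** to control
  collinearity among polynomial terms; degree-1 slopes are unaffected by
  centering, and LS-means are evaluated at the covariate grand mean
  (centered value 0) by default or at caller-supplied raw values.
* **Backward elimination** removes, one term at a time, the removable term
  with the largest drop-one F-test p-value above `alpha_stay` (default
  0.05), refitting until all removable terms pass. *Removable* enforces
  marginality: no main effect leaves while an interaction containing it is
  kept, and no power xᵏ leaves while x^(k+1) or a factor·xᵏ term is kept.
  Ties break deterministically by reverse term order (highest-order terms
  leave first).
* **Outliers** are flagged by externally studentized residuals
  (leave-one-out variance, the standard regression influence diagnostic)
  at |r| > 3, removed in a single pass, and the model refit once.
  Observations with numerically zero residuals on exact fits are never
  flagged.
* **LS-means** come with SEs from the coefficient covariance,
  Tukey–Kramer-adjusted pairwise p-values (studentized range with residual
  df), and a compact-letter display computed from maximal cliques of the
  nonsignificance graph.

The two-way weight/length ANOVA (y = μ + αᵢ + βⱼ + (αβ)ᵢⱼ + ε) reuses the
same machinery with no covariate; on balanced data its LS-means equal cell
means, which the tests assert exactly.

## Synthetic cohort generator

Each synthetic fish is an ellipsoidal body plus a triangular caudal fin on
a uniform light background, composed in Lab space and stored as 8-bit
sRGB. Two independent cues are injected: fin b\* yellowness (the SVM's
signal) and body depth (females are rendered ~45% deeper, giving a
whole-body classifier a shape cue that survives color attenuation). The
fin ROI recorded in the metadata is an interior rectangle of the fin
triangle, so the crop contains fin pixels only.

Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_per_cell | 50 | 200-fish cohorts; desk-scale but enough for stable φ |
| yellow_mean_male / female | 32 / 17 b\* | a clear but not caricatured dichromatism; the 15 b\* gap is 3× the pixel noise |
| color_sd | 3 b\* | between-individual variation; ~5:1 signal-to-variation |
| treatment_male_attenuation | 12 b\* | strong temperature effect: treated males land near the female color range, so a fin-color classifier degrades on the treated group while a shape-aware one does not |
| noise_sd | 5 (Lab units/pixel) | visible pixel grain; averages out over the ~10²-pixel fin ROI |
| size_color_slope_male | 30 b\*/g | with weight sd 0.07 g, a ±2 b\* color range attributable to size in males; females get no slope |
| weight/length cell means | per-cell values around 0.36–0.44 g and 34.8–35.8 mm | realistic adult zebrafish morphometrics with heavier females and heavier/longer high-temperature fish |
| weight_sd / length_sd | 0.07 g / 1.9 mm | consistent with per-cell SEs of ~0.007 g / 0.19 mm at n ≈ 100 |

The male size–color slope is applied to the within-cell weight deviation,
so configured cell mean yellowness is preserved exactly. Sex assignment is
fixed per cell ("balanced", the default, for reproducible contingency
tables) or Bernoulli with male probabilities 0.798 (treated) and 0.502
(control) in "ratio" mode. All randomness flows from one seed;
identical configs yield byte-identical images and metadata.

**Assumptions and limits.** Between-individual color variation is modeled
as Gaussian — a modeling assumption, not an empirical claim. The generator
omits stripes, iridophore shininess, post-mortem paling, lighting
gradients and background clutter; consequently, passing tests demonstrate
that the pipeline recovers the statistical structure it assumes (color
separation, attenuation, size–color coupling, shape dimorphism), not that
any particular accuracy transfers to real photographs. The "noiseless fin
b\* equals generated yellowness" check holds up to 8-bit sRGB quantization
(~0.3 b\*), which is inherent to PNG storage.

## Numerical choices and degenerate inputs

Histogramming an empty crop, single-class SVM training, zero-variance
decision values, rank-deficient ANCOVA designs (reported with the aliased
term names), missing factor cells, degenerate (constant) covariates, and
(near-)saturated models for studentized residuals all raise informative
errors rather than returning silently wrong numbers. φ is undefined (and
raises) on tables with a zero margin. Exact decision-value ties and exact
probability ties in the CNN head classify as female, deterministically.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run at desk scale: 200-fish
cohorts for both classifiers (the CNN at the reduced 64×64 geometry,
15 epochs), 5-fold cross-validation, 50–100 replicate simulations for the
ANCOVA recovery/elimination/outlier studies at n = 400, and 20 label
permutations for the chance-level control. These sizes give stable
pass/fail behavior under the fixed seeds while keeping a full run in the
minutes range on one CPU.
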