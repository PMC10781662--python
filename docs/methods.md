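# Methods

This note documents the statistical model behind `pcorona`, the
package's default parameters and the reasoning behind them, the design
of the synthetic data generator, and the numerical choices that are
easy to get subtly wrong.

## 1. Problem setting

Each record describes one nanoparticle incubation: a mix of
categorical factors (particle type and core material, surface
modification, dispersion medium, protein source, ...) and numerical
factors (sizes, zeta potential, polydispersity index, centrifugation
and incubation protocol settings). The targets are per-protein
relative protein abundances (RPA): strictly positive, heavily
right-skewed quantities. One independent regression model is trained
per protein.

The skew is the central difficulty. Standard regressors minimize an
average loss, so they allocate capacity to the dense low-RPA region
and under-resolve the rare high-RPA tail — the region of greatest
practical interest. The package's answer is *relevance-guided
resampling*: define a continuous rarity score Φ(y) over target values
and rebalance the training set so that rare-but-relevant rows carry
more weight.

## 2. The relevance function Φ(y)

Φ: ℝ → [0, 1] is built by monotone piecewise cubic Hermite
interpolation (pchip) through a small set of control points
(yₖ, φₖ, φ′ₖ). On each interval [yₖ, yₖ₊₁] with h = yₖ₊₁ − yₖ and
secant δ = (φₖ₊₁ − φₖ)/h, the cubic is

    Φ(y) = aₖ + bₖ(y − yₖ) + cₖ(y − yₖ)² + dₖ(y − yₖ)³

with the standard Hermite coefficients

    aₖ = φₖ,   cₖ = (3δ − 2bₖ − bₖ₊₁)/h,   dₖ = (bₖ + bₖ₊₁ − 2δ)/h².

(Published presentations of this construction sometimes print the
quadratic coefficient with a `+bₖ₊₁` sign; that variant does not
reproduce Φ(yₖ₊₁) = φₖ₊₁, so the standard form above is used. The
pass-through property is asserted in the test suite.)

Slopes bₖ are corrected by the Fritsch–Carlson procedure
(`check_slopes`) so the interpolant is monotone wherever the control
data is monotone: a flat secant zeroes both adjacent slopes, a slope
whose sign opposes its secant is zeroed, and slope magnitudes are
projected into the circle (bₖ/δ)² + (bₖ₊₁/δ)² ≤ 9 that is sufficient
for monotonicity.

Control points conventionally sit at local extrema of the relevance,
so explicit derivatives default to 0. A derivative left as `None` is
instead estimated by the weighted harmonic mean of adjacent secants
(interior knots) and the clipped three-point formula (endpoints) —
the same estimator used by reference monotone-pchip implementations.
Estimated slopes already lie in the monotonicity region, so they are
used without the circle projection; re-projecting them could alter
valid estimates (the projection circle is not invariant under uneven
knot spacing) and would break exact agreement with reference
implementations, which the tests verify to 1e−8.

The default control points (`default_control_points`) follow the
boxplot recipe for an upper-tail rare region: relevance 0 at the
sample minimum and median, relevance 1 at the upper outlier fence
Q3 + 1.5·IQR, all derivatives 0. Outside the outermost control points
Φ extends as a constant and the output is clamped to [0, 1].

## 3. Resampling strategies

All three strategies operate on one protein's encoded training set and
are steered by Φ fitted on the *training* targets only. Every output
row carries provenance (`original` / `replica` / `synthetic` with
source-row indices), which the ablation harness uses to audit that no
resampled row derives from a test row.

**Random Oversampling.** Rows in the rare partition
Dᵣ = {i : Φ(yᵢ) ≥ t} are duplicated by seeded sampling with
replacement; `round(over_percent · |Dᵣ|)` replicas are appended.

**SmoteR.** For each synthetic row, a seed is drawn from Dᵣ and paired
with one of its k nearest neighbours within Dᵣ (Euclidean distance in
the encoded space). Numeric features are interpolated,
x = x_seed + u·(x_nb − x_seed) with u ~ U(0, 1); each one-hot group is
copied wholesale from one parent chosen by fair coin (so synthetic
rows remain valid one-hot encodings); the target is the
distance-weighted mean of the two parents' targets, the closer parent
weighing more. Degenerate rare partitions fall back gracefully:
|Dᵣ| < 2 falls back to random oversampling, |Dᵣ| ≤ k reduces k.

**WERCS.** No threshold: ⌈over_frac·n⌉ replicas are drawn with
probability ∝ Φ(y) and ⌈under_frac·n⌉ rows are removed (without
replacement) with probability ∝ 1 − Φ(y).

Defaults: threshold t = 0.8 and k = 5 (the canonical defaults of the
imbalanced-regression framework this follows), over_percent = 2.0
(two synthetic/replica rows per rare row — enough to visibly shift the
training distribution at |Dᵣ|/n ≈ 0.1), WERCS over_frac = under_frac
= 0.5 (a symmetric combination of the two mechanisms).

The expected effect of all three is the same and is what the
diagnostics measure: the variance of the training target increases
(mass moves into the wide tail) and the entropy of its equal-width
histogram increases (mass spreads across bins that were nearly empty).

## 4. Preprocessing

- **One-hot encoding** is full (no dropped level), so every level can
  surface as its own feature in level-resolved importance tables.
  Unseen levels at prediction time encode as an all-zero group, with a
  warning.
- **Min-max normalization** maps each numeric factor to [0, 1] by
  (x − Xmin)/(Xmax − Xmin) with the training-time bounds reused
  verbatim at prediction time — the only leakage-free choice. Nothing
  is clipped; out-of-range outputs are allowed and logged. A constant
  training column maps to all zeros with a warning.
- **The 9:1 train/test split** stratifies on 10 quantile bins of the
  continuous target, drawing a seeded 10% of each bin for the test
  side. This keeps the heavy tail represented proportionally on both
  sides, which an unstratified split frequently fails to do at these
  sample sizes.

## 5. Models and evaluation

Each protein gets a Random Forest regressor (scikit-learn, bagged
trees, predictions averaged across trees). Defaults: 500 trees
(100 in the ablation and acceptance runs, for runtime), unbounded
depth, all features considered at each split, `min_samples_leaf = 10`,
fixed seed.

The leaf floor deserves a note, because it is also what makes the
resampling ablation informative rather than vacuous. With 1-sample
leaves a forest on a few hundred rows effectively memorizes its
training set, including the tail; duplicating tail rows then changes
nothing that generalizes. With a 10-sample floor — a standard
regularization level for noisy tabular data at n ≈ 600 — the model's
resolution in any target region is proportional to that region's
*sample weight*: a rare region cannot be split finely until it
contains enough rows. That is exactly the imbalance pathology
relevance-guided resampling is designed to correct, and it is why
oversampled arms genuinely improve held-out tail accuracy here
instead of merely shifting predictions.

Metrics: **R²** is the squared Pearson correlation between observed
and predicted targets (an unsquared covariance-over-variances variant
is available via `r_squared(..., literal=True)` for auditability);
**RMSE** is standard. Because squared correlation is invariant to
affine rescaling of predictions, an R² gain from resampling cannot
come from bias shifts alone — it requires genuinely better *ordering*
of the tail, which makes it a conservative headline metric. RMSE
captures the calibration improvements as well.

The **ablation harness** (`run_ablation`) evaluates four arms — no
resampling and the three strategies — under identical conditions: per
protein, one shared stratified split and one shared encoder fitted on
the train side only; the train side alone is resampled; R²/RMSE are
measured on the untouched test side; a provenance audit raises if any
resampled row traces to a test row. Per-protein scores are averaged
unweighted, and Gini importances (one-hot columns summed into their
parent factor, so a factor's importance is comparable regardless of
its level count) are averaged across proteins and filtered at 0.01.

**Learning curves** re-run resampling inside each cross-validation
fold, on the fold's training portion only.

## 6. The synthetic generator

Real corona screens are small, heterogeneous and proprietary, so the
package validates itself on synthetic data engineered to have the same
statistical shape: 652 rows, 8 categorical factors with plausible
level sets, 13 numerical factors with plausible physical ranges, and
60 protein targets.

For protein *j*, with z denoting a numeric factor rescaled to [0, 1]:

    log RPA_ij = μⱼ + s·[ Σ_f effect_jf(x_if) + γⱼ·1{cat_i = Lⱼ}·z_i ] + ε_ij

- Three designated informative factors carry signal:
  `incubation_plasma_concentration` (slope |β| ∈ [0.8, 1.6], forced
  positive — more available protein means more adsorption), `PDI`
  (slope of random sign) and `surface_modification` (per-level offsets
  ~ N(0, 0.6²)). The other 18 factors are pure noise.
- Each protein additionally gets one synergy term: a randomly chosen
  surface-modification level Lⱼ amplifies the plasma-concentration
  effect with strength γⱼ ~ U(2.5, 3.5). This mirrors the real
  mechanism (a particular surface chemistry strongly amplifies
  concentration-dependent adsorption of a given protein) and is what
  produces the long right tail: high-RPA rows are the rare conjunction
  of one coating level with high plasma concentration — sparse in
  feature space, yet fully predictable.
- Defaults: skewness scale s = 1.2, log-scale noise ε ~ N(0, 0.2²).
  These produce mean target skewness ≈ 5 and a tail that a
  regularized forest under-resolves without resampling, which is the
  regime the pipeline exists for.

**Realism limits.** Factors are sampled independently (real protocols
correlate them), effects are additive on the log scale apart from the
single planted synergy, the noise is homoscedastic, and proteins are
generated independently (real coronas compete for surface area, which
couples RPAs and would make the per-protein modeling assumption less
clean). The generator is a test harness with a known answer, not a
simulator of corona physics.

## 7. Numerical and reproducibility notes

- Every stochastic stage takes an explicit seed; derived sub-seeds are
  produced by a small multiply-add chain kept below 2³¹ so they are
  valid for every RNG in the stack. The full pipeline re-run with the
  same configuration is bit-identical (asserted in the tests).
- Entropy diagnostics use a shared set of equal-width bin edges
  spanning the pooled before/after range, so the two entropies are
  directly comparable; variance uses the unbiased (ddof = 1)
  estimator; skewness uses biased central moments, the usual
  convention for shape diagnostics.
- Φ evaluation uses interval lookup by binary search; forests run
  single-threaded (`n_jobs=1`) because multi-threaded reduction order
  can break bit-reproducibility.
- R² is reported as NaN-safe across proteins: a degenerate test fold
  (constant predictions or targets) contributes NaN and is excluded
  from the mean rather than poisoning it; RMSE is always defined.

## 8. Limitations

- Per-protein independent models ignore the compositional coupling
  between RPAs.
- The importance filter (0.01) and resampling defaults are sensible
  conventions, not tuned optima; real datasets may need different
  thresholds.
- SmoteR interpolates in the encoded space; with many one-hot columns
  the Euclidean neighbourhood structure is dominated by categorical
  mismatches, which is faithful to the published method but worth
  knowing when feature counts grow.
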