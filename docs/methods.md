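# Methods

## Setting

`mrdml` implements bidirectional two-sample Mendelian randomization (MR)
between a continuous exposure (the motivating use case is brain
imaging-derived phenotypes, IDPs, measured in SD units in a GWAS of 8,428
individuals) and a binary outcome (autoimmune inflammatory diseases with
case/control GWAS of 10^4–10^5 samples), plus a summary-level double
machine learning (DML) estimator that re-estimates the same causal
parameter while adjusting for pleiotropy that clusters along observable
SNP-level features. Only GWAS summary statistics are consumed; no
individual-level data.

## Models and estimators

### Instrumental-variable model

For SNP j with true effect γ_j on the exposure, the generating model is the
partially linear structure

    β̂_X,j = γ_j + ε_X,j                       ε_X,j ~ N(0, se_X²)
    β̂_Y,j = θ γ_j + α_j + ε_Y,j               ε_Y,j ~ N(0, se_Y²)

with θ the causal effect (log-OR per SD of exposure for binary outcomes)
and α_j horizontal pleiotropy. Per-study standard errors are 1/√n, the
scale of a standardized genotype and trait; this makes the per-SNP variance
explained identity R² = β²/(β² + se²·n) internally consistent, and the
instrument-strength statistic F = R²(n − k − 1)/(k(1 − R²)) behaves as the
squared z-statistic in the large-n limit.

### MR estimators

* **Wald ratio** β_Y/β_X with first-order delta SE |se_Y/β_X| (single-SNP
  sets only).
* **IVW**: weighted least squares of β_Y on β_X through the origin with
  weights 1/se_Y². The default is the multiplicative random-effects
  variant: the fixed-effect SE is scaled by √max(1, Q/(n−1)) where Q is
  Cochran's heterogeneity statistic. This choice matters in the two-sample
  setting: exposure-side estimation noise violates the "no measurement
  error" assumption and shows up as over-dispersion of the per-SNP ratios
  (a factor 1 + θ²se_X²/se_Y²); the multiplicative term absorbs it, which
  is what makes the 95% interval cover at its nominal rate in the
  generator's two-sample regime. The fixed-effect variant is exposed for
  homogeneous panels and for oracle comparisons.
* **MR-Egger**: weighted regression with intercept after orienting every
  pair so β_X ≥ 0 (the intercept's sign is undefined without a fixed
  orientation). Coefficient SEs use the weighted residual variance floored
  at 1; p-values are t-distributed on n − 2 df. The intercept estimates
  the mean directional pleiotropy; the slope is the pleiotropy-adjusted
  effect under the InSIDE assumption.
* **Weighted median**: per-SNP Wald ratios ordered with normalized
  inverse-variance weights β_X²/se_Y²; the estimate is where the weighted
  empirical CDF (midpoint convention, so equal weights reduce to the
  ordinary median) crosses 0.5, linearly interpolated between straddling
  order statistics. The SE is a parametric bootstrap (default 1,000
  resamples of β_X and β_Y from their SEs, seed 1234). Consistent while
  ≥ 50% of the weight comes from valid instruments.

### Diagnostics

* **Cochran's Q** on the fixed-effect IVW fit, with per-SNP contributions
  w_j(r_j − θ̂)²; Q is exactly additive across SNPs.
* **Radial outlier pruning**: per-SNP Q contributions converted to
  χ²(1 df) p-values; SNPs with p < 0.05 removed; refit and repeat to
  convergence (the threshold-based rule alone does not say whether to
  iterate; iterating makes the operation idempotent). Pruning stops with a
  warning rather than dropping below 3 SNPs.
* **Global pleiotropy (PRESSO-style)**: observed statistic is the weighted
  leave-one-out residual sum of squares; the null distribution resamples
  *both* β_X* ~ N(β_X, se_X) and β_Y* ~ N(θ̂ β_X, se_Y) and recomputes the
  LOO RSS per replicate. Resampling the exposure side too is essential:
  with it the null p-value is uniform (verified by KS test over replicate
  datasets); without it the exposure noise in the observed residuals makes
  the test reject almost always.
* **Leave-one-out** IVW estimates, and an **MHC remove-and-rerun**
  comparison for instruments inside chr6:28,477,797–33,448,354 (GRCh37,
  closed interval — the published endpoints carry no open/closed
  convention, so both boundary positions are flagged).

### Summary-level DML

The same θ is estimated from the partially linear model
β_Y = θ β_X + h(Z) + ε with h an arbitrary nuisance function of SNP-level
features Z. With K = 5 cross-fitting folds, two learners per fold predict
m(Z) ≈ E[β_X|Z] and r(Z) ≈ E[β_Y|Z] out-of-fold; θ̂ is the
residual-on-residual slope Σβ̃_X β̃_Y / Σβ̃_X² pooled over all SNPs (not
averaged per fold), with the influence-function SE
√(mean(ψ²)/(n J²)), ψ = β̃_X(β̃_Y − θ̂ β̃_X), J = mean(β̃_X²), and a
two-sided normal p-value. The score is Neyman-orthogonal: first-order
insensitive to nuisance error, which the tests verify by perturbation.

**What is Z?** For summary data there is no canonical feature matrix; the
package treats Z as an explicit input. The default constructed from any
harmonized set is {allele frequency, per-chromosome indicators, distance
to the MHC mid-point, rank of |β_X|} — axes along which pleiotropy
plausibly clusters — and the generator's "feature" pleiotropy mode
produces datasets in which Z contains the true drivers of h. Callers with
real annotations (functional scores, trait-association counts) should
supply them.

**Learners.** `l1_linear` is LassoCV (penalty chosen by internal
cross-validation on the training folds); `tree_ensemble` is a
500-tree random forest with `min_samples_leaf=5`; `gradient_boosting`
uses 500 depth-2 trees at learning rate 0.05. The tree learners are
deliberately regularized: on panels of a few hundred SNPs, unregularized
trees add out-of-fold prediction noise to m̂ that acts like measurement
error on β̃_X and attenuates θ̂ toward zero.

**SE behaviour.** The influence-function SE is mildly anti-conservative at
moderate panel sizes when the nuisance fit leaves structured residuals:
under the null, replicate z-scores have SD ≈ 1.16 at 300 SNPs, so about 3%
of datasets put θ̂ beyond 3 SE of the truth. Tests of null recovery
therefore aggregate over replicates instead of asserting a single draw.

### Decision rules and power

Significance is judged against the Bonferroni threshold α/n_tests per
direction (the motivating study's families: 87 forward tests → 5.747×10⁻⁴,
3 reverse tests → 1.67×10⁻²; the pipeline computes n_tests from its own
screen counts, with an override). Statistical power for a binary outcome
uses the normal approximation

    power = Φ(|ln OR| √(n·VE) − z_{1−α/2})

with n the case count and VE the instrument variance explained (default
0.05, the conventional reporting choice), clamped to [0, 1]. A printed
variant Φ(OR·n·VE − z_{α/2} − z_β) circulates in the applied literature
but is not a self-consistent power function (z_β is the unknown); it is
evaluable behind `literal=True` for comparison only and is never used in
decisions. A significant finding is *hypothesis-confirming* only when
power ≥ 80%; significant but underpowered findings are *exploratory*;
everything else is *null*. Benjamini–Hochberg adjustment is available as
an off-by-default alternative for hypothesis-generating screens.

## The synthetic generator

`simulate_pair` emulates the two-sample design: instrument effects
γ ~ N(0, σ_γ) on `n_instruments` of `n_snp` SNPs, exposure GWAS of
n = 8,428 (the IDP GWAS scale) and outcome GWAS of n = 100,000 by default,
noise SDs 1/√n. σ_γ defaults to 0.3 so that instruments clear the
genome-wide threshold at n = 8,428 (that requires |γ| ≳ 0.06) with per-SNP
F = γ²n of order 10²–10³ — the strong-instrument regime the motivating
study reports. Pleiotropy modes:

* `balanced` — α ~ N(0, σ_α), InSIDE holds, Egger intercept null;
* `directional` — α = sign(γ)·N(μ_α, σ_α), i.e. aligned with the
  exposure-increasing allele. The sign-alignment is deliberate: with
  zero-mean γ an orientation-free constant shift would cancel under the
  β_X ≥ 0 Egger orientation and bias nothing, leaving directional
  pleiotropy undetectable by construction; aligning it with the oriented
  allele is the mechanism the Egger intercept is designed for and makes
  IVW genuinely biased while the weighted median stays consistent;
* `correlated` — α = ρ·γ + noise, an InSIDE violation for negative
  testing;
* `feature` — α = Z·w with a sparse weight vector over simulated
  features, the DML setting.

Allele labels include a configurable fraction of palindromic A/T and C/G
variants with frequencies drawn in (0.45, 0.55), guaranteeing they fall in
the default removal window [0.42, 0.58] (the conventional reading of
"allele frequency close to 0.5"). A configurable fraction of SNPs is
placed inside the GRCh37 MHC interval so the MHC filter is testable by
construction. `inject_ld_blocks` imposes block-equicorrelated LD (every
within-block pair at correlation ρ, i.e. r² = ρ²) by mixing z-scores with
a shared block component and co-locating the block's positions; clumping
is always performed against such a caller-supplied matrix, never a
downloaded reference panel.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency-dependent standard errors; winner's-curse selection
(instruments are selected in the same simulated exposure GWAS, but effects
are drawn independently of the selection, so the curse's upward bias is
absent); case/control imbalance effects on the log-odds scale; sample
overlap between the two GWAS. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
robustness to those real-data complications.

## Numerical and design choices

* Strict inequalities where a published rule states one: P < 5×10⁻⁸
  selection, F > 10 strength, p < α decisions.
* Clumping is greedy on ascending p with ties broken by SNP id, so output
  is independent of input row order; pairs absent from the LD matrix are
  treated as uncorrelated.
* Harmonization attempts strand-complement matching before declaring a
  SNP irreconcilable; palindromic SNPs with missing allele frequency are
  dropped (the ambiguity cannot be resolved; conservative choice).
* The ≥ 2 SNP rule: single-instrument pairs are still estimated (Wald
  ratio) but the report flags the decision as non-conforming.
* Q-based radial pruning runs before estimation; PRESSO is a post-hoc
  test. The order is configurable; this default keeps the estimator input
  stable under re-running diagnostics.
* 95% CIs use the normal quantile (1.959964); Egger p-values use t(n−2).
* Fixed seed 1234 everywhere a default seed is needed, matching the
  reproducibility convention of the motivating analysis.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use 50–200 replicates at 40–500 SNPs: 200 replicates
for bias/coverage and Type-I calibration, 100 replicate datasets (500
inner simulations) for PRESSO uniformity, 50–100 batches of 87 null pairs
(40 SNPs each) for family-wise error, 50–100 replicates at 300 SNPs for
DML/IVW sign concordance. These sizes give binomial 99% bands tight
enough to detect miscalibration of a few percentage points while keeping
a full run in minutes on one CPU.

## Known limitations

* The DML influence-function SE is slightly optimistic at a few hundred
  SNPs (see above); a bootstrap SE would be heavier but better calibrated.
* The weighted-median bootstrap resamples β_X and β_Y independently per
  SNP; correlated sampling error between exposure and outcome (sample
  overlap) is not modelled.
* LD clumping against a user-supplied matrix cannot reproduce
  reference-panel clumping on real data; it is exact for the generator's
  block-diagonal structure.
* Power calculations use the normal approximation on the log-OR scale and
  ignore case/control imbalance beyond the case count.
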