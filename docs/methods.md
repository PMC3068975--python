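# Methods

This note documents the statistical procedures implemented in `roctools`,
the conventions and defaults chosen where several are defensible, what the
synthetic-data generators emulate, and the designs and problem sizes of the
validation suite.

## Empirical ROC curves

A curve is built from case values (positive class) and control values
(negative class).  Thresholds are the midpoints between consecutive
distinct pooled marker values, plus −∞/+∞ sentinels, so every achievable
operating point appears exactly once and the two trivial points (SP=0,
SE=1) and (SP=1, SE=0) are always present.  With `direction =
controls_lower` (controls tend to score lower), a subject is called
positive when its value is ≥ the threshold; `controls_higher` mirrors this.
`direction="auto"` picks `controls_lower` when the control median does not
exceed the case median — a deterministic rule that is robust to outliers.
Curves are stored as fractions; percent is purely a display option.

The total trapezoidal area equals the Mann–Whitney statistic
P(case > control) + ½·P(tie) exactly; this identity is exercised against
exhaustive pair counting in the tests.

**Partial areas.** pAUC(t₀, t₁) integrates the polyline over a window of
the specificity axis (or, by transposing the traversal, the sensitivity
axis), linearly interpolating the boundary points.  McClish
standardisation maps the window's chance area (min) to 0.5 and its perfect
area (max = t₁−t₀) to 1:

    pAUC_std = ½ (1 + (pAUC − min)/(max − min)),   min = (t₁−t₀)(1 − (t₀+t₁)/2).

The map is affine and order-preserving, hence the perfect/chance constants
hold for any window on either axis.

**Coordinate queries.** Sensitivity at a given specificity is linearly
interpolated along the unique segment joining adjacent distinct
specificity values; a query coinciding with an observed specificity
returns the *best observed* sensitivity at that specificity (the first
point of the tied vertical run), with no averaging.  This matches the
behaviour of the field's reference R implementation, which was used as a
cross-check oracle; one consequence worth knowing is that the query at
SP = 1 returns the best sensitivity achievable at full specificity — not
0 — so confidence-shape bands do not collapse at that end.

**Best threshold.** The observed point maximising the Youden index
SE + SP − 1 within the requested region; ties break toward higher
specificity (a documented package choice — the literature does not fix
one).

## Resampling

Bootstrap is stratified by default: each replicate draws exactly the
observed number of cases and of controls, with replacement, within class.
Non-stratified resampling draws subjects regardless of label; replicates
that lose an entire class are discarded and redrawn, with the redraw count
recorded on the plan.  Paired procedures draw one set of subject indices
per replicate and evaluate both markers on it, preserving the
within-subject correlation that the paired tests exploit.

Intervals use the equal-tailed percentile method with the
linear-interpolation quantile definition (continuous in the level).
Default replicate count is 2000, which pins roughly the first significant
digit of interval bounds; 10000 refines the second.

All randomness flows from one integer seed through a single sequential
`numpy` Generator per operation (the vectorised AUC path draws its index
matrices in one batch from the same generator).  Every procedure is
bit-reproducible given its seed.  Per-replicate spawned substreams were
considered and rejected: the package does not dispatch replicates in
parallel, and a second seeding mechanism would only add surface for
mistakes.

## Comparison tests

**DeLong.**  Placements v10ᵢ (fraction of controls beaten by case i, ties
½) and v01ⱼ (fraction of cases beating control j) have means equal to the
AUC.  For paired curves the variance of θ̂₁−θ̂₂ combines the 2×2 sample
covariance matrices S₁₀, S₀₁ of the paired placements,

    V = (S₁₀[1,1] + S₁₀[2,2] − 2 S₁₀[1,2])/m + (S₀₁[1,1] + S₀₁[2,2] − 2 S₀₁[1,2])/n;

unpaired curves drop the cross terms, so V is the sum of the two
single-curve variances.  p-values are read off the normal distribution
(one- or two-tailed).  The reference R implementation instead uses a Welch
t reference for the *unpaired* variant; the statistics are identical and
the difference vanishes with sample size.

**Bootstrap Z-test.**  Z = (θ₁−θ₂)/sd(D), where θ are the metrics of the
original curves and D the replicate-wise differences of the rebuilt
curves' metrics.  The same machinery serves total AUC, partial AUC
(standardised or not) and smoothed AUC (each replicate is re-smoothed with
the original settings).  Zero spread with equal metrics yields a
degenerate p = 1; zero spread with unequal metrics is an error.
Comparing a smoothed with an empirical curve is possible by evaluating
different metrics per curve but is deliberately not wired into the public
test API; curves built with opposite directions are refused rather than
silently flipped.

**Venkatraman permutation tests** compare the whole curve shape, not the
areas.  Paired design: with markers reduced to ranks R_X, R_Y over the N
subjects, the statistic is E = Σₖ |e_X(k) − e_Y(k)| over rank cut-offs
k = 1..N−1, where e(k) counts misclassifications (cases ranked ≤ k plus
controls ranked > k).  The null swaps the two ranks of each subject
independently with probability ½ and re-ranks each marker; ties created by
the swap are broken uniformly at random by adding U(0, 0.5) jitter
(strictly below the minimal gap between distinct midranks) before ranking,
with the jitter drawn from the seeded stream.  The statistic is invariant
to strictly monotone transforms of either marker.  For small N an
exhaustive mode enumerates all 2^N swap patterns.  Unpaired design (two
independent samples with their own labels): the misclassification
*fraction* e(p) = (FN+FP)/N is a step function of the cut-off quantile
p ∈ (0,1); the statistic integrates |e₁(p) − e₂(p)| over the union grid of
both samples' step points, and permutations exchange rank-transformed
(rank/(N+1)) subjects between the samples within each class before
re-ranking.  The published construction leaves details at this level to
the implementer; the choices here are rank-based and exchange-valid, and
reduce to the natural count statistic at equal sample sizes.  Permutation
p-values are the raw proportion of null statistics ≥ E (E is a
discrepancy, so only large values count); a zero proportion is displayed
as "< 1/N".

**Fixed operating point.**  The bootstrap machinery applied to the
interpolated sensitivity at a fixed specificity (or the converse) —
equivalent to a pAUC test over a vanishing window, which the tests verify
empirically.

Multiple-testing corrections are never applied inside the tests; the CLI
can append a labelled Bonferroni/Holm column on request.

## Confidence intervals

* AUC: θ̂ ± z·√(var(v10)/m + var(v01)/n), truncated to [0,1] (DeLong).
* pAUC and smoothed metrics: bootstrap percentile.
* Thresholds: the cut-off stays *fixed*; each replicate re-evaluates the
  (SP, SE) it induces, and the two coordinates get independent percentile
  bounds forming a rectangle that is always reported jointly — reporting
  one coordinate's bound without the other misrepresents the uncertainty.
* Shapes: pointwise percentile bounds of the interpolated conjugate
  coordinate over a grid of fixed levels (default 0, 0.05, …, 1), joined
  into a band; no simultaneous-coverage adjustment is attempted.

Defaults: level 0.95, 2000 replicates, stratified.

## Smoothing

* **Binormal** (the default): if some monotone transform makes both class
  distributions normal, probit(SE) = a + b·probit(1−SP) along the curve.
  a and b are estimated by unweighted OLS over the observed interior
  points — not by maximum likelihood — after dropping the infinite-probit
  endpoints and deduplicating plateau points so ties are not
  over-weighted.  The smoothed curve is Φ(a + b·Φ⁻¹(1−SP)) on a uniform
  specificity grid (default 512 points; areas by trapezoid on the grid),
  and its exact area is Φ(a/√(1+b²)), which the grid quadrature matches to
  ~1e-5 at 1001 points.  A fitted slope b ≤ 0 signals an improper curve
  and only warns.  At least 3 distinct interior points are required.
* **Kernel density**: Gaussian KDE per class, Silverman's rule by default
  (a numeric bandwidth is interpreted as an absolute width), cut-off grid
  spanning the pooled range ± 3 bandwidths; SE/SP from the class CDFs.
  Discrete markers (≤ 10 distinct values) trigger a warning; a
  zero-variance class is an error.
* **Distribution fit**: per-class maximum-likelihood fit of a named family
  (normal, lognormal, exponential, gamma, logistic), with support checks;
  location is pinned at 0 for the positive-support families.
* **Custom densities**: class densities tabulated on a shared grid
  (renormalised with a warning beyond 1e-3) run through the same CDF
  construction.

All smoothed curves are monotone by construction and expose the same
AUC/pAUC/coordinate operations as empirical curves, and feed the same
bootstrap test/CI machinery by re-smoothing each replicate.

## Synthetic data

`BinormalSpec` describes class-conditional normal markers; defaults
emulate a mid-sized clinical biomarker cohort: 141 subjects with 41 cases
(≈ 30% prevalence of the poor outcome, a realistic figure for the kind of
neuro-outcome study this mimics), unit variances, and a one-SD case shift
(true AUC Φ(1/√2) ≈ 0.76).  Paired markers are drawn from a within-class
bivariate normal with correlation ρ (default 0.5); a null pair shares
marginals exactly.  Ordinal clinical scores (WFNS-like 1–5 grades) come
from discretising a latent binormal marker through fixed cut-points; the
latent values are kept alongside, which is how the suite demonstrates that
the trapezoidal AUC of a few-point ordinal curve underestimates the latent
AUC and that binormal smoothing reduces that bias.

True AUC is reported from the closed form Φ(Δμ/√(σ₁²+σ₀²)); true partial
areas by adaptive quadrature of the exact binormal curve.  Generators are
pure functions of their seed.

What the generators do *not* emulate: heavy-tailed or multimodal marker
distributions, missingness, covariate structure, or verification bias.
Passing tests therefore establish correctness of the procedures under the
binormal family (plus rank-invariance where applicable), not robustness of
ROC analysis to arbitrary real-world data.

## Validation designs and problem sizes

The suite runs in well under a minute on one CPU; sizes below were chosen
as the smallest giving stable Monte-Carlo verdicts.

* AUC ≡ Mann–Whitney: 1000 random samples (n ≤ 30 per class, with forced
  ties), exact equality.
* DeLong placements/variance: 200 random paired datasets (classes ≤ 12)
  against direct ψ-table enumeration, 1e-12 agreement.
* Null calibration: 300 equal-AUC datasets per test (binormal AUC 0.8,
  ρ = 0.5, n = 50/50); DeLong paired/unpaired, bootstrap paired/unpaired at
  200 replicates, Venkatraman at 500 permutations; Kolmogorov–Smirnov
  uniformity at α = 0.01.
* DeLong↔bootstrap agreement: 200 paired datasets at 1000 replicates,
  Pearson r ≥ 0.95 (observed ≈ 0.9996).
* Venkatraman exhaustive null: N = 8 subjects, all 256 swap patterns,
  vectorised engine vs an independently coded naive enumeration under the
  shared tie-break contract.
* Binormal identities: (a, b) recovery to 1e-6 on exactly tabulated curve
  points; grid AUC vs Φ(a/√(1+b²)) to 1e-4 at 1001 grid points.
* Coverage at nominal 95%: DeLong AUC CI at AUC 0.8, n = 50/50; bootstrap
  pAUC CI over SP ∈ [0.9, 1] at the same model with n = 100/100 (so the
  window holds ~10 controls and the replicate pAUC distribution stays
  non-degenerate at the 2.5% quantile) and 500 replicates; 300 runs each,
  acceptance band 92–98%.
* One cross-implementation check evaluates AUC, partial AUC on both axes,
  McClish standardisation, the paired DeLong test and the DeLong CI
  against the reference R implementation on a 70-subject fixture.

## Known limitations

* No BCa or studentized bootstrap; percentile intervals can undercover
  slightly for strongly skewed statistics (narrow-window pAUC at small n).
* Venkatraman's unpaired statistic follows this package's documented
  construction of the rank-based test; other implementations may scale the
  discrepancy differently (the p-value is invariant to common scalings).
* No covariate adjustment, ROC regression, multi-class outcomes, or
  simultaneous confidence bands.
* Binormal smoothing is regression-based by design; maximum-likelihood
  binormal fitting is out of scope.
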