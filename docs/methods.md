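# Methods

`psycop` profiles 2×2 genotype-by-environment (G×E) mouse cohorts: a
transgenic manipulation crossed with an environmental insult (e.g. a `Tcf4`
gain-of-function line crossed with adolescent social-defeat stress), with
groups labeled `wt-ns`, `wt-sd`, `tg-ns`, `tg-sd`. The pipeline has three
layers: derivation of behavioral variables from automated home-cage event
streams, a multivariate factorial statistics engine, and dimension-reduced
profile visualizations organized by Research Domain Criteria (RDoC) domains
(cognitive **C**, sensorimotor **S**, positive valence **+**, negative
valence **−**, arousal/regulatory **A**).

## Behavioral metrics

**Trials.** A *trial* is a corner visit containing at least one nosepoke at
the same corner within the visit interval; it is *correct* when made in the
animal's assigned corner. Visits without nosepokes are dropped from scoring
(their count is logged).

**Preference score.** Two event counts A (target) and B (other) are
contrasted as `(A − wB)/(A + wB)`, with the weight `w` chosen so chance
behavior maps to 0: `w = k_target/k_other` for corner contrasts (1/3 when
one corner of four is rewarded) and `w = 1` for binary contrasts (sucrose
vs. water licks, night vs. day visits). A zero denominator yields a missing
value, never 0. Scores are bounded in [−1, 1] and antisymmetric under
swapping A and B at `w = 1`.

**SPRT learning criterion.** Learning speed is the number of trials needed
to cross the upper boundary of Wald's sequential probability ratio test for
Bernoulli outcomes, with null success probability `p0 = 0.25` (random
expectation over four corners), alternative `p1 = 0.35` (chance + 10
percentage points) and `alpha = beta = 0.05`. The cumulative log-likelihood
ratio `L_n = Σ x_i·ln(p1/p0) + (1−x_i)·ln((1−p1)/(1−p0))` is compared with
`ln((1−beta)/alpha) = ln 19`; the criterion is the first `n` with
`L_n ≥ ln 19`. The lower Wald boundary is deliberately *not* a stopping
rule: an animal that drifts down keeps accumulating until the phase ends,
and is then censored at its total trial count (0 for an empty sequence).
For an all-correct learner the criterion falls at trial 9, the smallest `n`
with `n·ln(0.35/0.25) ≥ ln 19`. One operating-characteristic caveat: the
`beta` guarantee applies to the untruncated test. At `p = p1` the mean
crossing time is ≈119 trials with a long tail, so a phase capped at ~200
trials censors ≈17% by truncation alone; calibration checks therefore use
long phases for the `beta` side.

**Serial reversal.** Learning flexibility is the trials-to-criterion of the
first reversal phase alone; serial reversal performance is the trapezoidal
area under the trials-to-criterion curve across all reversal phases at unit
phase spacing, with censored values entering as-is. A missing phase value
makes the AUC missing.

**Activity and circadian measures.** Activity is visits/day over a
configurable window (default 5 days). Nocturnality is the preference score
of dark-phase vs. light-phase visit starts (`w = 1`), with zeitgeber time
ZT0 at lights-on (07:00, 12:12 cycle) and night = ZT12–24. The hourly
profile bins visit starts into 24 ZT-hour bins averaged across days.

## Factorial statistics

One multivariate bifactorial linear model is fitted to the untransformed,
listwise-complete measure matrix under sum-to-zero (−1/+1) coding of
genotype and environment — the coding that makes Type-II tests meaningful
in unbalanced designs. Hypothesis cross-product matrices are Type-II: each
main effect is adjusted for the other main effect (not the interaction),
the interaction for both main effects; the error matrix R comes from the
full model with `df_e = n_complete − 4`.

* **MANOVA.** Wilks' Λ = det(R)/det(R+H) per term, converted to F by Rao's
  approximation (exact for the 1-df hypotheses of a 2×2 design, and for
  any case with min(p, q) ≤ 2). With one response variable the MANOVA F
  reduces to the univariate ANOVA F exactly.
* **Univariate follow-ups.** Per-variable Type-II two-way ANOVAs from the
  same cross-products, Benjamini–Hochberg adjusted. The default FDR family
  is all variables × all three terms jointly (configurable to per-term).
  Stars follow * p<0.05, ** p<0.01, *** p<0.001 on adjusted p-values.
* **Interaction follow-up.** For variables with adjusted G×E p < 0.05, a
  one-way ANOVA of environment within each genotype level (`wtE`, `tgE`),
  reported unadjusted — it tests an environment effect free of genotype
  influence.
* **E-test of multivariate normality.** The energy statistic
  `n·(2·mean_i E‖y_i − Z‖ − E‖Z − Z′‖ − mean_ij ‖y_i − y_j‖)` of the
  whitened residuals against the standard d-variate normal, where
  `E‖a − Z‖` uses the confluent-hypergeometric closed form
  `√2·Γ((d+1)/2)/Γ(d/2)·₁F₁(−½; d/2; −‖a‖²/2)` and
  `E‖Z − Z′‖ = 2·Γ((d+1)/2)/Γ(d/2)`. Residuals are whitened by the
  inverse Cholesky factor of their sample covariance; each parametric
  bootstrap replicate (default 1000) draws standard normal samples of the
  same shape and whitens them identically, and
  `p = (1 + #{boot ≥ observed})/(n_boot + 1)`.
* **Repeated measures.** Hourly activity profiles are analyzed by a
  split-plot ANOVA: two between factors (G, E, G×E tested against
  subjects-within-groups) and one within factor (ZT hour and its
  interactions with the between terms, tested against the
  subject-by-within residual). Mauchly's W is computed on the orthonormal
  contrast covariance of the cell-mean residuals; when its p < 0.05, the
  Huynh–Feldt epsilon (grouped-design form, truncated to [1/(T−1), 1])
  rescales the degrees of freedom of within-involving terms.
  Greenhouse–Geisser epsilon is reported but not applied. The implementation
  was validated term-by-term against R's `car::Anova` type-II univariate
  repeated-measures output on a frozen seeded dataset.

Missing data policy: the statistics stage is strictly complete-case; the
imputed matrix exists only for dimension reduction and visualization, and
observed values are never overwritten. Animal exclusions are only ever an
explicit user-supplied list, logged verbatim.

## Dimension reduction

**NIPALS imputation.** Principal components are extracted sequentially by
alternating score/loading regressions that skip missing cells, deflating
after each component. Missing cells are then filled from the rank-k
reconstruction and the decomposition is re-run on the completed matrix
until the fills stabilize (an EM-style refinement; for exactly rank-k data
it converges to the exact completion). On complete data the components
equal the SVD solution. The default imputation rank is **k = 2**: a 2×2
design spans at most 3 between-group dimensions and behavioral batteries
have low intrinsic dimension, while high ranks interpolate measurement
noise into the filled cells — on synthetic cohorts with known deleted
values, imputation RMSE roughly triples when the rank is chosen by a
99.9%-variance rule instead. `k=None` restores a variance-cap rule for
users who want a full PCA. Loadings are signed so each component's
largest-magnitude entry is positive, making plots reproducible.

**Standardization.** The reconstituted matrix is z-transformed columnwise
(mean 0, sample sd 1 over the full cohort, ddof = 1); zero-variance columns
are dropped with a warning.

**CDA.** Canonical discriminant analysis in four steps: (1) whiten by the
pooled within-group covariance (denominator n − g) so it becomes the
identity; (2) compute group means of the whitened variables; (3) SVD of the
sample-size-weighted, grand-mean-centered group means; (4) back-transform
the right singular vectors to canonical coefficients in z-score units.
Canonical scores then have identity pooled within-group covariance, and
each component's share of the total canonical correlation is its squared
singular value over the sum (summing to 100%). The result matches a
generalized eigendecomposition of between- vs. within-group cross-products
up to sign and scale. Per model term, the 1-df hypothesis cross-product
H_term against R yields a single canonical direction (`H c = λ R c`),
scaled to unit pooled within-group score variance; `λ/(1+λ)` is the term's
squared canonical correlation. These per-term coefficient vectors form the
variables × terms heatmap.

## Visualization

The profile heatmap shows group-mean z-scores minus the reference group
(`wt-ns`), so the reference row is zero by construction; columns are
blocked by RDoC domain in fixed domain order and rows are ordered by
complete-linkage clustering of Manhattan distances (ties broken by
lexicographic label pre-sorting). The diverging color scale is symmetric
about 0 and clipped at the 99th percentile of absolute cell values.
Dimension plots show canonical scores on components 1–2 with per-group
normal-theory coverage ellipses at χ²₂ radius (default 75% coverage,
radius ≈1.665 sd); vector mode replaces points with one arrow per variable
at its canonical coefficients, all scaled by a single factor (80% of the
score range over the largest coefficient norm). Degenerate group clouds
are drawn as a marker and flagged. Boxplots use 1.5·IQR whiskers, seeded
horizontal jitter for points within 3% of the variable range of a
neighbor, and stars from adjusted p-values. Figures are written as SVG and
PNG with a fixed hash salt and no embedded date, so identical inputs give
byte-identical files.

## Synthetic cohorts

The generator emulates the *structure* the pipeline assumes — it is not a
behavioral mouse model. Cohorts are multivariate normal with group means
`baseline + (g·dG + e·dE + g·e·dG×E)/2` for codes g, e ∈ {−1, +1}: an
effect of d sd means the two factor levels differ by d residual sd
(Cohen's d), so noncentral-F power oracles apply directly. Defaults mirror
the study design: group sizes 15/17/15/17, 19 variables spanning the five
RDoC domains, exchangeable correlation 0.2, 2% missing cells (deleted
completely at random, with ground truth retained), a strong environment
signature on valence/arousal and fear-memory variables, a genotype
signature on sensorimotor gating and serial-reversal learning, and an
interaction only on open-field speed. Event streams draw visit times from
a two-rate light/dark Poisson process (default 120 visits/day, dark:light
rate ratio 3, giving an expected nocturnality of 0.5); corner choice
follows `p ← p + lr·(asymptote − p)` per trial, resetting at each phase
start, with nosepokes and reward licks attached per visit. The default
schedule reproduces the home-cage timeline (free/nosepoke adaptation with
50%/30% probabilistic days, 2 days place learning, 7 one-day serial
reversal phases with balanced rotating assignments, 1 day sucrose
preference with sucrose on the right side of every corner).

What the generator does **not** emulate: individual behavioral
heterogeneity beyond the learning-rate parameters, non-normal residuals,
informative missingness, within-day nonstationarity beyond the two-rate
cycle, or social interaction. Passing recovery tests therefore show the
*pipeline* recovers what it assumes, not that real cohorts satisfy those
assumptions — the E-test and residual diagnostics exist to check the
normality assumption on real data.

## Numerical choices and problem sizes

Wilks' Λ uses `slogdet`; whitening uses eigendecompositions with a
relative eigenvalue floor of 1e-10 (a singular within-group covariance is
an error advising variable reduction; an optional ridge is off by
default). NIPALS converges scores to a 1e-9 relative tolerance with at
most 1000 iterations per component and 200 refinement sweeps; components
whose residual is numerically exhausted are not extracted. The Monte-Carlo
suites use 1000 phases for SPRT operating characteristics, 1000–2000 null
cohorts for MANOVA/ANOVA calibration, 600 replicates × 160 bootstrap
samples for E-test calibration, and 160–200 cohorts per term for
planted-effect recovery; these sizes keep Monte-Carlo error near or below
the tolerance being checked while the whole suite runs in minutes.

## Known limitations

* The per-term CDA direction is estimated with noise of order
  `sqrt(p/λ)` (λ the term's noncentrality); with many variables and
  moderate effects its alignment with the true discriminant degrades
  before its detection power does.
* The split-plot RM-ANOVA requires every animal at every within level;
  animals with missing bins must be excluded explicitly.
* The E-test p-value resolution is limited by the bootstrap count
  (minimum p = 1/(n_boot+1)).
* Orphan nosepokes/licks (outside any visit) are logged and retained but
  never scored; heavily corrupted event streams should be inspected before
  profiling.
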