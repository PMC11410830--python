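# Methods

This note documents the statistical machinery implemented in `gcfpool`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data studies do and do not establish.

## The design

A factor pool of 12 named global-change factors, in fixed declaration order
(the order defines composition-matrix columns and all tie-breaking). Per
number-of-factors level k ∈ {2, 5, 8} the complete set of C(12, k) subsets is
enumerated in lexicographic pool order; sampling without replacement is a
seeded shuffle of that enumeration followed by taking the first n — exact and
reproducible, with an explicit infeasibility error when n exceeds the
enumeration. The reference layout (20 controls, 10 water controls, 8
replicates × 12 single factors, 50 combinations × 3 levels) totals 276 units.
Water controls are carried in the design but excluded from all statistics:
they exist to check solvent effects, not to estimate them.

## Effect sizes

The effect of a treatment group versus control is the raw mean difference,
estimated by a nonparametric bootstrap: B resamples (default 10,000) of each
group independently, statistic = mean(treatment*) − mean(control*). The
reported effect is the bootstrap mean, the CI the percentile interval
(the percentile form was chosen over basic/BCa; it is the simplest interval
consistent with summarizing a prediction *distribution*, and the same
convention is used for the null-model distributions). Two-sided p-values use
the bootstrap sign frequency, `p = 2·min(Pr(stat ≤ 0), Pr(stat ≥ 0))`,
clipped to [2/B, 1] so p is never claimed below the Monte-Carlo resolution.
Benjamini–Hochberg adjustment (via statsmodels) is applied within each
response family across treatments; the family choice is configurable.

## Dissimilarity

Single-factor effect profiles (12 factors × 7 responses) are standardized by
z-scoring each response column across factors, so every response contributes
equal variance to the geometry regardless of units. Factor–factor distances
are Euclidean in that standardized space. The dissimilarity index of a
combination is the sum over its C(N, 2) member pairs of those distances; since
the pair count grows from 1 (level 2) to 28 (level 8), raw DIs are
range-normalized to [0, 1] *within* each level before any cross-level use.
Degenerate cases (zero-variance response column; zero DI range within a
level) are mapped to zeros with warnings rather than errors. PCoA is
classical Torgerson scaling (scikit-bio); variance fractions divide each
positive eigenvalue by the sum of positive eigenvalues. Clustering is
agglomerative on the distance matrix, UPGMA by default, serialized to Newick.

## Null models and prediction distributions

Point predictions follow the three combination rules (additive sum;
multiplicative proportional change relative to the control level CT;
dominative signed maximum-absolute effect, ties to the first member in pool
order). The prediction distribution bootstraps K = 1000 iterations: one
shared control resample per iteration (so all member effect sizes within an
iteration are measured against the same control draw), one resample per
member group, `Z_i = t_i − c`, combination under the rule with `CT := c`,
and `T = c + Z`. Effect sizes are *signed* throughout — the dominative rule
and the direction-dependent classification are meaningless on magnitudes
alone. Multiplicative iterations whose control resample averages exactly
zero are flagged and redrawn (counted; an all-zero control raises).

## Interaction classification

For each multi-factor treatment × response, observed = treatment group mean.
Inside the 95% percentile CI of the prediction distribution → no net
interaction. Outside, the rescaled deviation `DN = (observed − mean)/sd` of
the draws decides: for responses that increase under stress, DN > 0 is
synergistic; for responses that decrease under stress (decomposition rate,
water-stable aggregates), DN < 0 is synergistic. The `(x − mean)/sd` scaling
is the only scale-free form that makes DN comparable across responses;
dividing by the CI half-width is available as an alternative. Per response,
the best-fitting null model minimizes the SSD of observed means from
prediction means, ties broken additive → multiplicative → dominative.
Per-level one-sample t-tests on DN (BH-adjusted across level × response
cells) and Spearman correlations of DN against normalized DI quantify
number-of-factors and dissimilarity trends in the deviations.

## The hierarchy of seven models

Rows are non-control units × responses. Predictors: the three null
predictions on the response scale (bootstrap means for multi treatments; for
singles all three coincide with control mean + effect), number of factors
(1 for singles), normalized DI (0 for singles, by convention — they have no
pairs; a sensitivity switch excludes singles), and the binary composition
matrix in pool order. Model 1 = nulls only (identity baseline); 2 = number
only; 3 = DI only; 4/5/6 = baseline + number / + DI / + both; 7 = 6 +
composition. R² increments are reported against the bases 4−1, 5−1, 6−1,
7−6. The GLM backend is Gaussian-identity (OLS) with AIC and nested F-tests;
Model 7's composition columns sum to the number of factors, so the design is
structurally rank-deficient and aliased columns are dropped with a warning.
The forest backend reports out-of-bag R² (in-sample forest R² is inflated;
switchable) and Altmann-style permutation importance: the importance
statistic is the mean MSE increase over independent column shuffles, and its
null distribution comes from refitting on response-permuted data,
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`, BH-adjusted across predictors.

A caveat discovered during validation and worth knowing: under a pure null
world the *estimated* null predictions carry sampling error, and that error
grows with the number of member factors. The regression on noisy predictors
is therefore attenuated in a level-dependent way, and Model 4 can pick up a
small spurious R² increment (~0.02–0.03 at the study sizes) that is
errors-in-variables leakage, not a number-of-factors effect. The recovery
studies bound it; it vanishes as single-factor replication grows. Similarly,
when real identity signal is present, the response-permutation null destroys
*all* structure, making Altmann p-values for irrelevant predictors
conservative (biased toward 1) rather than uniform; they are uniform under
the global null. The importance test is therefore a valid but conservative
screen.

## The synthetic generator

The generator emulates the reference experiment's structure: 12 factors ×
7 responses, control mean 10 and unit noise σ = 1 per response by default
(the scale is arbitrary; CT = 10 keeps multiplicative brackets well away
from −1 at unit-scale effects), true single-factor effects drawn
N(direction·0.5, 1) — mean magnitude half a noise SD, so single effects are
detectable but not dominant, and negative-direction responses (decomposition
rate, WSA) get negative expected effects to exercise both classification
branches. Each response combines member effects under a declared null world,
and an optional interaction rule adds, per unordered member pair, either a
fixed γ or `sign · γ · d_ij` with d_ij the *true*-effect Euclidean distance
(distance-proportional synergy; sign may be set per response). Higher-order
interactions are not injected — pairwise terms suffice to exercise the
aggregate net-interaction classifier. Noise is homoscedastic Gaussian per
response; real soil data will have heteroscedastic, possibly skewed errors
and correlated responses, so passing calibration here shows the machinery is
correct under its own assumptions, not that real data meet them.

## Calibration of the validation studies

The studies in `gcfpool.studies` are sized from explicit derivations:

* **Coverage requires adequate replication.** The classifier compares an
  observed mean (variance σ²/n_multi) against a bootstrap spread that
  reflects only the prediction's uncertainty (variance v_pred ≈
  σ²(k/n_single + 1/n_control) for the additive rule). Marginal coverage is
  ≈ 2Φ(1.96·√(v_pred/(v_pred+σ²/n_multi)))−1: with the reference single
  replicate per combination this is ~65% — deviations simply cannot be
  separated from unit noise — so the calibration study gives multi-factor
  treatments 700 replicates, keeping σ²/n_multi below ~5% of the *smallest*
  v_pred among the three worlds (the dominative one, 1/n_single +
  1/n_control).
* **The percentile bootstrap is a z-interval where a t-interval belongs.**
  With the dominative prediction resting on one group of n, two-sided
  coverage is ≈ P(|t_{n−1}| < 1.96·√((n−1)/n)): 92.3% at n = 24, 93.5% at
  n = 48. The calibration study uses 48 single replicates and 120 controls,
  leaving all three worlds at ~94% — within the 95 ± 3 band the type-I
  test asserts.
* **Flags cluster within replicates.** All treatments of one simulated
  experiment share the same realized single-factor samples, so their flags
  are strongly correlated; the study runs 300 replicates with 2 treatments
  per level (levels 2 and 5) rather than few replicates of 50.
* **Power study.** Injected mean interaction = 3 standard errors of the
  detection statistic observed − prediction mean, i.e.
  3σ·√(2/8 + 1/20 + 1/40) at the 2-factor level with the reference 8/20
  groups and 40 multi replicates — the textbook Φ(3 − 1.96) ≈ 85% power
  shift, eroded a few points by the dispersion of pair distances across
  combinations (γ is calibrated to the *mean* injection). The seven-response
  truth keeps true distances concentrated, as 7-dimensional profiles are.
* **Best-null recovery** runs at σ = 0.05 against order-1 effects: "low
  noise" meaning all three worlds' predictions are separated by many
  standard errors, so SSD selection should essentially always find the
  generating world; 24 combinations across levels 2 and 5 per replicate.
* **Hierarchy recovery** injects β = 1 per factor (term spans 2–8σ) or a
  dissimilarity term spanning 0–5σ on top of the additive world — well
  above noise, so Model 4/5 should win on both ΔR² and AIC essentially
  always.

Study sizes (replicate counts, K, B, forest sizes) are the package's chosen
operating points balancing Monte-Carlo error against desk-scale runtimes;
all are arguments, so heavier runs are one call away.

## Numerical conventions

Seeds: every stage derives an independent 31-bit stream from the master seed
by SHA-256 hashing of a stage label, so changing one stage's depth never
perturbs another's draws, and each (treatment, response, model) bootstrap
has its own stream — results are independent of iteration order. Percentile
CIs use `np.quantile` order statistics. DN uses the draw SD with ddof = 1;
a zero-spread distribution yields DN = 0 only when the observation equals
the mean, and errors otherwise. Dominative ties take the first member in
pool order; best-null ties take additive first. Zero-variance standardization
columns, zero DI ranges, and degenerate t-test cells warn and degrade to
defined values (zeros / NaN) rather than raising mid-pipeline.

## Known limitations

* Classifier coverage is nominal only with replication far beyond the
  reference design's single unit per combination; applied to such designs
  the "no interaction" class is conservative in the extreme (most true
  nulls flagged neither way — they are simply uncertain, and ~35% of them
  land outside the CI from unit noise alone). Interpret single-replicate
  calls as screening, not testing.
* The DN–DI correlation inherits the identity confound it is meant to
  escape only partially; the hierarchy (Models 4–6) is the inferential
  surface, and even there the errors-in-variables leakage above sets a
  floor on honest "no effect" increments.
* The generator's noise model is Gaussian and homoscedastic with
  independent responses; none of the studies validate robustness to
  violations of that.
* Only pairwise interactions are injected; the classifier's behavior under
  strong genuine higher-order interactions is unexercised.
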