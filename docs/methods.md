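# Methods

This note records the models, numerical choices and open design decisions
behind `shortform`, and what the synthetic-data tests do and do not show.

## Instruments and scoring

An instrument is an ordered list of items, each with a response-scale size
(≥ 2 options), a content-domain label, a `core` flag and a `min_code` (the
lowest score a response contributes, default 1). Totals are plain sums of
category codes; higher totals mean greater challenge. The packaged CLCF-SF
definition has 15 items — thirteen 5-point and two 4-point, all scored from
1 — so totals span 15..73. The alternative 0-based rescoring discussed for a
future all-5-point revision is available by setting `min_code: 0` per item;
it is not the default. Reverse keying is supported by a per-item flag and is
off everywhere in the packaged definition, since nothing indicates any item
is reverse-scored. The fixture's item wording is a paraphrased
reconstruction (the published item table is not redistributed here); its
structural fields follow the published instrument, and the choice of the two
perceived-support items as the 4-point pair is recorded as an assumption in
the fixture header.

## Missing data

Missing responses (about 1.6% of cells in the motivating data, with no
observable pattern) are replaced by the per-item median of observed
responses, pooled across all respondents in the supplied matrix. With an
even number of observations the *lower* median is used by default so the
imputed value is always an attained ordinal code; a midpoint-rounded
convention is available (`convention="midpoint"`). Imputation is idempotent
and never creates out-of-range codes. Model-based or multiple imputation is
out of scope.

## Cronbach's alpha and its interval

α = k/(k−1) · (1 − Σ item variances / total variance), with **n−1
denominators** throughout (alpha differs slightly between variance
conventions, so this is fixed and documented). Raw-covariance alpha is the
default even when 4- and 5-point items mix, matching standard practice; a
standardized (correlation-based) alpha is available.

The default confidence interval is Bonett's: log(1−α) is approximately
normal with variance 2k/((k−1)(n−2)), back-transformed to the α scale. Its
half-width at a planning value α is (1−α)·sinh(z·se), which the sample-size
planner inverts in closed form and then verifies by direct search (the
returned n satisfies the target and n−1 does not). Feldt's exact
F-distribution interval is available for comparison; which construction
produced any particular published interval is generally unstated, and the
two differ slightly (Feldt is asymmetric around the point estimate). A
precision requirement quoted over a range of plausible alphas is evaluated
at the smallest value in the range, where the interval is widest.

## Genetic algorithm

Fitness is α(S) times the length penalty 1 − (|S|/K)^p. The penalty is
*interpreted*: the source formula is printed as a raw difference which
cannot lie in [0, 1], while the accompanying text requires a penalty score
between 0 and 1 that punishes long subsets with polynomial order controlling
length; the ratio form satisfies all of that. The literal raw-difference
variant is retained behind `penalty_formula="raw"` purely for audit. K is
the full pool size the workflow targets (46 for the CLCF pool) and can be
set independently of the number of items in the supplied matrix.

Defaults — population 200, cull fraction 0.5, uniform crossover between two
random survivors, per-bit mutation 1/K, elitism of 1, stagnation limit
100 generations — are standard textbook GA settings; the exact published
parameterization is not stated, so correctness is guarded by an
exhaustive-search oracle on small pools rather than by parameter fidelity.
Core items are fixed on in every member; members with fewer than two items
score −∞ rather than erroring mid-run. Equal-fitness ties break toward
fewer items, then lexicographically smaller id sets, for determinism.
Because alpha depends on data only through the item covariance matrix, the
pool covariance is computed once and subset alphas are read off submatrices,
with memoisation over revisited bitstrings. Multi-start runs derive
independent seeds from one master seed and report whether all runs returned
the identical subset.

Whether post-hoc expert additions (the two support items) were core during
the published GA run or appended afterwards is ambiguous; the package
supports both (core flags are caller-controlled), and appending afterwards
is the reading the workflow narrative suggests.

## Polychoric correlations and EFA

Two-step ML: thresholds from the inverse normal of marginal cumulative
proportions, then the latent correlation maximizing the multinomial
likelihood of the cross-table (bounded scalar optimization on
[−0.9999, 0.9999], xatol 1e−8). Joint ML would differ negligibly at these
sample sizes and is slower. Cell probabilities come from an Owen's-T
representation of the bivariate normal CDF (absolute accuracy ~1e−13,
vectorised; the T-function singularity at zero arguments is handled by a
1e−13 nudge, far below the representation's own error). Empty boundary
categories are dropped before thresholding, making the estimate invariant to
category padding; the 2×2 case reduces to the tetrachoric correlation. A
non-PSD assembled matrix is smoothed by eigenvalue clipping (floor 1e−8)
with diagonal rescaling, and the smoothing is flagged.

ML factor extraction is delegated to `statsmodels.multivariate.factor`.
"Second eigenvalue" rules are ambiguous between the correlation-matrix
eigenvalue and the second factor's sum of squared loadings, so both are
reported; the unidimensionality check uses the correlation-matrix
eigenvalues with a strict < 1 threshold (exactly 1, as for an identity
matrix, fails). Rotations beyond none/varimax, parallel analysis and
confirmatory models are out of scope.

## Rating Scale Model

Category probabilities: P(X=x|θ) ∝ exp(xθ − xβ_i − Σ_{k≤x} τ_k),
x = 0..m−1, one difficulty β_i per item and one set of thresholds τ shared
across items. Identification: latent trait ~ N(0, 1) (mean fixed at 0, the
MML convention, so difficulties are free) **and** Στ_k = 0 — the second
constraint is required because a constant can be traded between the
threshold mean and all difficulties. Note that Rasch software using
conditional/joint ML often sum-zeroes the difficulties instead; estimates
differ by a constant shift.

Estimation is MML by EM: 41 equally spaced quadrature nodes on [−6, 6] with
normalized normal weights, E-step posteriors per respondent over nodes from
observed items only (missing-by-design cells contribute nothing), M-step
L-BFGS-B on the expected complete-data log-likelihood, warm-started.
Convergence: absolute log-likelihood change < 1e−5, cap 500 iterations; the
EM log-likelihood trace is non-decreasing by construction. Standard errors
are from the inverse numerical Hessian of the marginal log-likelihood at the
MLE. Person scores are EAP (posterior means). Items whose observed responses
all fall in one category are inestimable and are excluded with a warning.
Higher categories mean greater difficulty, so higher person scores mean
poorer treatment management. "Does not apply" responses are coded as
structurally missing, not as an extra category — the treatment a child does
not receive carries no information about management competence.

## Validity statistics

Correlation method choice is gated on Shapiro–Wilk normality of **both**
variables at level 0.05 ("the variables", plural): Pearson only if both
pass, else Spearman; both coefficients are retained in the result either
way. The t-test is Student's pooled-variance by default (the classical
"independent t-test" reported with a single mean-difference CI), Welch by
flag; Cohen's d uses the pooled SD with n−2 denominator. Each comparison
runs on its pairwise-complete cases and reports its own n. No
multiple-testing adjustment is applied by default.

## Synthetic cohorts

The generator draws a standard-normal trait t, item responses by
discretizing λ_j·t + √(1−λ_j²)·ε at per-item ordered thresholds (so the
latent item variables are standard normal — exactly the polychoric model,
making polychoric recovery an exact-model test), missingness completely at
random, covariates conditional on the trait to hit target correlations in
expectation, and binary groups as standardized latent mean shifts.

Defaults are the emulated study conditions: 135 respondents on the packaged
15-item form, loadings 0.55 (chosen to put the form's alpha in the low 0.8s,
the reported regime), equal-probability thresholds, 1.6% missingness,
covariate correlations 0.48 / 0.41 / 0.43 / −0.37, group shifts 0.37 and
0.26 SD. An `anchor="total"` option plants covariate correlations against
the standardized observed total instead of the trait; correlations measured
against totals are otherwise attenuated by roughly the square root of the
reliability, so total-anchored planting is what makes a round-trip recovery
test meaningful. Group shifts act on the trait, so their observed d on
totals is attenuated by corr(total, trait) ≈ 0.9 at the default loadings.

What the generator does **not** emulate: real item wording effects,
cross-loadings or domain-level multidimensionality, non-random missingness,
respondent styles (acquiescence, extreme responding), or clinically
realistic treatment mixes. Passing recovery tests therefore demonstrates
correctness of the estimators under their assumed models, not robustness to
the ways real questionnaire data violate them.

## Problem sizes in the test suite

The suite exercises each stage at sizes chosen to make sampling error small
relative to the assertion tolerances while keeping a full run around two
minutes: GA-vs-exhaustive comparisons use 10-item pools (2¹⁰ subsets) at
n = 300 over 20 datasets; planted-structure multi-start uses 8 signal items
among 20 at n = 300 with the pool penalty at K = 46; polychoric and validity
recoveries use n = 5000; RSM recovery uses 7 items at n = 2000 (complete and
30% missing-by-design); the unidimensionality rule is checked over 100
replications at n = 1000.

## Known limitations

- Alpha-optimised selection capitalises on chance in the selection sample;
  the package reports but cannot correct this (cross-validation would need
  more data than the workflow assumes).
- The Bonett planner ignores the clustering of pooled cohorts.
- Two-step polychoric SEs are not propagated into the EFA.
- The RSM assumes a normal latent distribution; no partial-credit or graded
  response alternatives, and no differential item functioning tests.
- A separately mentioned "5% alpha / 80% power" framing alongside the
  precision formula has no computational home in precision-based planning
  and is intentionally not implemented.
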