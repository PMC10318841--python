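# Methods

`metasample` implements a quantitative meta-research analysis of
neuroimaging-based machine-learning classifiers for psychiatric diagnosis:
how unevenly the literature samples the world, how reported performance
should be synthesised and contrasted across methodological strata, and how
study quality can be rated on a five-item checklist.  This note records the
models, the defaults and why, the numerical choices, and the limits of what
the synthetic-data validation shows.

## Sampling inequality

The unit of analysis is a geographic unit (a country worldwide, or a
first-level administrative region within a country) carrying the total
sampled population contributed by all studies recruiting there.  Inequality
of the allocation y₁…yₙ is measured by the Gini coefficient

    G = Σᵢ Σⱼ |yᵢ − yⱼ| / (2 n² ȳ),

computed through the algebraically identical sorted-rank form
`G = 2Σᵢ i·y₍ᵢ₎ / (nΣy) − (n+1)/n` (O(n log n), exact to float precision;
the O(n²) double sum is kept as a test oracle only).  G is 0 at perfect
equality and (n−1)/n for a one-hot allocation.  The Theil T index
`(1/n)Σ(yᵢ/ȳ)ln(yᵢ/ȳ)` (with 0·ln 0 = 0) is computed alongside as an
entropy-based robustness check, and Lorenz curves are returned for
inspection (trapezoidal area A satisfies G ≈ 1 − 2A up to the 1/n
discretisation).

When units carry a module label (the MEDC/LEDC economic blocs), the Gini is
decomposed after Dagum into within-module, net-between-module and
transvariation parts.  Modules are ordered by descending mean; for a pair
(j richer, h poorer), d_jh is the mean positive excess of j-values over
h-values across cross pairs, p_jh the symmetric moment for the poorer
module, and the relative affluence D_jh = (d−p)/(d+p) ∈ [0,1].  When
d + p = 0 (identical degenerate modules) D_jh is defined as 0 by
continuity; the pair term vanishes anyway because G_jh = 0.  The identity
G = G_w + G_nb + G_t is exact and is property-tested to 1e-10 on random
grouped samples.

**Inference.**  Significance of an observed G is assessed against an
explicit "no sampling inequality" null: the rounded grand total reallocated
across the observed units by an equal-probability multinomial (a continuous
flat-Dirichlet null is selectable).  p-values use the add-one (permutation)
correction p = (1 + #{G_null ≥ G_obs})/(B + 1), so p > 0 always at finite
B; default B = 10,000.  Under the multinomial null itself the test's
p-values are uniform (checked by KS at α = .01 over 500 replicates).

**Unit universe.**  Units observed with zero totals are excluded by
default; a supplied universe (e.g. all recognised countries) can be
injected at zero via `include_zero_units`, since a global Gini is larger
under the all-countries convention.  Both conventions are first-class
because published unit tables are ambiguous on this point.

## Precision-weighted performance synthesis

A study reporting accuracy p on n subjects carries sampling variance
p(1−p)/n, so accuracies are pooled with inverse-variance weights
wᵢ = nᵢ/(p̃ᵢ(1−p̃ᵢ)), where p̃ is clipped to [0.5/n, 1−0.5/n] to keep
weights finite at reported 0% or 100% accuracy.  n is the held-out test
size when coded, else the total sample; the output flags which was used per
study.  95% CIs are percentile bootstrap over studies (seeded, default
B = 1,000).

Because these weights depend on the observed proportion itself, the
weighted mean is pulled slightly upward near the [0,1] boundary; for
*recovering an additive accuracy shift* between strata the unweighted mean
difference is the unbiased estimator (we measured the weighted-difference
bias at ≈ +1.3 accuracy points with sd ≈ 1.2 points on 2,000-study
corpora).  `compare_groups` therefore reports both: precision-weighted
means as the synthesis quantity and unweighted means for effect recovery.

Contrasts use the Wilcoxon rank-sum W (rank sum of group A; exact null
enumeration for small untied samples, tie-corrected normal approximation
otherwise), Cohen's d on the raw metric (pooled SD; weighting a d is
nonstandard), and optionally a JZS Bayes factor.

**Case–control skewness** is max(n_patients, n_controls)/min(...) ≥ 1,
symmetric in its arguments.  A study is flagged skewed when the ratio
strictly exceeds τ = 1.5 (configurable) — a conventional imbalance
criterion; prevalence estimates are reported with the threshold used.

## Shared statistics

* **Spearman correlation** uses mid-ranks everywhere, asymptotic two-sided
  p, and a seeded percentile bootstrap CI over paired resamples (default
  B = 1,000); a permutation variant permutes the y-ranks (add-one p,
  one- or two-tailed).  Bootstrap CI coverage is property-tested at
  ≈ 95% ± 3 points on bivariate-normal draws.
* **Mann–Kendall trend**: S = Σ_{i<j} sgn(xⱼ−xᵢ), tie-corrected variance
  [n(n−1)(2n+5) − Σₜ t(t−1)(2t+5)]/18, ±1 continuity correction on Z,
  two-sided normal p.  S is verified against exhaustive pair enumeration
  for every permutation of n ≤ 7.
* **Exponential growth** of yearly study counts is fit as
  k = a·exp(b·t̃) on centered time by iteratively reweighted nonlinear
  least squares: weights come from the *fitted* curve (σᵢ ∝ √μᵢ, the
  Poisson scaling) because weighting by observed counts biases a
  multiplicative fit.  Wald 95% CIs on b cover a true rate of 0.25 in
  ≈ 93% of Poisson simulations.
* **JZS Bayes factors** are computed by adaptive quadrature of the
  Zellner–Siow g-prior mixture (log-integrand with a mode shift for
  stability): the Liang-form regression factor from (r, n) for
  correlations and the standard two-sample t form with effective
  N = n₁n₂/(n₁+n₂).  The Cauchy prior scale defaults to 0.34; for the
  correlation kind the scale enters through g ~ InvGamma(1/2, n·s²/2),
  one of several conventions in circulation — published BF values computed
  under a different prior parameterisation will differ accordingly.  The
  implementation is checked against an independent 200,001-point
  fixed-grid quadrature to better than 3 significant digits, and the
  two-sample kind additionally against pingouin at scale 0.707.
* **Semi-parametric spline regression** fits y = α + βx + f(x) with f a
  penalized cubic B-spline (interior knots at x-quantiles, default 10;
  second-order difference penalty; smoothing by GCV over a 40-point log-λ
  grid).  The basis is residualized against [1, x], which both centers the
  smooth and removes its linear direction, so β is identifiable; the
  orthogonality also decouples the parametric and smooth normal equations.
  `smooth_edf` is the trace of the smooth's hat block floored at 1 (the
  penalty's surviving null-space dimension): a purely linear signal
  shrinks to edf ≈ 1.  R²_adj uses total edf = 2 + trace.  A pure-smooth
  mode (no separate linear term) is available.

## Quality rating (N-ML-MAP-P)

Five items, each 0–2 points in the default rubric: (1) sampling
representativeness — one point for n ≥ 200 and one for multi-site
acquisition; (2) CV scheme — none/other 0, LOOCV 1, k-fold or nested 2;
(3) external validation — none 0, within-country 1, cross-country 2;
(4) reporting transparency — half a point per reported secondary metric
(sensitivity, specificity, balanced accuracy, AUC), capped at 2;
(5) availability — verified 2, claimed 1, absent 0.  Stars map from the
0–10 total as max(0.5, ⌊total + 0.5⌋/2): monotone, confined to the
half-star grid, with a 0.5-star floor so the scale bottoms out at half a
star rather than zero.  The rubric is data (JSON/YAML): items, point
tables and the star map are replaceable without code changes, because the
canonical point table circulates as a figure rather than text and users may
hold the exact one.  Missing information scores the item floor and is
flagged, never raised — the transparency-penalty convention of
risk-of-bias tools.  Dual-rater totals differing by strictly more than 2
points flag a third rater.  The default "low quality" cutoff is < 3 stars
(configurable, reported with every summary).

## Synthetic corpus generator

The generator is first-class, tested code; its defaults are the study
conditions of the modelled literature, chosen once: 476 studies over
1995–2021 with an exponential publication ramp (rate 0.12/yr); a 30-unit
world (18 MEDC, 12 LEDC) with GDP-proportional allocation weights and
total Dirichlet mass 18.434, calibrated by simulation
(`calibrate_concentration`, deterministic internal seed) so the expected
allocation Gini is ≈ 0.81; base accuracy 0.72 with additive effects
+0.04 for LOOCV, +0.05 for no external validation, +0.10 for within-
versus cross-country validation, Gaussian noise sd 0.05 truncated to
(0, 1); skew probability 0.2537 (patient/control counts are nudged after
integer rounding so the realized ratio always honors the drawn flag);
availability and reporting flags at the prevalence the literature shows.
Each country's total is further spread over 8 admin-1 regions with
Dirichlet evenness increasing in GDP (exponent 1.5), producing the
negative GDP → within-country-Gini relation the covariate stage probes.
All draws come from one seeded generator in a frozen order, so a
(config, seed) pair is byte-reproducible.

What the generator does *not* emulate: real studies cluster by research
group and dataset (the generator draws independently), accuracies are
reported with rounding and selective emphasis, covariates like GDP are
measured with error, and the real unit universe is far larger than 30
countries.  Passing parameter-recovery tests therefore shows the pipeline
is a consistent estimator of its own generative structure — not that any
particular published estimate is correct.

## Pipeline and reproducibility

`run_full_analysis` composes the stages and equals the composition of the
individually invoked operations on the same seeds (tested).  Per-stage
seeds are spawned from the run seed via `SeedSequence`; every stochastic
result carries its seed and replicate count.  Stage failures are recorded
and skipped unless `--strict`.  Percentages are rendered to two decimals
in reports but stored at full precision.

Problem sizes used by the test suite and `scripts/acceptance.py` — 2,000
studies for effect recovery, 60 allocation draws for the Gini condition,
500 replicates for calibration checks, B = 200–10,000 for resampling —
were chosen as the smallest sizes at which the Monte-Carlo error is well
inside the tolerance being asserted.

## Known limitations

* The binomial-variance precision weights treat each reported accuracy as
  an independent binomial; correlated folds, repeated cohorts and
  publication selection are ignored (no random-effects heterogeneity
  model is fit, by scope).
* The JZS correlation Bayes factor's prior convention is one of several;
  cross-software comparisons need the scale mapping stated above.
* The equal-allocation permutation null tests "no systematic inequality"
  among the *observed* units; it says nothing about units never sampled.
* The GAM reports a linear β alongside a constrained smooth; fits made
  under other identifiability conventions (e.g. an unconstrained smooth
  absorbing the linear trend) report different βs for the same data.
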