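# Methods

## The quantity being modelled

For each disease, onset is summarised by the age-specific rate of first
recorded diagnosis on the integer age grid 21..84:

    q_x = d_x / l_x

where `d_x` is the number of patients first recorded with the disease at age
`x` and `l_x` the number with no record of the disease at age `x`. The grid
is a hard contract: ages ≤ 20 are excluded (onsets there are plausibly
developmental rather than ageing-driven) and ages ≥ 85 are excluded
(survivors past 85 are a selected, unusually robust subgroup, and little
previously undiagnosed disease is first recorded there). Inputs containing
out-of-window ages are rejected unless trimming is requested explicitly.

`l_x` counts patients *without a prior record*, not survivors: the at-risk
pool depletes only by diagnosis. Mortality and censoring are deliberately
absent from both the rate definition and the synthetic generator, because
the target quantity is the diagnosis rate among the not-yet-diagnosed.

For clustering, each curve is standardised to unit mass,

    q̂_x = q_x / Σ_{i=21..84} q_i ,

so that two diseases with the same *shape* of onset-vs-age but different
absolute frequency are treated as identical. A disease whose rate is zero
at every age has no shape and is flagged rather than clustered.

Ages where `l_x = 0` get `q_x := 0` with a flag, rather than being dropped,
so every curve keeps the full 64-point grid needed for Euclidean distances.
At realistic cohort sizes this case does not arise; the convention exists
for degenerate synthetic inputs.

## Clustering with model selection

Pairwise Euclidean distances between standardised curves feed a
model-selection cascade, each stage scored by an internal validation index:

1. **Linkage** (hierarchical agglomerative clustering): candidates single,
   complete, average, weighted; the winner maximises the cophenetic
   correlation coefficient — the Pearson correlation between original
   distances and dendrogram merge heights. Ties go to the earlier
   candidate in the listed order.
2. **Number of clusters k**, per algorithm: the Tibshirani gap statistic.
   With `W_k = Σ_r D_r / (2 n_r)` (D_r the sum of pairwise squared
   distances in cluster r, equal to the within-cluster sum of squares),

       Gap(k) = (1/B) Σ_b log W*_kb − log W_k ,

   over B reference datasets, with `s_k = sd_b(log W*_kb)·√(1+1/B)`, and
   the chosen k is the smallest with `Gap(k) ≥ Gap(k+1) − s_{k+1}`.
   **Reference distribution:** uniform in the box aligned with the data's
   principal axes (Tibshirani's method (b)). Standardised onset curves are
   64-dimensional but concentrate near a low-dimensional manifold; with
   the plain per-feature box (method (a)) the gap curve keeps creeping
   upward well past the generative number of families, because a full-box
   null is too easy to beat when splitting elongated clusters. Method (a)
   remains available via `gap_reference="box"`. `W_k = 0` (all points in
   every cluster coincident) is floored at the smallest positive float
   with a warning.
3. **Algorithm**: hierarchical (at the selected linkage), k-means (on the
   curves, k-means++ init, best of 10 restarts), PAM (classic BUILD +
   steepest-descent SWAP on the distance matrix) and spectral clustering
   (Gaussian affinity with bandwidth = median pairwise distance,
   normalised Laplacian, k-means on the embedding), each evaluated *at its
   own gap-chosen k*, compared by the Dunn index (minimum between-cluster
   distance / maximum within-cluster diameter). Ties prefer hierarchical,
   the reference method. A k of 1 cannot be scored by Dunn and is treated
   as −∞ in the comparison.

Determinism: scipy's linkage is deterministic for a fixed input (merge ties
resolved by its nearest-neighbour-chain order); PAM is deterministic with
lowest-index tie-breaks; k-means and spectral take seeds derived from
`random_state` via a fixed per-algorithm mapping, so adding or removing
candidate algorithms does not change the others' draws. Clustering output
is invariant to disease input order up to label permutation.

PAM stops at swap-optimality (no single medoid/non-medoid exchange lowers
the cost) — the classic algorithm's defining condition, which is a local,
not global, optimum.

**Main vs outlier clusters.** After cutting at the chosen k, clusters with
≥ 3 diseases become main clusters, relabelled 1..M by *descending*
within-cluster median of member diseases' median onset ages (main cluster 1
always has the oldest onset); clusters with ≤ 2 diseases are outliers,
numbered the same way.

## Actuarial banding

Both models are ordinary least squares on the log scale, over the ages with
`q_x > 0` (the log of a zero rate is undefined):

- Gompertz: `log q_x = log α + β x`, p = 1 predictor;
- Gompertz–Makeham: `log q_x = log a + b x + c x²`, p = 2. This is the
  exponential-*polynomial* usage of the Gompertz–Makeham name (a quadratic
  in the exponent), not the classical additive-constant Makeham hazard;
  the quadratic term is what lets the model track non-monotone curves.

Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) penalises the extra quadratic term:
plain R² can only rise when a regressor is added, adjusted R² rises only
when the term earns its keep.

The banding rule is a total function of (sign of β, GM adjusted R²):

| condition            | band                     |
|----------------------|--------------------------|
| β < 0                | very_low_beta_negative   |
| adj R² ≥ 0.95        | very_high                |
| 0.90 ≤ adj R² < 0.95 | band_090_095             |
| 0.85 ≤ adj R² < 0.90 | band_085_090             |
| 0.80 ≤ adj R² < 0.85 | band_080_085             |
| adj R² < 0.80        | low                      |

Conventions where the rule is silent at the edges: β = 0 exactly is
non-negative (proceeds to the R² step); band intervals are half-open,
closed at the lower threshold. A perfectly flat log-rate curve has zero
total variance; we define β = 0 and R² = 0 for it rather than a 0/0.

A disease needs at least `min_positive_ages` (default 10) positive-rate
ages to be fitted at all; sparser diseases are flagged `unclassified`, and
per-disease failures never abort a batch. The default of 10 balances
letting sparse but real curves through against fitting a quadratic to a
handful of points; it is configurable and was not tuned to any dataset.
Fits are unweighted: the model is the plain linear regression of log-rate
on age, and weighting variants are out of scope.

## The synthetic cohort generator

The generator emulates the *aggregated* shape of EHR onset data: for each
disease, counts `d_x ~ Binomial(l_x, h(x))` with `l_{x+1} = l_x − d_x`,
starting from `cohort_size_at_21` (default 10⁶, of the order of a large
national primary-care extract) at age 21. The default panel has five hazard
families, chosen to span the archetypal onset shapes seen among high-burden
diseases:

| family                | hazard on 21..84                        | ageing-related |
|-----------------------|------------------------------------------|----------------|
| late_exponential      | 2·10⁻⁶ e^{0.12x} (dementia-like)        | yes |
| mid_exponential       | 5·10⁻⁵ e^{0.07x} (CVD/cancer-like)      | yes |
| linear_rise           | 2·10⁻⁴ + 6·10⁻⁵(x−21) (gradual riser)   | yes |
| early_peak_decline    | 4·10⁻³ exp(−(x−30)²/288) (young-adult peak) | no |
| declining_exponential | 10⁻² e^{−0.06(x−21)} (falls with age)   | no |

Ground truth is *analytic*: a family is labelled ageing-related exactly
when its noise-free hazard, pushed through the banding algorithm, lands in
the very-high band. The three rising families do (the linear riser's exact
log-curve has GM adjusted R² ≈ 0.976; its baseline was set at 2·10⁻⁴ so
this documented invariant holds with margin rather than by a hair). The
two non-rising families have analytically negative fitted β: for the
early-peak family the log-hazard is an exact quadratic peaking at age 30,
and the OLS line through a quadratic peaking below the grid midpoint
(52.5) always slopes down.

Within-family diversity comes from per-disease parameter jitter:
amplitude-like parameters are rescaled log-normally
(exp(N(0, noise_scale))), shape parameters get additive
N(0, noise_scale·|value|). The default `noise_scale = 0.02` keeps
within-family spread of the same order as binomial sampling noise at the
default cohort size — families stay coherent clusters, which is the
panel's purpose; at several times this jitter the families smear into
overlapping filaments and no clustering method can recover them. Each
disease draws from its own random stream, split from the master seed by
disease index, so adding or removing diseases never perturbs the others;
output is bit-reproducible for a fixed seed.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: diagnostic delay and screening artefacts
(e.g. spikes at screening ages), period/cohort effects, correlated
multimorbidity between diseases, mortality-driven depletion, and
within-disease heterogeneity beyond smooth parametric jitter. Recovery
rates on the panel are an upper bound on what identically configured runs
would achieve on messier real curves.

## Other numerical conventions

- **Weighted quantiles** (median onset age): inverse-CDF with midpoint
  averaging when a quantile falls exactly on a mass boundary — identical
  to numpy's `averaged_inverted_cdf` on the expansion of ages repeated
  `d_x` times. Integer-year data make the convention visible (equal mass
  at 40 and 60 gives median 50), so it is fixed and tested, not left to a
  library default.
- Hazards must lie in [0, 1): a zero hazard is a valid "no onsets" curve,
  a hazard of 1 would diagnose the entire pool in one year and is
  rejected.
- The gap search range is capped at n − 1 clusters; k = n gives W = 0
  identically.

## Problem sizes

The test suite and the acceptance script run the panel at its reference
conditions (100 diseases, cohort 10⁶) with gap settings k_max = 12 and
B = 20–50, and the parameter-recovery experiment at 200 diseases — sizes
chosen so a full run completes in well under a minute on one core while
leaving every selection step (linkage, k, algorithm) genuinely exercised.
The defaults in the library itself (k_max = 30, B = 50) are sized for
real panels of a few hundred diseases.

## Known limitations

- First recorded diagnosis is a proxy for onset; the package inherits all
  its biases (diagnostic delay, screening, consultation patterns).
- The gap statistic's chosen k is the usual 1-SE heuristic; on data with
  genuine nested structure it can reasonably sit one or two above the
  coarsest family count (the merge tree, returned alongside, shows the
  full hierarchy).
- PAM returns a swap-optimal, not globally optimal, medoid set.
- Adjusted R² rewards smooth curves; sparse diseases with noisy log-rates
  get banded lower for reasons of sample size, not biology. The
  `min_positive_ages` threshold flags only the extreme cases.
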