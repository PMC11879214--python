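# Methods

## Model and assumptions

The package estimates how the joint profile of exposure–outcome effect sizes
(the ESP) varies over a space of candidate modifier covariates. Within any
subset of observations the association between exposure X_m and outcome Y is
summarised by the univariate model

    f(Y) = β₀ + β_m X_m + Σ_j α_j Z'_j + ε,

fitted once per exposure: linear regression (E_m = β_m) for continuous Y,
logistic regression (E_m = e^{β_m}) for binary Y. The working assumptions
are those of the window estimates: within a window the effect sizes are
approximately homogeneous, the exposures enter linearly, and confounders
(Z'_j) are adjusted linearly. The method is purely exploratory — it locates
regions of covariate space with distinct profiles; it does not test
individual interaction coefficients.

## Window cover

Continuous covariates are standardized (sample SD) only for the
nearest-neighbour search; all geometry is reported in original units. For
each observation the minimal axis-aligned box around it and its n−1 nearest
neighbours is measured per dimension; window sides are the 95th percentile
of the box sides (linear interpolation between order statistics) and gliding
steps their minimum, with a zero minimum (duplicate points) replaced by the
smallest positive side. Candidate centres form the grid Z_j^min + i·Δ_j,
i = 0..⌊(Z_j^max − Z_j^min)/Δ_j⌋, so windows may overhang beyond Z^max but
centres never exceed it. Membership intervals are closed on both ends.
Discrete covariates multiply the grid by their observed value combinations;
a stratum whose windows all fail the occupancy rules is reported as
uncovered, not treated as an error.

Occupancy rules: a window is retained with ≥ `min_obs` members (default:
the same n used for sizing) and, for binary outcomes, ≥ `min_class_count`
members of each class (default 5) — a logistic fit needs both classes, and
fewer than ~5 per class gives effectively unidentified odds ratios. A guard
rejects covers whose candidate grid would exceed 10⁶ windows (degenerate
steps from near-duplicate observations).

Tunable parameters: `n_target` (default 20; the dominant resolution/stability
trade-off — larger n gives wider windows, smoother profiles, fewer windows),
`percentile` (default 95), manual `sides`/`steps` overrides and
`side_scale`/`step_scale` multipliers for sensitivity analyses.

## Window effect sizes

Windows hold a few dozen observations, so for binary outcomes complete
separation is routine and unpenalized maximum likelihood diverges, turning
single windows into enormous outliers that dominate the standardized feature
space. Every window logistic fit therefore carries a weak L2 penalty on the
slope (`ridge`, default λ = 1.0 — the strength of the conventional default
in regularized logistic classifiers; the intercept is never penalized),
identical in every window so that effect sizes remain comparable across
windows. Fits that still fail to converge are refit with a stronger penalty,
and slopes are clamped to |β| ≤ 10 as a final guard. The solvers are
vectorised Newton–Raphson across exposures (the Monte-Carlo validation needs
~10⁶ tiny fits); they are checked against statsmodels in the test suite.

Feature scale: binary effect sizes enter the clustering on the **log
odds-ratio** scale by default (`log_odds=True`). The log scale is symmetric
around no-effect and keeps the standardized columns from being dominated by
the right tail of the odds-ratio distribution; with raw odds ratios the
benchmark operating characteristics degrade markedly (both false splits on
homogeneous data and missed splits on heterogeneous data). The raw-OR scale
remains available behind the flag.

Per-exposure standardization across windows uses the sample SD; zero-variance
exposures are dropped and recorded. Exposures failing in > 20% of windows
are dropped; isolated failures take the exposure's across-window mean raw
effect so the matrix stays complete. Within-window confounder adjustment is
configurable (`None`, `"covariates"` = the continuous modifiers themselves,
or an explicit list); the synthetic validation runs unadjusted, matching its
univariate design.

## Cluster-number selection

Ward linkage on Euclidean distance is used throughout: its objective is the
within-cluster quadratic error, which is exactly the inertia I_k driving the
elbow statistic, so the elbow and the clustering refer to the same
hierarchy. I_k is computed from the cluster labels at each cut; inside the
reference loop the identity I_k = Σ h²/2 over merge heights (exact for Ward)
avoids recomputing labels, and the two routes are asserted equal in tests.

Four indices vote over k ∈ [2, kmax] (elbow over [2, kmax−1]):
Calinski-Harabasz and silhouette maximised, Davies-Bouldin minimised, elbow
maximising δ_k = s_k/s_{k+1} − 1. The consensus k₁ is the most frequent
vote; no repeats or a tie resolve to the smallest vote. `kmax` defaults to
min(5, N_w − 1): with the few dozen windows a realistic cover yields, larger
search ranges let the score indices chase micro-clusters of correlated noise
and the benchmark's specificity collapses; in the package's own validation no
true design needs more than 5.

The one-cluster null is tested by drawing n_ref matrices (default 2000, so
p < 10⁻³ is attainable with resolution) with each feature uniform over its
observed range, computing each reference's δ_{k₁}, and rejecting when the
fraction exceeding the observed δ_{k₁} falls below α (default 10⁻³). When
the consensus lands at k₁ = kmax, the inertia curve is extended to k₁ + 1
rather than failing. If `fixed_k` is set the vote and test are skipped.

Known limitation: overlapping windows share observations, so under a truly
homogeneous ESP the window profiles form a smooth correlated field rather
than independent noise. Ward cuts of such fields show more prominent elbows
than the iid uniform references, which inflates false splits as overlap
grows (denser steps or wider windows). The validation quantifies this:
specificity on the no-modification design degrades from ~85-90% at the
baseline geometry to ~64% at halved steps and ~46% at 1.5× sides. Choosing
larger gliding steps restores specificity at the cost of resolution. A null
that preserved the overlap correlation (e.g. outcome permutation) would be
better calibrated but changes the procedure; the uniform reference is kept
as specified.

## Regions

Cluster centroids are means of member-window standardized profiles; the
dispersion σ is the SD of member-window coordinates per exposure (ddof 1;
0 for singleton clusters) — the only dispersion computable without
resampling. Point membership is the share of containing windows per cluster
label (fractions sum to 1; points outside every window are flagged
uncovered); a majority-label column is provided for convenience but no
defuzzification is imposed. Exposures are ranked by the largest
between-centroid gap (max − min across clusters), default top 20. The 2-D
view projects standardized profiles onto their first two principal axes
(centred, not rescaled; the largest-magnitude loading is made positive for
reproducible orientation).

## Synthetic benchmark

The generator emulates a balanced case-control metabolomics study: 100
observations per outcome class, 30 exposures, two modifiers Z₁, Z₂ ~ U(0,1).
Controls always draw X_m ~ N(2, 0.5²). Cases draw from region-dependent
distributions: design D1 has one region (no modification anywhere); D2 has a
shifted region B (Z₁, Z₂ > 0.5) where three random 10-exposure sets take
means 2, 2.7, 1.3 (SD 0.5); D3 adds region C (Z₁ > 0.5, Z₂ < 0.5) with an
independently drawn set partition. Region boundaries are smoothed: each
half-space indicator becomes a logistic ramp of width `smoothing_width`
(default 0.05 — a visible but narrow transition band; the width is a free
parameter of the generator and is reported with any run), and case regions
are sampled from the resulting membership probabilities.

What the generator does **not** emulate: correlated exposures, non-Gaussian
measurement error, missingness, confounding, or continuous outcomes. Passing
benchmarks therefore demonstrates the selection machinery under clean
conditions, not robustness to real-data pathologies; the preprocessing
module addresses some of those (missingness, skew) but is exercised on its
own tests.

## Validation scale and seeds

The packaged validation runs 100 replicates per condition in the test suite
and 150 in `scripts/acceptance.py` (the package's own desk-scale choice;
estimates carry ~±4 and ~±3 percentage-point binomial error respectively).
All randomness flows from explicit seeds: replicate seeds are spawned from a
master seed via `numpy.random.SeedSequence`, so validation rows are
reproducible and independent of execution order.

## Numerical choices

- Percentile: linear interpolation between order statistics.
- Standardization denominators: sample SD (ddof 1) everywhere.
- Newton solvers: gradient tolerance 1e-8 (vectorised) / 1e-9 (general),
  linear-predictor clip at ±30, damped steps near separation.
- Ties in nearest-neighbour searches follow the underlying library's
  deterministic ordering.
- δ_k with a zero denominator (s_{k+1} = 0, identical rows) is undefined and
  skipped in votes; reference draws with zero slope count as non-exceeding.
- p-values use a strict inequality (δ_ref > δ_obs), so nref bounds the
  attainable resolution at 1/nref.

One further limitation of the region map: windows that straddle a true
region boundary contain observations from both regions, so their profiles
fall between the cluster centroids and their labels are genuinely ambiguous
within roughly half a window width of the boundary. Agreement between
window-midpoint labels and a crisp ground truth is bounded accordingly (on
the two-region benchmark, adjusted Rand > 0.6 in about two thirds of
replicates; mismatches concentrate in the boundary band).
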