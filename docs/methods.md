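# Methods

This note documents the models and numerical choices behind
`chronosere`, what its synthetic data do and do not emulate, and the
design decisions taken where more than one reasonable convention
exists.

## Data model

A chronosequence substitutes space for time: plots at different stages
of recovery stand in for long-term monitoring of one site. Plots are
`active_cacao` / `active_pasture` (still in use, recovery age t = 0),
`secondary_cacao` / `secondary_pasture` (regenerating, t > 0 years), or
`old_growth` (reference, no age). The land-use *legacy* (cacao or
pasture) stratifies every fit; old-growth plots are shared between
legacies. Ages are real-valued years and are never rounded or binned.
Counts are non-negative reals; species and plots are identified by id
strings, never by position. All-zero species rows are tolerated on
input and dropped before any metric computation (no metric is affected;
the drop is logged).

## Diversity metrics

Alpha diversity is the Hill number
`D_q = (Σ p_i^q)^(1/(1−q))` (with the exponential-Shannon limit at
q = 1), computed from each plot's own relative abundances.

Pairwise compositional similarity offers three families:

- **Bray–Curtis similarity** `1 − ½ Σ |p_a − p_b|` on relative
  abundances (each plot normalized by its own total), delegated to
  `scipy.spatial.distance.braycurtis`.
- **Hill-partition overlap**: for a pair of equally weighted
  assemblages, alpha is the Hill number of the joint assemblage with
  within-plot relative abundances halved, gamma that of the mean
  profile, `D_beta = D_gamma / D_alpha ∈ [1, 2]`, transformed to
  `((1/D_beta)^(q−1) − 2^(1−q)) / (1 − 2^(1−q))` (and
  `1 − log2(D_beta)` at q = 1). This convention is pinned by the
  classical equivalences — Sørensen at q = 0, Horn at q = 1,
  Morisita–Horn at q = 2 — which the test suite verifies to 1e-10
  against independently coded textbook formulas on random communities.
- **Jaccard** on presence/absence, for the literature mode.

The similarity of a disturbed or recovering plot to the old-growth
state is its mean pairwise similarity to *every* old-growth plot.
ψRef for similarity metrics is the median, over old-growth plots, of
each plot's mean similarity to the remaining old-growth plots — full
recovery means being as similar to old-growth as old-growth plots are
to each other, which accommodates natural spatial variation in the
reference. For scalar metrics ψRef is the center of the old-growth
per-plot values. The center is the median unless the old-growth median
is 0, in which case the mean is used for *all* centers of that series
(recovery toward 0 is not biologically meaningful); the ±10% recovery
target always uses whichever center ψRef was computed with. Plots on
which a pairwise similarity is undefined (zero total) are dropped from
the series with a logged reason.

## Resilience decomposition

- **Resistance** `exp(−|ln(ψ0/ψRef)|)` equals `min(r, 1/r)` with
  r = ψ0/ψRef: bounded in [0, 1], 0 when the attribute is lost, 100%
  when active and reference levels coincide, and deliberately
  penalizing excesses above the reference (77% for a 30% excess vs 70%
  for a 30% deficit).
- **Fit**: only λ is free; ψ0 and ψRef are fixed at the data centers,
  because resistance is *defined* by those centers and the trajectory
  is meant to interpolate between them — freeing them would decouple
  the curve from the resistance it is paired with. A `free-psi0` mode
  exists as a config switch for sensitivity work (default `fixed`).
  Active plots enter the fit at t = 0 alongside the secondary plots of
  the same legacy. Optimizer: `scipy.optimize.curve_fit` with bounds
  λ ∈ [0, 10] /year, start 0.05 /year, ftol/xtol/gtol 1e-10. λ's
  standard error comes from the asymptotic covariance; significance is
  a two-sided Wald test against 0 at α = 0.05 (a zero SE from an exact
  fit counts as significant). A series with all values equal yields
  λ = 0, flagged non-significant, with undefined R². Fewer than 3
  points is a fit error.
- **Recovery time**: one code path covers recovery from below (target
  0.9 ψRef) and from above (1.1 ψRef) via the absolute value in
  `T_rec = −ln(0.1 ψRef/|ψRef − ψ0|)/λ`. Resistance > 90% short-
  circuits to T = 0 with no λ (undisturbed or instantly recolonized);
  for such taxa the reported 30-year relative recovery equals the
  resistance (flat-trajectory convention). λ = 0 with resistance ≤ 90%
  gives an infinite time (arrested candidate). The degenerate case
  |ψRef − ψ0| ≤ 0.1 ψRef with resistance ≤ 90% — reachable only under
  the mean rule — returns 0 with a warning.
- **Classification**: recovery times beyond a 300-year cap
  (configurable) are set to 0 when the mean ± sample-SD (ddof = 1)
  intervals of active and old-growth plot values overlap
  (`artefact_zeroed`: the huge time is an artefact of data spread) and
  kept, reported as `>300`, when they do not (`arrested`).

## Jackknife uncertainty

Each replicate deletes one plot — any plot of the focal legacy or any
old-growth plot — and reruns the entire pipeline from the abundance
matrix, so similarity values and ψRef are recomputed when a reference
plot is deleted. The bootstrap is deliberately avoided: with ~40 plots
it omits too much data per replicate for a stable nonlinear fit.
Reported intervals are percentile intervals (2.5th/97.5th, linear
interpolation between order statistics) over the replicate statistics;
curves get a pointwise percentile envelope on a time grid. Replicates
where the instant rule fires contribute T = 0 and no λ; λ intervals are
computed over defined replicates only, with the count reported.
Arrested replicates contribute infinite recovery times, which surface
as `>cap` upper bounds.

Percentile-of-replicates bands describe the spread of the
leave-one-out curves, which is the reporting convention mirrored here,
but leave-one-out replicates cluster tightly around the full estimate,
so these bands understate sampling uncertainty: on synthetic data they
contain the generating λ in only ~30% of repetitions. The classical
inflation-corrected jackknife standard error
(`SE² = (n−1)/n Σ (θ_i − θ̄)²`, `jackknife_se_interval`) is provided
alongside; its normal-theory interval covers the generating λ in ~94%
of 50 seeded repetitions, and the suite's coverage sanity check targets
that interval.

## Synthetic chronosequence generator

The generator emulates the targeted study design: per legacy 6 active
plots, 16–17 secondary plots with integer ages uniform on 1–38 years,
and 17 shared old-growth plots (62 plots in the two-legacy bundle).
An old-growth composition is drawn from a lognormal rank-abundance
model (σ = 1) over a pool of 100 species — a species-rich, strongly
uneven community typical of tropical inventories; a uniform model is
available. Each legacy's disturbed community mixes a surviving
old-growth fraction with a disjoint pool of disturbance specialists
(25% of the pool). Plots sample 500 individuals multinomially from a
Dirichlet-perturbed composition (concentration 200): enough depth and
concentration that sampling noise is visible but does not dominate.

Sampling noise attenuates measured Bray–Curtis similarities, and the
attenuation depends on how similar the compositions are, so applying
the recovery curve naively to the mixing weight would distort the
measured trajectory (and bias λ̂ upward by ~20%). The generator
therefore calibrates, once per dataset via seeded Monte Carlo with
common random numbers, the monotone response G from mixing weight to
pipeline-measured similarity ratio, and inverts it: the active
composition uses `G⁻¹(R)` and a plot of age t uses
`G⁻¹(R + (1−R)(1−e^(−λt)))`. The expected *measured* similarity then
follows the negative-exponential trajectory with the requested rate,
and Bray–Curtis is the calibration target for the requested resistance
(Hill-partition similarities are measured, not calibrated). Under the
default conditions (λ = 0.05 /year, resistance 40%, study-shaped
counts), the full pipeline recovers λ with ~5% median relative error
and resistance within a few percentage points, over 50 seeds.

What the generator does *not* emulate: mechanistic succession
(dispersal, interactions), patchy per-taxon sampling designs,
detection failure, spatial autocorrelation among plots, and the
biology behind arrested microbial recovery (approximable by λ = 0).
Passing parameter-recovery tests therefore shows the estimator chain
is consistent under the assumed sampling model, not that field data
meet those assumptions.

## Comparative analyses

Instant-recovery rows (resistance > 90%) carry no return rate and are
omitted from the cross-taxon analyses. The random forest (500 trees,
scikit-learn defaults otherwise, seeded) regresses recovery time on
resistance and return rate and reports impurity importances; results
are deterministic given seed and sorted input. Spearman uses midranks;
the Wilcoxon statistic is reported as V (sum of positive-difference
midranks, the R convention), with zero differences dropped, exact
p-values for n ≤ 10 without ties and the continuity-corrected normal
approximation otherwise. Kruskal–Wallis applies tie correction;
Benjamini–Hochberg FDR spans all tests submitted in one invocation
(the declared family). The literature mode restricts metrics to
richness (q = 0) and Jaccard — well defined without abundances —
requires ≥ 2 reference samples, ≥ 1 disturbed and ≥ 1 aged secondary
sample, and records an explicit reason for every skipped study.

## Degenerate inputs and tie-breaks

Zero-total abundance columns make similarity and Hill metrics
undefined: such plots are dropped from series with a logged reason
(abundance 0 itself is a valid value). An empty union makes Jaccard
undefined. ψRef ≤ 0 makes resistance undefined. Replicates rendered
degenerate by a jackknife deletion (e.g. no active plot left) are
excluded and logged, with the exclusion count visible on the ensemble.
File dialects: UTF-8, TSV by default with comma auto-detected from the
header; outputs are TSV. Logs go to stderr; the CLI exits 0/2/3 for
ok/validation/computation failures.

## Problem sizes used in the checks

The parameter-recovery checks run 50 seeded datasets of one legacy
(6 + 17 + 17 plots, 100 species, 500 individuals per plot); the
jackknife coverage check runs 50 seeded datasets of 6 + 16 + 17 plots.
These sizes match the emulated study design; larger pools or depths
only sharpen the estimates.

## Known limitations

- The recovery model is a single negative exponential by design;
  alternative shapes (linear, logarithmic, logistic) are out of scope,
  and long extrapolations (recovery times far beyond the 38-year
  chronosequence span) inherit its assumptions.
- Coverage-standardized (rarefied/extrapolated) Hill numbers are not
  implemented; observed counts are used as-is.
- The percentile jackknife band is a curve-spread summary, not a
  calibrated confidence interval (see above).
- Resistance conflates direction: 70% could be a deficit or a smaller
  excess; consumers needing direction should inspect ψ0 vs ψRef.
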