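# Methods

## The experimental design being modelled

A group-feeding trial offers m = 8 food-deprived *Berghia stephanieae* a
circle of n = 8 evenly spaced *Exaiptasia diaphana* (a 1:1 predator:prey
ratio, so feeding alone is always possible). After 20 minutes each trial is
reduced to three scalars: the mean size of the groups actively feeding at
the endpoint, the largest co-feeding group seen at any point during the
trial, and the number of slugs not feeding. The packaged table holds 15
trials at 7 days of deprivation and 13 at 3 days. Two-alternative choice
assays offer one slug a pair of anemones differing by a single manipulated
cue; their tables record per condition the sample size, the number choosing
the manipulated ("social") option, and trials omitted because no choice was
made within 30 minutes.

A known quirk of the trial table is preserved verbatim: one trial records a
whole-trial maximum (1) smaller than its endpoint mean (1.4), which is
possible only because the two statistics are taken at different times. The
loader warns on such rows but never rejects them — the printed aggregates
must be reproducible exactly as published. Sample standard deviations use
the n−1 denominator; medians use the midpoint convention for even n.

## Uniform-choice null model

Under the null each feeding slug picks anemone i with probability 1/n,
independently. Per-trial statistics are the mean group size over occupied
anemones and the maximum occupancy; a dataset of T trials is summarised by
the dataset mean of each. The Monte-Carlo p-value is the fraction of
simulated datasets whose statistic is **greater than or equal to** the
observed one, with no add-one correction — an observed statistic above the
entire simulated support legitimately reports P = 0. 100,000 datasets per
comparison, matching the published procedure.

**Feeder conditioning.** The observed per-trial statistics are computed over
feeding slugs only, so the default comparison conditions each simulated
trial on the observed feeder count (8 − non-feeders for the matching
experimental trial). This is both the fair comparison — non-feeding slugs
carry no information about prey choice — and, empirically, the procedure
that reproduces the published tail probabilities; seating all 8 slugs in
every simulated trial shifts the null distribution upward by enough to
change the p-values by two orders of magnitude. The all-slugs-feed variant
remains available (`feeders_per_trial=None`) and is always reported as a
sensitivity run.

An exhaustive enumeration of all n^m assignments (`exact_null_distribution`,
guarded at n^m ≤ 10^7) serves as the small-problem oracle for the sampler.

## Social dining model

Sequential seating with k slugs already feeding:

- join the group on occupied anemone i: probability m_i / (k + α);
- open a new group: probability α / (k + α), the anemone drawn uniformly
  from those unoccupied (one always exists because the model assumes
  n ≥ m); the first slug seats uniformly.

The denominator is (number already seated) + α — the standard Chinese-
restaurant-process normalisation, and the only reading under which each
step's probabilities sum to one. A fixed-m denominator variant was checked
and cannot even reach the observed statistic at any α. Anemone identities
do not affect group-size statistics, so the batched sampler tracks only
group sizes; the labeled single-trial sampler and the batch sampler are
cross-checked against each other and against exhaustive enumeration of the
seating tree (the partition law is exchangeable and matches the closed-form
CRP partition probability).

**Concentration-parameter fit.** α is estimated by moment matching: the
Monte-Carlo expectation of the dataset mean of per-trial mean group sizes
is strictly decreasing in α, so bisection on α converges against an
observed target. Defaults: bracket [1e-6, 1e3], 10,000 datasets per
evaluation, tolerance 1e-3 on the statistic, at most 100 iterations.
Every evaluation reseeds the generator identically (common random numbers),
making the objective a deterministic, monotone step function of α and the
whole fit reproducible. The matched statistic is the mean (the headline
statistic, and monotone); the max is available as an option. The fit seats
all m slugs — the model itself has no non-feeding state — while fitting
against per-trial feeder counts is possible via `feeders_per_trial`.

Targets outside the attainable range (1, mean trial size) are rejected; a
bracket that cannot straddle the target pins the fit at the nearer endpoint
with `converged=False` rather than silently extrapolating.

**Tail probabilities under the fitted model.** `sdm_pvalue` uses the same
≥-tail convention as the null. Note an arithmetic consequence of moment
matching: the fitted α centres the simulated distribution of the matched
statistic on its observed value, so the upper-tail probability is near 0.5
(about 0.44 for the mean and 0.86 for the max at the fitted parameter)
rather than 1. That is the quantitative form of "the observed data sit
inside the model's distribution"; a tail probability of 1 would require
the observed value to fall below the entire simulated support, which the
fit construction rules out.

## Choice-assay statistics

- **Exact binomial test** (scipy's implementation behind the module
  surface): two-sided by the minimum-likelihood rule — the sum of the
  probabilities of all outcomes no more likely than the observed count —
  which at p₀ = 0.5 equals doubling the smaller tail, capped at 1. The 95%
  interval on the proportion is Clopper-Pearson by default; a Jeffreys
  (Beta(½,½) posterior) interval is available since only the interval, not
  the p-value, depends on the choice.
- **Welch's t** with Welch-Satterthwaite df; two degenerate zero-variance
  samples with equal means report t = 0, p = 1. When both samples have
  exactly equal variances and sizes it coincides with the pooled t.
- **One-sample Wilcoxon signed-rank**: midranks of absolute deviations,
  V = sum of positive-deviation ranks, normal approximation with
  continuity correction and tie-corrected variance, effect size r = z/√n.
  This approximate method is the one consistent with the published
  statistic-and-p pair (V = 231 is the maximum rank sum for n = 21, and
  the printed p is far from the untied exact sign-flip p, indicating ties
  plus approximation in the original analysis). An exact enumeration
  (dynamic programme over the 2^n sign patterns) is available for n ≤ 25
  without ties. Latencies are log-transformed by a helper before any
  location test.

## Synthetic data

`synthetic_data` generates study-shaped data with known ground truth:

- **Group trials**: per-slug feeding thinned independently with
  `feeding_prob` (default 1 — the models assume every slug feeds), feeders
  seated by either model, endpoint statistics recorded. Zero-feeder trials
  are kept with missing group statistics. Non-feeding as independent
  thinning is a modelling convenience; real non-feeding may be state- or
  interaction-dependent.
- **Choice records**: i.i.d. Bernoulli(p_social) outcomes.
- **Individual scores**: per-individual choice probability drawn once —
  shared 0.5 at heterogeneity 0, otherwise Beta(a, a) with total
  concentration 1/heterogeneity — then n_tests (default 4) Bernoulli
  choices. Large heterogeneity produces the bimodal score distribution a
  population of fixed social/solitary personalities would show.

Defaults mirror the experimental design (m = n = 8; 15 or 13 trials;
choice-assay sample sizes in the twenties). What the generators do *not*
emulate: arena geometry and movement, time-resolved group membership
(joining/leaving), latencies beyond an optional transform, and any
dependence between trials. Passing tests therefore validate the inference
machinery, not the behavioural realism of the models.

## Problem sizes and numerical conventions

Monte-Carlo comparisons use the published 100,000 datasets; bisection uses
10,000 datasets per evaluation (Monte-Carlo standard error on the matched
statistic ≈ 0.001, i.e. α resolved to ≈ 0.01). Distributional test
properties use 200,000 draws against enumeration oracles (chi-square at
α = 0.001) and 5,000 replicates for p-value calibration (KS distance
< 0.02; calibration uses 30-trial datasets, where the dataset statistic's
support is fine enough that the discreteness of the empirical p-value is
negligible). The p-value calibration, oracle-equivalence and
parameter-recovery properties run in the regular test suite.

All randomness flows through numpy Generators seeded from a single run
seed; simulated batches are vectorised across trials (the CRP advances all
trials one seating step at a time), which is why full-scale runs complete
in seconds.

## Known limitations

- The simulated maximum group size is the endpoint maximum occupancy,
  whereas the experimental maximum was recorded over the whole trial. The
  comparison inherits this asymmetry from the original design; it biases
  the max-statistic p-values conservatively upward if anything, since the
  over-time maximum can only exceed the endpoint one.
- The concentration-parameter fit is moment matching, not likelihood; no
  uncertainty interval on α is produced beyond the Monte-Carlo resolution.
- The home-tank proportion test, the latency ANOVAs and the
  individual-consistency analyses (Fisher, bimodality, repeatability)
  require raw data the published tables do not contain; the corresponding
  test machinery is implemented and property-tested, but those published
  numbers cannot be recomputed from the fixtures.
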