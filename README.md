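# berghia-social

Group-formation statistics for social predation assays in the nudibranch
*Berghia stephanieae*, a specialist predator of the sea anemone *Exaiptasia
diaphana*. The package asks a simple behavioural-ecology question with
simulation models: when m slugs are offered n anemones at a 1:1
predator:prey ratio, are the feeding groups they form larger than expected
if each slug chose its prey independently — and if so, how strong is the
aggregation?

It is written for behavioural ecologists who want to re-run or extend the
analysis: the published trial tables ship as fixtures, every inference step
is a library function, and a synthetic-data generator produces study-shaped
data with known ground truth.

## Models

**Uniform-choice null.** Each feeding slug independently selects anemone
*i* with probability 1/n. A simulated trial yields a mean group size (slugs
per occupied anemone) and a maximum group size; a simulated dataset of T
trials yields the dataset means of those statistics. The Monte-Carlo
p-value is the fraction of 100,000 simulated datasets whose statistic is at
least as large as the observed one (no pseudo-count, so P = 0 is possible).
Each simulated trial is conditioned on the observed number of actively
feeding slugs in the corresponding experimental trial; an all-slugs-feed
sensitivity variant is also reported.

**Social dining model (SDM).** A Chinese restaurant process over a finite
set of anemones: with k slugs already seated, the next slug joins the group
on occupied anemone *i* with probability m_i / (k + α) and opens a new
group (a uniformly chosen empty anemone) with probability α / (k + α). The
concentration parameter α is the aggregation dial — α → 0 seats everyone on
one anemone, α → ∞ gives independent singletons. α is estimated by moment
matching: bisection until the simulated expectation of the dataset mean
group size equals the observed statistic, with common random numbers across
evaluations.

**Choice assays.** Two-alternative assay outcomes are tested against chance
with the exact binomial test (minimum-likelihood two-sided p,
Clopper-Pearson or Jeffreys 95% interval); group sizes across deprivation
conditions with Welch's t; proportion data with the one-sample Wilcoxon
signed-rank test (normal approximation with continuity and tie corrections,
effect size r = z/√n, exact enumeration for small untied samples).

## Worked example

```sh
$ python analysis/02_null_model_pvalues.py
7-day mean: observed 1.8220  P = 3e-05  (all-feed sensitivity P = 0.00276)
7-day max: observed 3.0000  P = 0  (all-feed sensitivity P = 0.02299)
3-day mean: observed 1.8508  P = 0.00028  (all-feed sensitivity P = 0.00193)
3-day max: observed 3.0000  P = 0.00085  (all-feed sensitivity P = 0.03333)
```

The observed dataset mean of per-trial mean group sizes (1.82 after 7 days
of food deprivation, 1.85 after 3) essentially never occurs among 100,000
datasets simulated under independent prey choice: the slugs aggregate.
Fitting the social dining model to the 3-day data,

```sh
$ python analysis/03_fit_social_dining.py
concentration parameter alpha = 3.9673 (target 1.8508, achieved 1.8500, 16 evaluations, converged=True)
SDM tail P (3-day mean): observed 1.8508  P = 0.4443
SDM tail P (3-day max): observed 3.0000  P = 0.8569
...
```

a single concentration parameter near 4 places every observed statistic —
from both deprivation conditions — comfortably inside the simulated
distribution, so hunger state does not change the strength of aggregation.

The same pipeline is available as a CLI (`berghia-social reproduce`,
`pvalue`, `fit-sdm`, `test-choice`, `synth`, ...) and as library calls:

```python
from berghia_social import NullConfig, load_packaged_trials, null_pvalue, summarize

seven = load_packaged_trials().subset(7)
cfg = NullConfig(m=8, n=8, trials_per_dataset=15, n_datasets=100_000,
                 seed=1, feeders_per_trial=seven.feeders_per_trial)
print(null_pvalue(summarize(seven).mean_of_means, "mean", cfg).p_value)
```

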