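# Methods

## The model

The quantity estimated is the fraction of an observed bird population that
died from external oil exposure. For a species with `N` total detections,
`n_assessed` birds scored for oiling, and `n_c` assessed birds in oiled
category `c` (trace, light, moderate, heavy), each Monte Carlo iteration
computes

```
E_c ~ Binomial(N, n_c / n_assessed)        exposed birds per category
m_c ~ Uniform(low_c, high_c)               one draw per category per iteration
D_c ~ Binomial(E_c, m_c)                   deaths per category
decrease = sum_c D_c / N
```

and 100,000 iterations are summarized by the median and the 2.5th/97.5th
percentiles (linear interpolation between order statistics, numpy's default
quantile rule).

Key modelling readings, each of which was genuinely open:

* **Denominators.** Category exposure rates are estimated over the assessed
  sample (`n_c / n_assessed`) because only assessed birds have category
  information; the binomial is applied to all `N` detections, and the
  decrease divides by `N`. This treats the assessed birds as a random
  subsample of the detected population with respect to oiling — the closed
  forms this reading implies land on the reported medians, which supports it.
* **One mortality draw per category per iteration, not per bird.** The
  panel's range is epistemic uncertainty about a category's true mortality
  rate, not bird-to-bird variability. A per-bird draw would average the
  uniform away and collapse the intervals far below anything plausible; with
  a per-category draw the interval for a trace-only scenario is dominated by
  the uniform's own quantiles, which is the behaviour the published gannet
  interval shows.
* **Independent per-category binomials.** `E_trace, E_light, ...` are drawn
  independently rather than multinomially. Their sum can in principle exceed
  `N`; such an iteration is discarded and redrawn (counted in
  `n_resampled`). At the observed rates (pooled oiling ≤ 24%) this
  essentially never fires; it matters only for pathological inputs, which
  the tests exercise deliberately.
* **`uniform_any` assigns each exposed bird a category independently** with
  probability `1/k` over the categories in play (default trace, light,
  moderate — heavy is excluded because no heavily oiled bird was ever
  recorded, and including it would shift the scenario away from the
  published value). Its closed-form expectation is
  `(pooled rate) × mean(midpoints) = 3.68%` for the gannet, somewhat above
  the published 3.4%; the original work did not describe its assignment
  scheme, so the mode is exposed as an explicit `ScenarioSpec` choice and
  the discrepancy documented rather than hidden.

The analytic companion `expected_decrease` — `Σ_c rate_c × midpoint_c` —
serves as the oracle for the simulation mean throughout the tests.

### Known divergence on one interval bound

Under this reading the loon 97.5th percentile is stable at ~16.3–16.4%
across seeds, versus the published 15.8%. Alternatives were checked
(multinomial category split, dropping the survival binomial, a
mean ± 1.96 sd interval, deterministic expected exposure counts): only
fixing the exposure counts at their expectations reproduces both published
upper bounds closely, but that contradicts the explicitly stated random
binomial exposure draw, so the faithful variant is kept and the ~0.5-point
divergence on this one bound is accepted and documented. All medians and
the gannet bounds agree with the published values to ≤0.3 points.

## Survey arithmetic

* **Oiling categories** are contiguous half-open surface bands: none = 0%,
  trace (0, 5], light (5, 20], moderate (20, 40], heavy (40, 100]. The
  published labels leave gaps (trace "<5%", light "6–20%"); these are
  printing artifacts, and the seams here give every surface fraction exactly
  one category.
* **Species oiling rate** = oiled / assessed (e.g. pelican 347/2050 =
  16.9%). Unassessed birds carry no category at all — absence of evidence —
  and never enter a denominator.
* **Per-state rates** divide a state's oiled count by its *assessed* count.
  The published per-state count columns sum exactly to each species'
  assessed total (pelican 1819+27+204 = 2050, loon 64+13+9+20 = 106), so
  they are assessed counts, and this denominator reproduces every published
  state percentage (69/204 → 34%, 276/1819 → 15%, 2/27 → 7%). One published
  inconsistency is reproduced as-is: the Louisiana loon rate prints as 33.3%
  with n = 64, but 21/64 = 32.8%.
* **Photo review** is an explicit operation: post-hoc category upgrades by
  record id, applied immutably, which is how two gannets moved from none to
  trace (4 → 6 oiled of 87).
* **Rounding** is display-only, half-up (via `decimal`): integer percents in
  table cells, one decimal for in-text rates and simulation results.
  Internal values are exact fractions of integer counts.

## Mortality table

The built-in table holds the expert panel's ranges (fractions): pelican
0–30 / 15–70 / 40–100%, loon 0–60 / 80–90 / 90–100%, gannet
0–40 / 30–80 / 70–100% for trace / light / moderate. Per-species heavy
ranges were never itemized; heavily oiled birds were judged 95–100% likely
to die regardless of species, so heavy defaults to [0.95, 1.00] everywhere.
No heavily oiled bird occurs in the survey data, so nothing downstream
depends on it. JSON interchange files store percents; the loader divides
by 100. Within a species both range ends must be non-decreasing with
severity; the loader rejects tables that violate this.

## Synthetic surveys

`generate_survey` draws `n_observed` records with multinomial state
allocation, Bernoulli(assessment_prob) assessment, and a categorical oiling
distribution conditional on assessment; grid cells cycle round-robin within
state and dates are uniform over the survey window. Defaults mirror the
pelican survey (85% assessment, trace-dominated mix at ~17% pooled oiling).
What it deliberately does **not** emulate: detection bias with distance,
pre-survey mortality of heavily oiled birds, spatial clustering of oil, or
survey-effort structure. Passing parameter-recovery tests therefore shows
the pipeline's arithmetic is right under its own assumptions, not that
field rates are unbiased — the real survey rates are explicit
underestimates for exactly those unmodelled reasons.

`reference_survey` is the deterministic counterpart: a record list whose
tally reproduces the published per-species and per-state counts exactly.
The only unprinted quantity — which states the unassessed birds were in —
is allocated proportionally to the printed per-state counts by largest
remainder, and nothing asserts against it.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit integer seed and builds a single
`numpy.random.Generator`; identical inputs and seed give bit-identical
output, including the interval bounds. The simulation is vectorised across
iterations, so the full 100,000-iteration run per species completes in well
under a second; tests use 100,000 iterations for checks against published
values and 2,000–30,000 for structural properties, with tolerances derived
from binomial/Monte-Carlo standard errors (typically 4 SE) rather than
fixed constants.
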