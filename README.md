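# oilimpact

Exposure assessment and population-impact simulation for wintering
waterbirds oiled by the Deepwater Horizon spill.

After the 2010 blowout, winter surveys in the northern Gulf of Mexico
recorded American white pelicans (AMWP), common loons (COLO) and northern
gannets (NOGA), scoring each clearly visible bird (>50% of body surface
observable) into ordinal oiling categories — none, trace (0–5% of body
surface), light (5–20%], moderate (20–40%], heavy (>40%). An expert panel
supplied the probability that an oiled bird dies as a range per species and
category. This package reproduces that analysis pipeline for anyone doing
wildlife injury assessment:

1. **Tallying** — per-bird observation records (CSV) are reduced to
   per-species and per-state counts: birds observed, birds assessed, and
   assessed birds per oiling category, with oiling rates computed over the
   assessed sample.
2. **Monte Carlo simulation** — starting from the total detections *N* of a
   species, each iteration draws the number of exposed birds per category
   `E_c ~ Binomial(N, n_c / n_assessed)`, one mortality probability per
   category `m_c ~ Uniform(low_c, high_c)` from the panel range, and deaths
   `D_c ~ Binomial(E_c, m_c)`. The population decrease for the iteration is
   `Σ_c D_c / N`; 100,000 iterations are summarized by the median and the
   2.5th/97.5th percentiles. The estimate is an *observed-population*
   impact, not a total-population decline.
3. **Synthetic surveys** — a generator draws observation records with the
   same statistical structure (multinomial states, Bernoulli assessment,
   categorical oiling), so the whole pipeline is testable and parameter
   recovery demonstrable without the original field data.

## Worked example

```python
from oilimpact import (PopulationDecreaseModel, Species, exposure_rate,
                       reference_survey)

records = reference_survey(Species.COLO)          # 1148 loon observations
model = PopulationDecreaseModel.from_records(records, Species.COLO)
print(round(exposure_rate(model.tally), 4))       # 0.2358  (25/106 assessed)
res = model.fit(n_iterations=100_000, seed=1)
print(res.summary())
```

```
Population decrease - Monte Carlo simulation
====================================================
Species:            COLO
Scenario:           as_observed
Iterations:         100000
Seed:               1
----------------------------------------------------
Median decrease:    10.7%
95% CI:             5.6% - 16.4%
Analytic E[dec]:    10.8%
====================================================
```

Of 1148 loons detected, 106 could be assessed and 25 of those (23.6%) were
visibly oiled. Propagating those rates through the panel's mortality ranges,
the simulation's central estimate is that oil exposure removed about 10.7%
of the observed loon population, with a 95% interval of roughly 6–16%.
`ScenarioSpec` selects how oiled birds are spread over categories: the
default `as_observed` uses the tallied per-category counts; `all_trace` and
`uniform_any` pool the oiled rate for species (like the gannet) whose
assessed sample was too small to trust the category split.

The same pipeline is available from the shell:

```sh
oilimpact --out-dir out tally --observations obs.csv
oilimpact --out-dir out mcs --tally out/tally_COLO.json --iterations 100000 --seed 1
oilimpact --out-dir out simulate --config cfg.json --out records.csv
```

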