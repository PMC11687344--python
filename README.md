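# metaoccu

Tools for asking whether habitat restoration in cities durably enriches wild
pollinator communities — and for the statistical machinery that question
needs. The package targets the study design in which restored and control
parks are surveyed repeatedly within and across years, pollinator–plant
interactions are recorded, and a phytometer plant measures pollination
service: it estimates how restoration, woody floral resources and dietary
specialisation drive pollinator *metacommunity dynamics* (initial occurrence,
colonisation, persistence) while correcting for imperfect detection, then
projects the consequences for species richness and scores a paired
pollen-supplementation experiment.

It is written for community ecologists and conservation analysts who have
long-format survey tables and interaction edge lists and want a tested,
scriptable pipeline rather than a one-off analysis.

## The models

**Specialisation.** From a pollinator × plant-genus count matrix `A` the
package computes each species' degree and Blüthgen's standardised
specialisation

    d_i = Σ_g p'_ig ln(p'_ig / q_g),        d'_i = (d_i − d_min) / (d_max − d_min)

where `p'_ig` are the species' interaction frequencies and `q_g` the
availability of each genus (its share of all interactions). The ceiling is
`d_max = ln(m / A_i)`; the floor is the best integer allocation of the
species' interactions, found by largest-remainder rounding plus local swaps
and pinned against brute-force enumeration in the tests. `d' ∈ [0, 1]` runs
from perfect opportunism to perfect specialisation.

**Occupancy.** Let `Z[i,j,k]` be the latent presence of species `i` at site
`j` in year `k`, with `Ψ1` the first-year occurrence probability and, for
later years,

    Ψ[k] = φ[k] · Ψ[k−1] + γ[k] · (1 − Ψ[k−1])

(persistence `φ`, colonisation `γ`). Detection on survey `l` is
`V ~ Bernoulli(Z · p)`. Each probability gets a logit-linear predictor with
species intercepts drawn from community distributions; `Ψ1`, `γ` and `φ` carry
effects of d', restoration, woody floral abundance and the d' interactions
(`φ` uses the previous year's woody resources), and `p` carries degree, a
species-specific quadratic date phenology, survey flower abundance and year
offsets. The latent `Z` is marginalised out of the likelihood by a two-state
forward recursion, and the posterior is sampled with the package's
Hamiltonian Monte Carlo sampler using analytic gradients. A fit is declared
converged only when split R-hat < 1.05, the effective-sample-size ratio
exceeds 0.1 and no trajectory diverged.

**Richness projection.** For each posterior draw the occurrence process is
re-simulated at hypothetical restored/control sites and richness is the
species sum, giving full posterior richness distributions and paired
scenario contrasts (common random numbers across scenarios).

**Pollen limitation.** Control/supplemented flower pairs are scored by their
seed ratio (pairs excluded when the supplemented flower set no fruit or the
control out-produced it two-fold; "limited" means the control made less than
half the seeds), then modelled as `logit(θ_j) = β0_j + β1·restored_j` with
site random intercepts.

A synthetic-data generator (`metaoccu.simulate`) forward-simulates the whole
design with known truth — occupancy dynamics, detection phenology,
interaction networks with a controllable specialisation gradient, pollen
pairs — so every stage of the pipeline can be validated without field data.

## Worked example

```python
import numpy as np
from metaoccu import (GeneratorConfig, generate_dataset, fit, SamplerSettings,
                      summarize, Scenario, scenario_contrast, d_prime,
                      fit_pollen_model, score_pairs, limitation_probability)

data = generate_dataset(GeneratorConfig(n_species=40, n_sites=12,
                                        n_restored=6, seed=1))
scores = d_prime(data.network)

draws, report = fit(data.detections, data.covariates,
                    settings=SamplerSettings(iterations=1200, warmup=600,
                                             chains=2, seed=1))
mean, bci50, bci95, label = summarize(draws, "psi1[1]")   # restoration slope

contrast, summary = scenario_contrast(
    draws, Scenario(restored=1, woody_z=0.0, years=3),
    Scenario(restored=0, woody_z=0.0, years=3), data.covariates, seed=7)

pairs = score_pairs(data.pollen_pairs.drop(columns=["restored"]))
pfit = fit_pollen_model(pairs, dict(zip(data.pollen_pairs.site_id,
                                        data.pollen_pairs.restored)), seed=1)
```

Printed output of the full script (`python examples/worked_example.py`,
~1 minute):

```
40 species detected at 12 sites over 3 years
network specialisation: mean d' = 0.34 (SD 0.10)
fit: max R-hat = 1.033, divergences = 0
  restoration -> initial occurrence: +2.36 [95% BCI +1.72, +3.07] (strong)
  restoration -> colonisation: +0.88 [95% BCI -0.00, +1.73] (marginal)
  woody flowers -> colonisation: +2.12 [95% BCI +1.42, +2.95] (strong)
  d' x woody -> colonisation: +1.54 [95% BCI +0.87, +2.25] (strong)
richness gain from restoration, year 1: 15.6 species [95% BCI 9, 22]
pollen limitation in control parks: 30% (intercept -0.84)
```

Reading it: the synthetic community was generated with a strong positive
restoration effect on initial occurrence (+2.26 on the logit scale), positive
woody and d'×woody effects on colonisation (+1.60, +1.36) and a true
pollen-limitation probability of 0.3 — the fit recovers each sign and
magnitude, the posterior richness contrast shows restored sites holding more
species from year one, and the pollen intercept maps back to the simulated
~30% limitation probability through the inverse logit.

The same pipeline runs from the shell: `metaoccu simulate | ingest | dprime |
fit | summarize | project | pollen` (see `metaoccu --help`).

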