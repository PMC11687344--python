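# Methods

This note records the statistical models implemented in `metaoccu`, the
numerical choices behind them, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Data model and covariate preparation

Surveys arrive long-format (species × site × year × survey with capture
counts, day-of-year and floral counts) and are collapsed to a binary
detection tensor `V[i,j,k,l] = 1{count > 0}`. Three conventions matter:

* **Masking, not imputation.** A site-year-survey with no record is treated
  as *not conducted* and masked out of the likelihood; the Bernoulli
  detection model applies only to surveys that happened.
* **Never-detected species are excluded.** A species with zero detections
  anywhere contributes no likelihood information about its own parameters
  (its posterior would be prior-driven and its inclusion would bias the
  community hyper-parameters); such species are removed and reported.
  Downstream richness estimates therefore condition on the detected
  community.
* **Standardisation.** Continuous covariates are z-scored: day-of-year over
  all conducted surveys jointly (one standardiser, so phenological peaks are
  comparable across years), survey floral abundance and woody abundance on a
  log1p scale (zero counts occur in mown control lawns, so a plain log is
  unusable), and degree as log-then-z because it is strongly right-skewed.
  The restoration flag stays binary. Standardisers are retained so
  projection scenarios can be phrased on either scale.

Indices are 1-based in files and 0-based in memory; the conversion happens
only at the I/O boundary.

## Specialisation (d')

Availability `q_g` is each plant genus's share of all interactions in the
pooled network. For species `i` with row `A[i,·]` and total `A_i`:

* `d_i = Σ_g p'_ig ln(p'_ig/q_g)` over used genera (natural log).
* `d_max = ln(m/A_i)`: exclusive use of a genus whose interactions are
  entirely the species' own.
* `d_min`: the smallest `d` achievable by an *integer* allocation of `A_i`
  interactions, found by largest-remainder proportional rounding (remainder
  ties break to the lower genus index) followed by local one-unit swaps
  until no swap lowers `d`. The heuristic is pinned against exhaustive
  enumeration for all species with `A_i ≤ 6` in networks of ≤ 4 genera.
* `d' = (d − d_min)/(d_max − d_min)`, clipped to `[0, 1]`; a degenerate
  network where `d_max = d_min` (the species is the whole network) scores 0
  because a species with no alternatives carries no specialisation signal.

External interaction records are ordinary edge-list rows; a `source` column
is carried for provenance only.

## The dynamic occupancy model

Latent occurrence `Z[i,j,k]` follows `Ψ1` in year one and the recursion
`Ψ_k = φ_k Ψ_{k−1} + γ_k (1 − Ψ_{k−1})` afterwards; detection is
`V ~ Bernoulli(Z·p)`. Logit-linear predictors:

| rate | terms |
|------|-------|
| `Ψ1` | species intercept + (d', restored, woody₁, d'×restored, d'×woody₁) |
| `γ`ₖ | species intercept + (d', restored, woodyₖ, interactions) + year offset |
| `φ`ₖ | species intercept + (d', restored, woody_{k−1}, interactions) + year offset |
| `p`  | species intercept + degree + date + date² (species-specific) + survey flowers + year offset |

Persistence into year `k` is driven by the *previous* year's woody resources
(the lag reflects resource-dependent overwinter survival and site fidelity of
largely annual insects); colonisation responds to the destination year.

**Marginalised likelihood.** For each species-site, the likelihood sums over
all `2^K` occupancy sequences via a two-state forward recursion. Emissions
are rescaled per year so running quantities stay O(1): in a year with a
detection the absence emission is zero and the occupied emission is scaled to
one (its log moves into the normalising constant); in years without
detections the emissions are `exp(Σ log Bernoulli)` and 1. The recursion is
exact (tested at 1e-10 against enumeration) and smooth in the parameters.

**Gradients and sampling.** The log posterior's gradient is computed by a
manual reverse-mode sweep through the forward recursion and the linear
predictors — validated against finite differences for both model variants.
Sampling is plain Hamiltonian Monte Carlo: leapfrog integration with
trajectory lengths jittered uniformly in `[1, 24]` steps, dual-averaging step
size tuned to an acceptance target of 0.85, and a diagonal mass matrix
estimated from the middle half of warmup. A trajectory whose energy error
exceeds 1000 counts as divergent and is rejected. Chains run sequentially
from independent RNG streams spawned from one seed, so fits are exactly
reproducible.

**Hierarchy and parameterisation.** Species intercepts on all four rates and
the phenology coefficients `p_2`, `p_3` are normal with estimated community
mean and SD, implemented non-centred (`θ_i = μ + σ z_i`); hyper-SDs are
sampled on the log scale with the Jacobian included. Year offsets are fixed
effects with the first level pinned to zero for identifiability against the
intercepts. Priors are weakly informative on the logit scale: Normal(0, 2)
for community slopes, hypermeans and year offsets; half-Normal(0, 1.5) for
hyper-SDs. All are overridable through `PriorConfig`.

**Diagnostics.** Split R-hat and bulk ESS are computed per scalar (arviz); a
`FitReport` declares convergence exactly when max R-hat < 1.05, min ESS/draws
> 0.1 and there were no divergences. A failed gate still returns the draws,
with a logged warning, so the diagnostics can be inspected.

**Defaults.** 4000 iterations per chain with the first 2000 discarded,
4 chains. The validation suite and the acceptance script use shorter chains
(1200/600, 2 chains) at 40 species × 12 sites × 3 years × 6 surveys — the
scale at which the package's recovery checks are run — which this sampler
mixes adequately for the community-level slopes.

**Random-slopes variant.** An a-posteriori model replaces the community d'
effects with species-specific random slopes for restoration and woody
abundance on `Ψ1`, `γ` and `φ` (hierarchically shrunk, non-centred), and then
correlates the per-species slopes with d' per posterior draw. Specialisation
thus enters only after the fit, as a posterior correlation distribution.

## Richness projection

For a scenario (restored or not; a fixed standardised woody abundance applied
to all years, including the persistence lag) each posterior draw's parameters
simulate Bernoulli occurrence trajectories for every species; richness in a
year is the species sum. Contrasts between scenarios reuse the same
random-number stream within a draw (common random numbers), so demographic
noise cancels from the paired difference. The analytic expectation
`Σ_i Ψ[i,k]` from the deterministic recursion is implemented alongside and
serves as the simulation's oracle; by default one occurrence replicate per
posterior draw is used, which leaves posterior parameter uncertainty — not
demographic noise — dominating the intervals.

## Pollen limitation

A pair is scored by `ratio = control seeds / supplemented seeds`. Exclusions:
supplemented flower without fruit (no denominator; a fruiting flower with
zero seeds is treated the same, as the ratio is equally undefined) and
`ratio > 2` (treatment failure). A retained pair is limited when
`ratio < 0.5`; a ratio of exactly 0.5 is classed *not* limited (strict
reading of the "less than half" criterion). The limitation indicator is
modelled as Bernoulli with `logit(θ_j) = β0_j + β1·restored_j`,
`β0_j ~ Normal(μ, σ)`; "herbaceous enhancement" is the binary restoration
flag. Priors: Normal(0, 2) on `μ_β0` and `β1`, half-Normal(0, 1) on `σ` —
enough regularisation to keep complete-separation fixtures finite. The fit
reuses the HMC sampler and diagnostics.

## The synthetic-data generator

The generator is the package's experimental test-bed: every stage of the
pipeline is validated on data whose truth is known. Defaults reproduce the
design shape the package targets — 18 parks (9 restored, 9 control), 3
years, 6 surveys per year, 108 species — with effect sizes chosen so the
synthetic study exhibits the phenomena the model must resolve: a strong
positive restoration effect on initial occurrence (+2.26), positive woody
(+1.60) and d'×woody (+1.36) effects on colonisation, a mild negative woody
effect on persistence (−0.61), positive degree (+0.98) and floral (+0.41)
effects on detection, and a specialisation distribution with mean 0.29 and
SD 0.13 (a Beta rescaled to those moments). Phenology peaks are spread
uniformly across the season with curvatures that leave a species detectable
in roughly 2–4 of 6 surveys — the sparse-detection regime the marginalised
likelihood exists for.

Construction notes:

* Each sub-generator (site covariates, species parameters, occupancy,
  detection, network, pollen) draws from its own named PCG64 stream spawned
  from the single seed, so enlarging the species pool does not shift site
  covariates.
* Generated tables round-trip through the ingest path unchanged, and
  covariates are standardised exactly as ingest would standardise them, so
  true slopes live on the scale the fit estimates.
* The interaction network gives each species a near-private genus receiving
  a share of its interactions equal to its specialisation weight, with the
  remainder spread over shared genera by availability. The private-genus
  device is what lets realised d' track the assigned weight (the d' ceiling
  is exclusive use of a self-supplied genus); per-species interaction totals
  are sized so the pooled network carries ~15k interactions, the volume of a
  regional dataset for a community of this size.
* Pollen pairs realise their intended ratio class by construction, and a
  configurable fraction of pairs is planted as exclusion cases of both
  kinds.
* The latent occupancy truth is returned (and serialised) separately from
  the observable tables so pipeline code cannot consume it by accident.

What the generator does **not** emulate: spatial structure and dispersal
limitation between sites, within-season abundance dynamics (detection
heterogeneity beyond the quadratic date curve), weather covariates, taxonomic
misidentification, and observer effects. Passing the recovery tests therefore
demonstrates that the estimator is correct *under the model's own
assumptions*, not that those assumptions hold for any particular field
system.

## Validation scales and numerical choices

* Likelihood oracle: exhaustive enumeration over all latent sequences for
  `K ≤ 4`, agreement within 1e-10.
* Slope recovery: 40 species × 12 sites × 3 years × 6 surveys, three
  replicates with 1200-iteration/600-warmup two-chain fits; posterior means
  of the restoration and woody slopes land within 0.3 logit units of truth
  on average, nominal 95% intervals cover truth, and strong positive effects
  carry posterior sign probability > 0.9. The acceptance script runs two
  replicates at the same scale with a longer warmup (1400/800) and a 0.95
  acceptance target for extra robustness across seeds.
* Richness oracle: Monte-Carlo means within 3 standard errors of the
  analytic expectation.
* Pollen recovery: 11 sites × 16 pairs at a homogeneous limitation
  probability of 0.3; the community intercept lands within 0.4 logit units
  of `logit(0.3)` averaged over three replicates.
* Probabilities entering the forward recursion are clipped to
  `[1e-12, 1 − 1e-12]`; hyper-SD logs are clipped at ±30 before
  exponentiation. Both clips only touch regions of negligible posterior
  mass and keep extreme HMC proposals finite rather than NaN.

## Limitations

* The sampler is static-trajectory HMC, not NUTS; very strong posterior
  correlations (e.g. under much longer time series) would mix more slowly.
  The convergence gates make such failures visible rather than silent.
* No data augmentation for never-detected species: richness is conditional
  on the observed community, and no asymptotic richness estimators are
  provided.
* One observation-level detection model (Bernoulli); capture counts beyond
  presence are not modelled (no N-mixture abundance).
* The pollen model collapses seed counts to a binary outcome by design;
  count-level models are out of scope.
* No spatial autocorrelation or model-comparison machinery (WAIC/LOO).
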