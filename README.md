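# covsync

Multispecies covariate synchrony for long-term count panels: a Tweedie
population-dynamics model with reversible-jump model selection over
*shared* regression coefficients.

## The problem

Species sharing an environment are exposed to the same drivers — weather,
predators, habitat gradients — but need not respond the same way. Given a
panel of annual mean counts `y[s,i,t]` for species *s* at site *i* in
winter *t* (the shape of multi-decade garden bird feeding surveys:
non-negative, effectively continuous, with exact zeros), `covsync` asks
two questions at once:

1. **How synchronous are the species after accounting for measured
   covariates?** Residual variation is split into a site effect common to
   all species (`eps(i)`, variance `sigma2_eps`) and a species-specific
   site effect (`delta_s(i)`, variance `sigma2_s`); the intraclass
   correlation `ICC_s = sigma2_eps / (sigma2_eps + sigma2_s)` is the
   synchronous fraction.
2. **Which species share which responses?** Every coefficient family (one
   per covariate) and the two Tweedie variance parameters may be shared
   across any subset of species. A reversible-jump sampler moves across
   the set partitions of the species for each family, so the output
   includes posterior probabilities of statements like "species 1 and 2
   share their northing coefficient, species 3 has its own".

The observation model is `y ~ Tw(mu, phi, p)` with `Var = phi * mu^p`,
`p in (1, 2)` (compound Poisson–gamma: continuous with an atom at zero),
and the mean follows a log-linear growth recursion with time-varying
covariates, lagged-abundance interaction terms (density dependence on the
diagonal), and the two random effects, hierarchically centered.
Augmented pre-survey means seed the recursion. See `docs/methods.md` for
the full model, priors, and numerical details.

## Worked example

Simulate the "tit-like" preset (3 species, high synchrony, one site
covariate whose coefficient is shared by species 1–2 with a gap to
species 3, species-specific density dependence) at a reduced desk scale,
then fit and summarize:

```python
import dataclasses
from covsync import (PriorConfig, RJConfig, generate, preset_scenarios,
                     run_pilot, run_sampler)
from covsync.summaries import (model_probabilities, icc_summary,
                               nu_inclusion_probabilities)

scenario = dataclasses.replace(preset_scenarios()["tit-like"],
                               n_sites=30, n_years=15)
data, (truth_state, truth_sharing) = generate(scenario)

priors = PriorConfig()
proposals = run_pilot(data, priors, iterations=800, burn_in=400, seed=1)
cfg = RJConfig(iterations=8000, burn_in=4000, thin=4, seed=2,
               rj_moves_per_iter=2, nu_toggles_per_iter=2, store_latent=False)
chain = run_sampler(data, priors, cfg, proposals=proposals)

print(model_probabilities(chain, "beta_0").to_string(index=False))
print(icc_summary(chain).to_string(index=False))
print(nu_inclusion_probabilities(chain)
      .query("inclusion_probability > 0.5")[
          ["effect_of", "on", "inclusion_probability", "mean_given_included"]]
      .to_string(index=False))
```

Output (about two minutes on one CPU):

```
           model  probability
  {bt, gt}, {ct}        0.456
    {bt, gt, ct}        0.343
  {bt}, {gt, ct}        0.074
  {bt, ct}, {gt}        0.065
{bt}, {gt}, {ct}        0.062

species     mean   ci_low  ci_high
     bt 0.775069 0.545373 0.935578
     gt 0.862920 0.690239 0.960768
     ct 0.625365 0.254707 0.852995

effect_of on  inclusion_probability  mean_given_included
       bt bt                    1.0            -0.044098
       gt gt                    1.0            -0.032731
       ct ct                    1.0            -0.035262
```

Reading it: the modal model for the site covariate is the simulated truth
`{bt, gt}, {ct}` (posterior probability 0.46 at this reduced scale; at
the full 60-site preset it reaches ~0.8); the first two species are
estimated as strongly synchronous (ICC means 0.78 and 0.86 against truths
of 0.89) and the third less so (0.63 vs 0.44, within its wide interval);
density dependence is retained with probability 1 for every species and
no spurious interspecific interaction exceeds 0.5.

The same pipeline is available from the shell:

```bash
covsync simulate --scenario tit-like --seed 1 --out runs/data
covsync pilot    --data-dir runs/data --seed 2 --out runs/pilot \
                 --iterations 800 --burn-in 400
covsync fit      --data-dir runs/data --proposals runs/pilot/proposals.json \
                 --seed 3 --out runs/fit --iterations 8000 --burn-in 4000 --thin 4
covsync summarize --chain-dir runs/fit --out runs/tables
```

Real data enter as three CSVs (counts with columns
`species,site,year,value`; site covariates; site-by-year covariates) via
`covsync.io.read_panel`, which standardizes covariates and rejects gaps
inside a site's observation window.

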