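# Methods

## The model

`covsync` fits a joint population-dynamics model to panel counts of
several species observed at many sites over many years — the setting of
long-running garden bird feeding surveys, where the response is the annual
mean of weekly maximum counts: non-negative, effectively continuous, and
with exact zeros.

The observation model is Tweedie with index p in (1, 2):

    y[s,i,t] ~ Tw(mu[s,i,t], phi{s}, p{s}),    Var(y) = phi * mu^p,

the compound Poisson–gamma family, which carries an atom at exactly zero
alongside a continuous positive density. The mean follows a log-linear
growth recursion:

    log mu[s,i,t] = log mu[s,i,t-1] + v[i,t]' gamma{s}
                    + sum_l nu[l,s] * y[l,i,t-1]
                    + eps(i) + delta_s(i),

where `v[i,t]` are time-varying covariates, `nu[l,s]` is the effect of
species l's lagged observed count on species s (`nu[s,s]` is density
dependence, constrained non-positive), `eps(i) ~ N(0, sigma2_eps)` is a
site effect common to all species (the *synchronous* residual component)
and `delta_s(i)` is a species-specific site effect (the *asynchronous*
component). Under hierarchical centering the intercept and site covariates
enter through the prior mean of the asynchronous effect,

    delta_s(i) ~ N(alpha_s + x_i' beta{s}, sigma2_s),

which is exactly equivalent to placing `alpha_s + x_i' beta{s}` in the
growth rate with a zero-mean `delta'` (unit Jacobian; verified numerically
to 1e-13) but mixes far better. The pre-survey mean `mu0[s,i]` is unknown
and treated by data augmentation with a U[0, 200] prior; it also serves as
the lagged-abundance regressor for each site's first observed year.

The intraclass correlation `ICC_s = sigma2_eps / (sigma2_eps + sigma2_s)`
summarizes what fraction of a species' residual variance is synchronous.
It is computed per posterior draw and then averaged (mean of ratios, not
ratio of posterior means — with a common sigma2_s the two differ, and only
the per-draw average is a posterior expectation of the estimand).

## Model uncertainty

Each regression-coefficient family (one per site covariate and one per
time-varying covariate) and the two Tweedie parameters can be *shared*
across species: the model indicator assigns a set partition of the species
to each family, plus inclusion flags for every interaction term
`nu[l,s]`. Posterior model probabilities are estimated by reversible-jump
MCMC:

* **Split/merge.** A split picks a block of size >= 2 uniformly, one of
  its 2^(m-1)-1 bipartitions uniformly, draws u ~ N(0, sd_rj^2) (default
  sd_rj = 1e-3) and assigns theta +/- u to the offspring (|Jacobian| = 2);
  a merge picks an unordered block pair uniformly and takes the midpoint
  (|Jacobian| = 1/2). The two maps are mutual inverses; the proposal
  ratio carries the move-choice probabilities, including the degenerate
  cases where only one move type is available.
* **Birth/death of interactions.** Births draw the new `nu` from a normal
  proposal whose mean and sd come from a pilot run of the saturated model
  (truncated to the negative half-line for density dependence); deaths set
  it to zero. No pseudo-prior is kept for excluded terms.
* **Model prior.** Uniform over set partitions per family, independent
  across families, and 1:1 prior odds for each interaction. An
  alternative prior (uniform over the number of blocks) is available via
  `model_prior="nblocks"`.

Intercepts and interaction values are never shared across species.

For exact oracle testing, a coefficient family can be given a *grid*
prior (uniform on a finite value set). Splits then draw the new block
value uniformly from the grid and merges keep the value of the sub-block
containing the smallest species index — a discrete trans-model chain that
needs no Jacobian and whose model probabilities can be enumerated by brute
force.

## Within-model sampling

Continuous parameters use single-update random-walk Metropolis–Hastings.
Because the likelihood factorizes over sites given everything else,
site-level scalars (`eps`, each row of `delta` and `mu0`) are proposed as
per-site independent batches with elementwise accept/reject — numerically
identical in distribution to sequential single-site updates, but one
likelihood-kernel call instead of one per site. The same argument batches
the disjoint blocks of one family (and interaction terms targeting
distinct species) into shared kernel evaluations. When any interspecific
interaction is in the model, `mu0` falls back to per-species batches
because a site's augmented means then couple across species.

The two variance components use conjugate Gibbs draws from their
inverse-gamma full conditionals — exact, and the stationary distribution
is unchanged.

Proposal sds adapt every 100 iterations during burn-in only, by
`sd *= exp(rate - 0.44)` clamped to [1e-6, 10], and are frozen afterwards.
Target 0.44 is the standard scalar-update optimum.

One split/merge attempt on a uniformly chosen family and one interaction
toggle per iteration is the default composition; `rj_moves_per_iter` /
`nu_toggles_per_iter` allow several attempts per sweep, which speeds
model-space mixing on short chains at negligible cost (trans-model moves
are much cheaper than a sweep).

### Initialization

Chains start from a data-driven state: `mu0` at the first observed count,
`delta` at each site's crude mean log growth corrected for the small
initial density-dependence value, `alpha` and `sigma2_s` at the matching
moments. The main run can additionally start from the pilot run's
posterior means (stored in the proposal table), with density dependence
included from the outset — inclusion of `nu[s,s]` is strongly coupled to
the intercepts, and birthing it from a cold chain is a near-reducible
move.

## Priors

| parameter | prior | default |
|---|---|---|
| alpha, beta, gamma, interspecific nu | Normal(0, sigma^2) | sigma^2 = 1e-2 |
| density dependence nu[s,s] | negative half-normal, same scale | sigma^2 = 1e-2 |
| mu0 | Uniform | [0, 200] |
| phi | Uniform | [0, 5] |
| p | Uniform | (1, 2), open |
| sigma2_eps, sigma2_s | InvGamma(a, b) | a = b = 1e-3 |

The coefficient prior scale deserves a note. The notation N(0, 10^-2) in
this literature can denote a variance or a precision. We use **variance
1e-2 (sd 0.1)**: on the log-growth scale, where effects of standardized
covariates are of order 0.01–0.05, sd 0.1 is weakly informative; and it
is the only reading commensurate with a reversible-jump innovation sd of
1e-3. Under the precision reading (sd 10) a split move pays
`log prior(theta_B) - log q(u)` of roughly −14 nats before any data
enter, which makes split models unreachable in practice — we verified
that a 60-site panel with a 13-posterior-sd coefficient gap then reports
P(pooled) = 0.999. With sd 0.1 the same data give the true two-block
partition probability ~0.8. Posterior model probabilities always depend
on this scale (Lindley–Bartlett); users comparing against other software
should match it deliberately.

`p` is kept strictly inside (1, 2): the series density degenerates at the
endpoints, and boundary proposals are rejected.

## Numerics

The Tweedie log-density sums the compound Poisson–gamma series outward
from its dominant term (index ~ y^(2-p) / (phi (2-p))), stopping when
terms fall below 1e-12 of the running sum, with a 10,000-term cap and
dynamic rescaling of the running maximum (the peak-index formula is
asymptotic; without rescaling, mis-located peaks overflow and an MH chain
can be attracted to spurious +inf densities near p -> 1). Zero is detected
exactly — the data are means of weekly maxima, so true zeros are
representable. The likelihood kernel tabulates the two lgamma sequences
(one universal, one per index parameter) and is compiled with numba; a
pure-Python fallback keeps the package importable without it. States with
overflowing means or non-convergent series contribute log-density -1e300,
so Metropolis–Hastings simply rejects them.

## Synthetic data

The generator simulates the exact model above, at conditions shaped like a
multi-decade garden bird survey: staggered site windows (uniform start
lag, minimum 4-year window), site covariates iid standard normal and
time-varying covariates AR(1) with coefficient 0.5 — both standardized
exactly, so simulated coefficients live on the scale the model reports.
Observations are drawn year by year so that lagged observed counts feed
the interaction terms, exactly as the likelihood assumes.

Presets (`preset_scenarios()`):

* **tit-like** — 3 species, 60 sites, 20 years; high synchrony
  (sigma2_eps = 0.004, sigma2_s = 0.0005/0.0005/0.005; true ICCs
  0.889/0.889/0.444); one site covariate with coefficient partition
  {{1,2},{3}} and a 0.04 gap (about 13 posterior sds at 60 sites);
  shared time-varying coefficient 0.015; species-specific density
  dependence; Tweedie parameters in the ranges reported for garden tits.
* **finch-like** — weak synchrony (sigma2_s about 3x sigma2_eps) and one
  active interspecific interaction (species 2 boosting species 1).
* **null** — everything shared, no covariate effects, no interactions.

What passing tests on these data do *not* show: robustness to
misspecification (real surveys have observer effects, imperfect
detection, non-AR covariates), behaviour with missing years or covariates
(out of scope), or spatial correlation between sites.

## Problem sizes used by the test suite and acceptance script

Runs are sized for a single CPU: the partition-recovery check fits the
full tit-like preset once (20,000 iterations, 10,000 burn-in, pilot
1,000); the coverage study uses 20 replicates at 24 sites x 12 years with
4,000-iteration chains; the ICC check fits the full preset for 8,000
iterations; the prior-recovery and gridded-oracle chains run 50,000
iterations on 4-site toys. The acceptance script repeats the same battery
with a 12,000-iteration recovery fit and 8 coverage replicates. The pilot/main lengths of the original
analysis (50k/30k and 100k/50k) remain the config defaults.

## Known limitations

* **Finite-window attenuation of density dependence.** With site-level
  intercept random effects and a lagged-abundance regressor, the exact
  posterior at 20-year windows concentrates at density dependence that is
  somewhat stronger than the generative truth, with the intercepts and
  sigma2_eps compensating along a ridge — the Bayesian analogue of the
  dynamic-panel (Nickell) bias. Doubling the window to 40 years removes
  it (posterior means within ~0.002 of truth). Consequently, 99% credible
  intervals for `nu[s,s]`, `alpha` and `sigma2_eps` under-cover the
  simulation truth at 20-year conditions; coefficient, Tweedie-parameter
  and partition recovery are unaffected. Users of multi-decade survey
  data should read density-dependence magnitudes with this in mind.
* Mixing across partition space relies on within-model drift between
  split and merge events; very short chains under-explore model space
  (the pilot-informed initialization and extra trans-model attempts per
  sweep mitigate, not remove, this).
* Missing years/covariates, observation-level random effects and
  spatially correlated effects are out of scope.
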