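# intabund — integrated abundance models for citizen-science counts

Estimating how many animals live in an area from counts collected by
volunteers is hard for two opposite reasons: observers miss animals that
are there (false negatives, governed by a detection probability *p*) and
they count animals that are not the target — an owned cat reported as a
stray, a common species mistaken for a rare one (false positives, an
expected *m* misidentifications per site per survey). Classical N-mixture
models correct only for the first failure and can wildly inflate abundance
when the second is present.

`intabund` implements an **integrated abundance model (IAM)**: a Bayesian
hierarchical model that couples replicated citizen-science counts with a
smaller set of high-quality *expert* counts — available for only some
sites — through shared latent site abundances. The expert layer, and in
particular expert-confirmed *empty* sites, makes the misidentification
rate identifiable, removing the inflation. The package is aimed at
ecologists and animal-welfare scientists running community survey programs
(the motivating application is estimating unowned domestic cats in urban
areas), and at anyone who wants to stress-test the design of such a
program by simulation before collecting data.

## The model

For sites *i = 1..S* and survey replicates *j = 1..R*:

```
z_i  ~ Bernoulli(Ω)                 occupancy
N_i  = z_i · λ_i                    latent site abundance
y_ij ~ Poisson(N_i · p + m)         citizen-science counts
w_i  ~ Poisson(N_i)                 expert counts (subset of sites)
       or Normal(N_i, k·N_i)        variance-scaled alternative
```

with broad priors p, Ω ~ U(0, 1), m ~ U(0, 40), λ_i ~ Gamma(1, 0.005).
Where an expert count exists it is trusted at the level of
presence/absence, fixing z_i = 1(w_i > 0); elsewhere z_i is marginalized.
The posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
(three chains of 20,000 iterations by default, burn-in 10,000, thinning 5)
with Brooks–Gelman–Rubin convergence diagnostics. A classical
binomial-Poisson N-mixture baseline (`fit_nmixture`, exact Gibbs) is
included for comparison, along with the full simulation-experiment harness
(30 scenarios sweeping expert-count variance, expert coverage,
misidentification, abundance and occupancy) and a spatial module that
turns raw geo-referenced sighting tables into site × replicate inputs by
single-linkage clustering at a 500 m radius.

## A worked example

```python
from intabund import (ScenarioConfig, MCMCConfig, generate_dataset,
                      fit_iam, summarize)

dataset = generate_dataset(ScenarioConfig(seed=42))   # 20 sites, truth N=2000
draws = fit_iam(dataset, MCMCConfig(n_iter=5000, burn_in=2500, seed=1))
print(summarize(draws).table.round(3))
```

prints

```
             mean     lower     upper    width   rhat
omega       0.725     0.525     0.881    0.356  1.001
p           0.778     0.742     0.817    0.074  0.999
m           9.845     9.005    10.757    1.752  1.000
N_total  2044.130  1955.653  2134.127  178.474  0.999
```

The dataset was generated with Ω = 0.8, p = 0.8, m = 10 and a total
abundance of 2000: every 95% credible interval contains its generating
value, and R-hat ≈ 1 says the three chains agree. Fitting the N-mixture
baseline to the same counts (`examples/03_nmixture_inflation.py`) gives a
total of 2637 (2557–2723) — the false positives, roughly 10 per site per
survey across 20 sites and 10 surveys, are absorbed into abundance when
the model has nowhere else to put them.

The `examples/` directory holds one short script per capability:
simulation, fitting, baseline comparison, a small simulation experiment,
and sighting clustering. A thin CLI (`intabund simulate|fit|nmixture|
experiment|cluster|compare`) wraps the same calls for shell use.

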