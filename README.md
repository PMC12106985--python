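# fgmspatial

Bayesian hierarchical spatial modelling of female genital mutilation (FGM)
risk among girls aged 0–14, for epidemiologists and statisticians doing
small-area prevalence estimation from two-stage cluster surveys (DHS /
MICS style) across two time periods.

## The model

For girl *i* with covariates *z′ᵢ*, survey weight *wᵢ* and state of
residence *sᵢ*, the probability *pᵢ* of being cut follows a Bernoulli
logistic model

```
logit(p_i) = β₀ + z′ᵢβ + f₁(x_i1) + … + f_p(x_ip)
             + f_str(s_i) + f_unstr(s_i) + β_w·w_i
```

* **β** — reference-coded fixed effects of the individual covariates
  (mother's education, marital status, support for FGM continuation, FGM
  status, household wealth, ethnicity, religion) and/or community
  covariates (zone, residence, EFI, cluster percentages, modal
  religion/wealth), with vague N(0, 1000) priors.
* **f₁…f_p** — nonlinear smooths of girl age, mother age and the cluster
  %-cut / %-support proportions, modelled as random-walk-order-2 priors
  on binned grids with sum-to-zero constraints.
* **f_str** — Besag intrinsic CAR (ICAR) structured state effect with
  precision τ_str·(D − A) over the state contiguity graph, sum-to-zero
  per connected component.
* **f_unstr** — iid Gaussian unstructured state effect (together with
  f_str this is the BYM pair).
* **β_w·w** — the sampling weight entered as a covariate, a
  representativeness adjustment.

Three nested specifications are compared by DIC: **m1** (no spatial
terms), **m2** (structured only), **m3** (structured + unstructured),
with DIC differences below 2 resolved in favour of the simpler model.
Inference uses an exact Pólya-Gamma data-augmentation Gibbs sampler
(`omega_i ~ PG(1, η_i)` latents, a joint Gaussian update of all linear
blocks with conditioning-by-kriging for the constraints, conjugate Gamma
updates for all precisions). Community covariates include the Ethnic
Fractionalisation Index `EFI = 1 − Σ s_k²`.

Because the underlying survey microdata are access-restricted, the
package ships a first-class synthetic generator that emulates the
two-stage cluster design (states → clusters → girls, inverse-inclusion
weights), the covariate structure, and outcomes drawn from the model
above with published odds ratios as generating coefficients.

## Worked example

```python
from fgmspatial import (BayesSpatialLogit, ModelSpec, icar_precision,
                        generate_geography, default_true_params, make_two_period,
                        weighted_prevalence, select_model)

graph, zones = generate_geography(12, (3, 4), seed=1)
structure = icar_precision(graph)
data = make_two_period(graph, zones,
                       default_true_params(structure, "pre", seed=1),
                       default_true_params(structure, "post", seed=1),
                       n_clusters_per_state=5, n_girls_per_cluster=50, seed=1)

model = BayesSpatialLogit.from_dataframe(
    data["pre"], ModelSpec("m2", "individual"), graph=graph)
results = model.fit(iterations=1500, burn_in=500, seed=2)
print(results.summary())
```

prints (abridged):

```
Bayesian hierarchical spatial logistic model
  complexity: m2   covariates: individual
  records: 3000   coefficients: 87
  draws: 1000 (iterations 1500, burn-in 500, thin 1, seed 2)
  Dbar 1914.6   pD 37.3   DIC 1952.0

covariate         level                 POR     2.5%    97.5%  sig
mother_support    no (ref)            1.000        -        -
mother_support    yes                18.306   13.725   24.683  *
mother_support    dk                  1.603    1.061    2.434  *
mother_fgm        uncut (ref)         1.000        -        -
mother_fgm        cut                 9.042    6.887   11.967  *
```

The posterior odds ratio (POR) is the exponentiated posterior-mean
coefficient; an effect is flagged significant when its 95% interval
excludes 1. Here the generating mother-cut odds ratio (8.145) and
support-continuation odds ratio (16.436) are recovered within posterior
uncertainty. `results.state_prevalence()` returns per-state posterior
prevalence (mean, SD, 95% interval, in %), and
`fgmspatial.evaluate.prevalence_change` tabulates post-minus-pre changes.

The same pipeline runs from the shell:

```sh
fgmspatial report --config config.yaml --seed 1 --out out/
```

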