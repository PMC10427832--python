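# avianiche

Hierarchical community distance sampling and multidimensional niche-overlap
analysis for point-count bird surveys along elevation gradients.

## The problem

How do ecologically similar species — congeners and confamilials with
near-identical diets — manage to coexist in a species-rich montane forest?
A classical answer is multidimensional niche partitioning: pairs that look
identical on one axis (diet) may separate on another (elevation, foraging
stratum, horizontal space within a habitat). Testing this with field data
requires (i) abundance estimates that correct for imperfect, distance- and
habitat-dependent detection, even for species seen only a handful of times,
and (ii) overlap indices along each candidate niche axis, referred to null
expectations.

`avianiche` implements that full workflow for point-count distance-sampling
surveys of the kind run along tropical elevation gradients (its survey
geometry: 100 m radius points, distance classes 0–10/10–20/20–50/50–100 m),
together with a forward simulator so every stage is testable against known
truth.

## The model

For site *j* and species *s*, with standardized elevation *x*:

```
detection:   g(r) = exp(−r² / 2σ²js),   log σjs = αs + γ·veg_j
cells:       p_djs = (2σ²/w²)[exp(−h²_{d−1}/2σ²) − exp(−h²_d/2σ²)]
abundance:   log λjs = β0s + β1s·x_j + β2s·x²_j
latent:      Njs ~ Poisson(λjs ρjs),  ρjs ~ gamma(r, r)      (mean 1)
observed:    njs ~ binomial(Njs, p_js),  yjs ~ multinomial(njs, p_d/p)
hierarchy:   αs, β0s, β1s, β2s ~ normal(μ•, σ²•)  across species
```

Inference is Bayesian (blocked adaptive Metropolis-within-Gibbs, written in
numpy); the latent `N` and `ρ` are marginalized analytically into a
negative-binomial × multinomial likelihood, verified against brute-force
enumeration. From the fitted curves the package computes, per within-family
species pair: directional elevation-niche overlap `N_AB = Ov_AB / T_A`
(with the similar / partial / no-overlap classification), Pianka overlap of
diet and foraging-strata compositions, the spatial site index
`SSI = |A∩B| / |A∪B|` over detection sites, family body-mass CVs, and null
distributions over random cross-family pairs. A joint species distribution
extension replaces the overdispersion with a site-level multivariate-normal
effect and reports residual species correlations before and after the
elevation terms. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from avianiche import (
    CommunityDistanceSamplingModel, GeneratorConfig, prepare_dataset,
    build_pair_table, detection_sites,
)
from avianiche.synthetic_data import generate_dataset

# a 15-species community at 250 point-count stations, known truth
ds, traits = generate_dataset(GeneratorConfig(seed=1))
prep, scaler, kept = prepare_dataset(ds)          # >=10 detections kept
print(len(kept), "of", ds.n_species, "species modeled")

model = CommunityDistanceSamplingModel(seed=11).fit(prep)
print("max Rhat", round(model.max_rhat_, 3))
for k in ("mu_beta1", "mu_beta2"):
    lo, hi = model.posterior_.credible_interval(k)
    print(k, round(float(model.posterior_.mean(k)), 3),
          [round(float(lo), 3), round(float(hi), 3)])

curves = model.abundance_curves(
    scaler, (prep.sites.elevation_m.min(), prep.sites.elevation_m.max()))
taxonomy = traits.table.set_index("species")["family"].to_dict()
pairs = build_pair_table(curves, traits, detection_sites(prep), taxonomy)
print(pairs[["species_a", "species_b", "n_ab", "n_ba",
             "elev_category", "ssi", "partitioning"]].head(3))
```

Output (seed 1):

```
13 of 15 species modeled
max Rhat 1.047
mu_beta1 -0.971 [-1.197, -0.753]
mu_beta2 -0.518 [-0.756, -0.297]
  species_a species_b      n_ab      n_ba elev_category       ssi partitioning
0      sp01      sp06  0.986210  0.880954       similar  0.183099      spatial
1      sp02      sp12  0.998873  0.996476       similar  0.055556      spatial
2      sp03      sp08  0.931301  0.977806       similar  0.068182      spatial
```

The generating truth for this community was μβ1 = −1.0, μβ2 = −0.45: both
95% credible intervals cover it. Each pair row reads as: species B's
standardized abundance-elevation curve overlaps 98.6% of A's and A's
overlaps 88.1% of B's (`similar` elevation niches — elevation cannot be
what separates them), yet the pair co-occurs at only 18% of the sites where
either was detected (`ssi`), pointing to horizontal within-habitat
segregation (`spatial`).

The same pipeline runs from the shell:

```bash
avianiche all --seed 1 --out run1           # simulate -> fit -> metrics -> report
avianiche fit --config survey.yml --preset paper   # long production schedule
```

with per-stage subcommands (`simulate`, `fit`, `metrics`, `jsdm`,
`report`), YAML configs, and a run manifest recording every seed.

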