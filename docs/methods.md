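# Methods

## The model

`avianiche` fits a hierarchical community distance-sampling model to
point-count surveys in which every detected individual is assigned to a
radial distance class, and derives multidimensional niche-overlap indices
from the fitted abundance-elevation responses.

**Observation process.** Detection at radial distance *r* follows the
half-normal key g(r) = exp(−r²/2σ²js), with the scale modelled on the log
scale as a species intercept plus a shared vegetation-category offset:
log σjs = αs + γ·veg_j (reference category fixed at γ = 0; a full dummy set
would be unidentifiable next to the per-species intercepts). In a point
transect the distance of an available individual has triangular density
2r/w² on [0, w] because surveyed area grows with radius, so the probability
that an individual is in class d = (h_{d−1}, h_d] *and* detected is

    p_d = (2σ²/w²)·[exp(−h²_{d−1}/2σ²) − exp(−h²_d/2σ²)].

The package evaluates this integral in closed form (an `expm1` formulation
avoids cancellation when σ ≫ w); adaptive quadrature of the same integral is
retained in the test suite as an independent oracle (agreement ≤ 1e-8 over
σ from 1 m to 10⁴ m).

**State process.** Expected abundance follows a quadratic log-elevation
response, log λjs = β0s + β1s·x_j + β2s·x²_j with x the standardized site
elevation, and latent abundance is overdispersed Poisson: Njs ~
Poisson(λjs·ρjs), ρjs ~ gamma(shape r, rate r) so E[ρ] = 1 (the
parameterization is a package choice; only "a gamma multiplier controlling
overdispersion" is prescribed). Detected totals are a binomial thinning
njs ~ binomial(Njs, p_js), and the class vector yjs is multinomial with the
conditional cells p_d/p.

**Marginalization.** Rather than sampling N and ρ, the likelihood is
marginalized analytically: a gamma-mixed Poisson thinned by p is negative
binomial with mean λp and unchanged shape, so njs ~ NB(mean λjs·pjs,
shape r) times a multinomial term. The identity is verified against a
brute-force enumeration over the latent abundance (capped at the 0.999999
NB quantile) to ≤ 1e-6 on randomized cases. Posterior draws of the latent
Njs, when needed (the latent co-occurrence index), are recovered from the
posterior predictive ρ | n ~ gamma(r + n, r + λp), N = n + Poisson(λ(1−p)ρ).

**Hierarchy and priors.** Species-level parameters (αs, β0s, β1s, β2s) are
draws from community-level normals with hyper-means μ and hyper-variances
σ². Hyper-means have normal(0, variance 100) priors. The hyper-variance
prior is gamma(shape 0.1, rate 0.1) applied, by default, to the
**precision** — the standard JAGS-style weakly informative choice for this
model family (`variance_prior="precision"`). The literal reading (the same
gamma on the variance itself) is available via `variance_prior="variance"`;
note its density diverges at zero and measurably over-shrinks small
hyper-variances, which narrows the hyper-mean intervals and costs
frequentist coverage (the parameter-recovery study below loses roughly 2-4
coverage points under that reading). The negative-binomial shape r also has
a gamma(0.1, 0.1) prior; γ offsets have normal(0, 100) priors.

## The sampler

No probabilistic-programming backend is used; the posterior is sampled with
a blocked adaptive Metropolis-within-Gibbs scheme written in numpy:

* **Species blocks.** Given the shared parameters, species are
  conditionally independent, so the (αs, β0s, β1s, β2s) blocks are updated
  jointly and vectorized across species. Proposals are covariance-shaped
  (adaptive Metropolis: per-species empirical covariance over a growing
  window, scaled 2.38/√d, with a per-species scalar tuned to ~0.3
  acceptance). Every tenth update is a small isotropic move, which prevents
  a degenerate covariance estimate from trapping a species. Three sweeps
  per iteration, since this block limits mixing (the hyper updates are
  Gibbs). Chains start from dispersed plausible values; a start with −∞
  likelihood (possible when a random σ cannot produce the observed
  far-class counts) is repaired to a moment-matched one.
* **γ and log r**: random-walk Metropolis, γ with a covariance-adapted
  joint proposal.
* **Hyper-means**: conjugate normal Gibbs. **Hyper-variances**: log-scale
  random walk against the chosen prior.

Defaults are the desk scale: 3 chains × 3000 retained draws after 1000
warm-up iterations (`preset="paper"` switches to 3 × 200 000 iterations,
50 000 burn-in, thinning 10). Convergence is summarized by the split-chain
potential scale reduction factor (Rhat), computed per parameter; any
Rhat ≥ 1.1 raises a warning and sets `converged_ = False` — it is flagged,
never silently accepted. The implementation is cross-checked against
arviz's rank-normalized Rhat in the tests.

## Niche metrics

* **Elevation overlap**: species curves λ(x) = exp(β0 + β1x + β2x²) are
  built from posterior means on a 1000-point grid over the observed
  elevation range and standardized to max 1 so rare and abundant species
  compare on the same scale. Ov_AB is the trapezoidal integral of the
  pointwise minimum; N_AB = Ov/T_A and N_BA = Ov/T_B. Pairs are `similar`
  when both directions ≥ 0.5, `no-overlap` when both < 0.1 (the published
  turaco pair at 0.08/0.03 is the calibration point for "≈ 0"), otherwise
  `partial`. All thresholds are configuration.
* **Pianka overlap** for diet and foraging-strata compositions uses the
  standard square-root denominator, Σp_Ap_B/√(Σp_A²·Σp_B²), which keeps the
  index in [0, 1]; the index is symmetric and scale-invariant. (The source
  table this mirrors contains a few symmetric values above 1, consistent
  with a missing square root in its own computation; this package uses the
  canonical form.)
* **Spatial site index**: |A∩B|/|A∪B| over detection sites, plus a latent
  variant computed from posterior draws of true abundance.
* **Body-size CV**: 100·sd/mean with the n−1 standard deviation.
* **Partitioning labels**: `elev` when the pair is not elevation-similar;
  `strata` whenever strata overlap ≤ 0.6; `spatial` for elevation-similar
  pairs (their coexistence must rely on within-habitat segregation). The
  rule is a codified heuristic and is exposed as configuration.
* **Null models**: any pair metric can be referred to its distribution over
  cross-family species pairs (all pairs enumerated when fewer than the
  requested draws, otherwise sampled without replacement, seeded).

## Joint species distribution extension

For a small focal set (≈5 ecologically similar species) the gamma
overdispersion is replaced by a site-level species vector ηj ~ MVN(0, Σ)
added to log λ, making detected totals Poisson conditional on η. Σ has a
weakly informative inverse-Wishart prior (df = S + 1, identity scale;
configurable) and is drawn by conjugate Gibbs; η rows are vectorized
random-walk updates. Because any abundance coefficient and the
corresponding combination of η are likelihood-equivalent (a flat ridge),
the sampler includes exact Gibbs translation moves along those ridges,
without which β0 mixes impractically slowly. Residual correlation matrices
are obtained by standardizing each Σ draw; comparing an intercept-only fit
with the elevation fit shows how much apparent association the shared
elevation response explains. A guard warns above 8 species: an unstructured
covariance grows quadratically. Σ's overall scale is only weakly identified
when the residual structure is near zero, so its own Rhat can be large in
the covariate model even when the correlations — the quantity reported —
are stable.

## Synthetic data

The generator emulates the survey design the model assumes: sites uniform
over an 1800–3900 m gradient with uniform vegetation categories (the real
joint elevation×vegetation layout is survey-specific, so both are free
configuration); species parameters drawn from the community
hyperdistributions; latent abundances Poisson-gamma; individuals placed by
drawing r from the triangular density directly (no 2-D placement — only
radial distance enters the model), thinned by the half-normal, binned into
the classes. The generating truth is always attached for recovery tests.

Defaults (the standard fixture): 15 species in 5 families at 250 sites,
8 vegetation categories, distance classes 0–10/10–20/20–50/50–100 m,
μβ1 = −1.0, μβ2 = −0.45 (community optimum just below mid-gradient),
μβ0 = 0 with var 0.4, μα = log 30 m (typical forest point-count detection
scale) with var 0.04, γ offsets spanning ±0.25, negative-binomial shape 2.
These sizes keep a full fit at ~20 s on one CPU while leaving every species
identifiable.

Trait tables are compositional Dirichlet draws around family-level centres
(within-family concentration `family_coherence`, default 50; ∞ makes
families internally identical), lognormal body masses, all-diurnal
activity.

What the generator does **not** emulate: spatially autocorrelated habitat,
observer movement or distance measurement error, temporal (within-season)
dynamics, and any trait-abundance dependence. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to their violation in field data.

## Calibration studies

* **Parameter recovery** (the acceptance surface): 20 independent
  communities from the fixture generator, each fitted at the desk scale;
  pooled 95% credible-interval coverage of the generating μα, μβ1, μβ2 must
  be ≥ 90%. Coverage here is frequentist at a *fixed* truth, which even an
  exact sampler does not guarantee at exactly 95%: the realized
  between-species variance of a 15-species community is itself noisy.
* **JSDM shrinkage**: five communities whose only shared structure is a
  common elevation response; the intercept-only model shows strongly
  positive residual correlations (≈ +0.5 on average) that collapse toward
  zero when elevation enters, in at least 4 of 5 replicates.
* `scripts/acceptance.py` recomputes everything at slightly reduced
  replicate counts (8 recovery replicates, 3 JSDM replicates) so a full
  from-scratch run stays within a few minutes.

## Numerical choices and edge cases

* Closed-form detection cells with `expm1`; σ proposals are floored so an
  extreme random-walk excursion is rejected by the likelihood rather than
  crashing the evaluation.
* p = 0 with detections present yields −∞ with a warning (impossible data).
* Elevation is standardized over surveyed sites, each site counted once.
* Species filtering ("at least 10 detections") happens after any vegetation
  collapse; the collapse mapping is user configuration (identity default)
  because no published 17→8 mapping exists.
* Ties/degenerate inputs: constant elevation and all-species-filtered
  datasets are rejected with explicit errors; single-vegetation surveys
  simply have no γ to update.
* All randomness flows from a single master seed through
  `numpy.random.SeedSequence` spawns; identical config + seed reproduces
  byte-identical generator output and identical posterior draws.

## Known limitations

* Random-walk MCMC at the desk scale leaves species-level Rhat in the
  1.0–1.2 range on occasional replicates; non-convergence is flagged.
* The overlap indices use posterior means of the curve coefficients, not
  full posterior propagation, matching the two-step design they mirror.
* No spatial random effects, no temporal dynamics, no hazard-rate or
  uniform detection keys, no line-transect geometry, no unbinned distances.
* The null-model randomization scheme (cross-family pairs, unordered,
  without replacement) is a generic design; field studies using such null
  expectations rarely publish their exact randomization recipe, so no
  specific published scheme is being mirrored.
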