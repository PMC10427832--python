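"""Hierarchical community distance-sampling model of abundance.

Model
-----
For site ``j`` and species ``s``, expected abundance follows a quadratic
log-elevation response,

    log(lambda_js) = beta0_s + beta1_s * x_j + beta2_s * x_j^2,

with ``x_j`` the standardized site elevation.  Latent abundance is
overdispersed Poisson, ``N_js ~ Poisson(lambda_js * rho_js)`` with
``rho_js ~ gamma(shape=r, rate=r)`` (mean 1), i.e. marginally negative
binomial with shape ``r``.  Detected totals are a binomial thinning,
``n_js ~ binomial(N_js, p_js)``, with the overall half-normal point-transect
detection probability ``p_js`` from :mod:`avianiche.detection`, and the
observed distance-class vector is multinomial with the conditional cell
probabilities.  Species-level parameters (``alpha_s`` for detection,
``beta0_s, beta1_s, beta2_s`` for abundance) are draws from community-level
normal distributions with hyper-means ``mu_*`` and hyper-variances
``var_*``; the vegetation detection offsets ``gamma`` are shared fixed
effects.

Inference marginalizes the latent ``N`` and ``rho`` analytically: a
gamma-mixed Poisson thinned by ``p`` is negative binomial with mean
``lambda * p`` and the same shape, so

    n_js ~ NegBin(mean = lambda_js * p_js, shape = r)
    y_js | n_js ~ multinomial(n_js, p_djs / p_js).

The sampler is a blocked adaptive Metropolis-within-Gibbs scheme: joint
random-walk updates per species (vectorized across species, which are
conditionally independent given the shared parameters), random-walk updates
for ``gamma`` and ``log r``, conjugate Gibbs draws for the hyper-means, and
log-scale random-walk updates for the hyper-variances.

Priors: hyper-means ~ normal(0, variance 100); hyper-variances get a
gamma(shape 0.1, rate 0.1) prior on the precision by default (a documented
switch applies it to the variance itself instead); vegetation offsets ~
normal(0, variance 100); the negative-binomial shape r ~ gamma(0.1, 0.1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .data_prep import ElevationScaler, SurveyDataset
from .detection import cell_probabilities

__all__ = [
    "CommunityHyper",
    "SpeciesParams",
    "PosteriorSamples",
    "AbundanceCurve",
    "site_species_loglik",
    "gelman_rubin",
    "expected_abundance_curve",
    "CommunityDistanceSamplingModel",
    "fit_community_model",
    "sample_latent_abundance",
    "SAMPLER_PRESETS",
]

# MCMC settings: "desk" is the default working scale; "paper" mirrors the
# long production runs (3 x 200k iterations, 50k burn-in, thin 10).
SAMPLER_PRESETS = {
    "desk": dict(n_chains=3, n_draws=3000, n_warmup=1000, thin=1),
    "paper": dict(n_chains=3, n_draws=15000, n_warmup=50000, thin=10),
}

_HYPER_FIELDS = ("alpha", "beta0", "beta1", "beta2")


@dataclass(frozen=True)
class CommunityHyper:
    """Community-level means and variances of the species parameters."""

    mu_alpha: float
    mu_beta0: float
    mu_beta1: float
    mu_beta2: float
    var_alpha: float
    var_beta0: float
    var_beta1: float
    var_beta2: float

    def __post_init__(self):
        for name in _HYPER_FIELDS:
            if getattr(self, f"var_{name}") < 0:
                raise ValueError(f"var_{name} must be >= 0")

    def means(self) -> np.ndarray:
        return np.array([getattr(self, f"mu_{k}") for k in _HYPER_FIELDS])

    def variances(self) -> np.ndarray:
        return np.array([getattr(self, f"var_{k}") for k in _HYPER_FIELDS])


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level detection intercept and abundance-curve coefficients."""

    alpha: float
    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self):
        for k in _HYPER_FIELDS:
            if not np.isfinite(getattr(self, k)):
                raise ValueError(f"{k} must be finite")


def _nb_logpmf(n, mean, shape):
    """Negative binomial log-pmf with mean/shape parameterization."""
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    lp = (
        gammaln(n + shape)
        - gammaln(shape)
        - gammaln(n + 1.0)
        + shape * np.log(shape / (shape + mean))
        + n * np.log(mean / (shape + mean), where=mean > 0, out=np.zeros_like(mean * n))
    )
    return np.where((mean == 0) & (n > 0), -np.inf, lp)


def site_species_loglik(
    y,
    params: SpeciesParams,
    *,
    gamma,
    veg: int,
    x: float,
    overdispersion: float,
    breaks=(0.0, 10.0, 20.0, 50.0, 100.0),
    w: float = 100.0,
) -> float:
    """Marginal log-likelihood of one site's distance-class counts for one
    species, with latent abundance ``N`` and the gamma multiplier ``rho``
    integrated out.

    Parameters
    ----------
    y : array_like of int
        Counts per distance class at this site.
    params : SpeciesParams
    gamma : array_like
        Vegetation detection offsets (reference first, = 0).
    veg : int
        Vegetation category code of the site.
    x : float
        Standardized elevation of the site.
    overdispersion : float
        Negative-binomial shape r (> 0).
    """
    if overdispersion <= 0:
        raise ValueError("overdispersion shape must be > 0")
    y = np.asarray(y, dtype=np.int64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    gamma = np.asarray(gamma, dtype=float)
    sigma = float(np.exp(params.alpha + gamma[veg]))
    cells = cell_probabilities(sigma, breaks, w)
    p_d, p = np.atleast_1d(cells.p_d.ravel()), float(cells.p)
    lam = float(np.exp(params.beta0 + params.beta1 * x + params.beta2 * x * x))
    n = int(y.sum())
    if p <= 0.0:
        if n > 0:
            warnings.warn("p_js = 0 with detections present: impossible data")
            return -np.inf
        return 0.0
    ll = float(_nb_logpmf(n, lam * p, overdispersion))
    if n > 0:
        p_cond = p_d / p
        with np.errstate(divide="ignore"):
            logp = np.log(p_cond)
        if np.any((y > 0) & (p_cond == 0)):
            return -np.inf
        ll += float(
            gammaln(n + 1.0) - gammaln(y + 1.0).sum() + np.where(y > 0, y * logp, 0.0).sum()
        )
    return ll


# -- convergence ------------------------------------------------------------


def gelman_rubin(draws, split: bool = True):
    """Split-chain potential scale reduction factor (Rhat).

    Parameters
    ----------
    draws : ndarray of shape (chains, iterations) or (chains, iterations, K)
        Posterior draws; at least 2 chains and 10 draws each (4 when
        ``split=False`` is forced off for hand-checks).
    split : bool
        Split each chain in half before computing the statistic (guards
        against within-chain trends).

    Returns
    -------
    float or ndarray of shape (K,)
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        return float(gelman_rubin(draws[..., None], split=split)[0])
    if draws.ndim != 3:
        raise ValueError("draws must be (chains, iterations[, K])")
    c, n, k = draws.shape
    if c < 2:
        raise ValueError("Rhat requires at least 2 chains")
    if split:
        half = n // 2
        draws = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
        c, n, k = draws.shape
    if n < 2:
        raise ValueError("need at least 2 draws per (split) chain")
    chain_mean = draws.mean(axis=1)  # (c, k)
    chain_var = draws.var(axis=1, ddof=1)  # (c, k)
    w = chain_var.mean(axis=0)
    b_over_n = chain_mean.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w == 0, 1.0, rhat)


# -- posterior container ----------------------------------------------------


@dataclass
class PosteriorSamples:
    """Multi-chain posterior draws with metadata and convergence summaries.

    ``draws`` maps parameter names to arrays of shape (chains, iterations)
    or (chains, iterations, K).
    """

    draws: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {k: v.shape[:2] for k, v in self.draws.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"inconsistent chain/iteration shapes: {shapes}")
        if first[0] < 2:
            warnings.warn("fewer than 2 chains: Rhat unavailable")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: (chains * iterations, ...)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def mean(self, name: str):
        return self.stacked(name).mean(axis=0)

    def quantiles(self, name: str, q=(0.025, 0.5, 0.975)):
        return np.quantile(self.stacked(name), q, axis=0)

    def credible_interval(self, name: str, level: float = 0.95):
        a = (1.0 - level) / 2.0
        return self.quantiles(name, (a, 1.0 - a))

    def rhat(self) -> dict:
        out = {}
        for name, v in self.draws.items():
            if self.n_chains < 2:
                out[name] = np.nan
                continue
            if v.ndim <= 3:
                out[name] = gelman_rubin(v)
            else:  # matrix-valued parameters (e.g. covariance draws)
                c, n = v.shape[:2]
                flat = gelman_rubin(v.reshape(c, n, -1))
                out[name] = np.asarray(flat).reshape(v.shape[2:])
        return out

    def max_rhat(self) -> float:
        vals = [np.max(np.atleast_1d(r)) for r in self.rhat().values()]
        return float(np.nanmax(vals))

    def summary(self) -> dict:
        """JSON-ready summary: mean, sd, 95% CI and Rhat per parameter."""
        out = {}
        rhats = self.rhat()
        for name, v in self.draws.items():
            flat = self.stacked(name)
            lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
            out[name] = {
                "mean": np.mean(flat, axis=0).tolist(),
                "sd": np.std(flat, axis=0, ddof=1).tolist(),
                "ci95": [np.atleast_1d(lo).tolist(), np.atleast_1d(hi).tolist()],
                "rhat": np.atleast_1d(rhats[name]).tolist(),
            }
        return out

    def save(self, prefix) -> None:
        """Persist draws (npz) and a JSON summary next to each other."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(prefix.with_suffix(".npz"), **self.draws)
        doc = {"meta": self.meta, "summary": self.summary()}
        prefix.with_suffix(".json").write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as z:
            draws = {k: z[k] for k in z.files}
        meta = {}
        jpath = prefix.with_suffix(".json")
        if jpath.exists():
            meta = json.loads(jpath.read_text()).get("meta", {})
        return cls(draws=draws, meta=meta)


# -- abundance curves --------------------------------------------------------


@dataclass(frozen=True)
class AbundanceCurve:
    """Expected abundance over an elevation grid for one species.

    ``grid`` is standardized elevation, ``grid_m`` the same points in
    metres; ``values`` is ``exp(beta0 + beta1 x + beta2 x^2)``, divided by
    its maximum when ``standardized``.
    """

    grid: np.ndarray
    grid_m: np.ndarray
    values: np.ndarray
    standardized: bool

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve over the standardized grid."""
        return float(np.trapezoid(self.values, self.grid))


def expected_abundance_curve(
    params: SpeciesParams,
    scaler: ElevationScaler,
    elev_range_m,
    n_grid: int = 1000,
    standardize: bool = False,
) -> AbundanceCurve:
    """Quadratic log-abundance response over an elevation grid.

    Parameters
    ----------
    params : SpeciesParams
        Typically posterior means of ``beta0, beta1, beta2``.
    scaler : ElevationScaler
        The standardization used at fit time.
    elev_range_m : (float, float)
        Grid limits in metres; should span the observed range.
    n_grid : int
        Number of grid points (>= 2).
    standardize : bool
        Rescale so the curve maximum equals 1 (for overlap comparisons
        between abundant and rare species).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    lo, hi = float(elev_range_m[0]), float(elev_range_m[1])
    if not lo < hi:
        raise ValueError("elevation range must satisfy min < max")
    grid_m = np.linspace(lo, hi, n_grid)
    x = scaler.transform(grid_m)
    vals = np.exp(params.beta0 + params.beta1 * x + params.beta2 * x**2)
    if standardize:
        vals = vals / vals.max()
    return AbundanceCurve(grid=x, grid_m=grid_m, values=vals, standardized=standardize)


# -- vectorized likelihood pieces (internal) ---------------------------------


class _Data:
    """Precomputed views of a prepared survey for fast likelihood evals."""

    def __init__(self, ds: SurveyDataset):
        if "elev_std" not in ds.sites.columns:
            raise ValueError("dataset must be prepared (missing elev_std); "
                             "run data_prep.prepare_dataset first")
        self.x = ds.sites["elev_std"].to_numpy(float)  # (J,)
        self.veg = ds.sites["vegetation"].to_numpy(int)  # (J,)
        self.V = int(self.veg.max()) + 1
        self.y = ds.counts  # (J, S, D)
        self.n = ds.counts.sum(axis=2)  # (J, S)
        self.breaks = np.asarray(ds.breaks, float)
        self.w = float(ds.w)
        self.J, self.S, self.D = ds.counts.shape
        self.X = np.stack([np.ones_like(self.x), self.x, self.x**2], axis=1)  # (J,3)
        # counts of sites per vegetation category, and per-category count sums
        # y summed over sites within category: (V, S, D)
        self.y_by_veg = np.zeros((self.V, self.S, self.D))
        np.add.at(self.y_by_veg, self.veg, self.y)


def _detection_terms(data: _Data, alpha, gamma_full):
    """Per-species detection pieces.

    Returns ``p`` (V, S) overall detection probability per vegetation
    category, and ``ll_multi`` (S,) the multinomial kernel
    ``sum_{j,d} y log p_cond`` (log multinomial coefficients excluded:
    constant in the parameters).
    """
    log_sigma = alpha[None, :] + gamma_full[:, None]  # (V, S)
    # floor keeps extreme proposals evaluable (p -> 0 then rejects them)
    sigma = np.maximum(np.exp(np.maximum(log_sigma, -300.0)), 1e-12)
    cells = cell_probabilities(sigma, data.breaks, data.w)
    p = cells.p  # (V, S)
    with np.errstate(divide="ignore", invalid="ignore"):
        # p_cond is nan where p underflowed to 0: counts there are impossible
        log_pcond = np.where(cells.p_cond > 0, np.log(cells.p_cond), -np.inf)
    ll = np.where(data.y_by_veg > 0, data.y_by_veg * log_pcond, 0.0)
    return p, ll.sum(axis=(0, 2))


def _nb_terms(data: _Data, betas, p, shape):
    """Negative-binomial kernel per species given detection p by category.

    betas: (S, 3); p: (V, S); returns (S,) of
    ``sum_j log NB(n_js; mean lambda_js p_js, shape)`` with the
    n-independent ``-gammaln(n+1)`` term included (constant, harmless).
    """
    log_lam = data.X @ betas.T  # (J, S)
    # floor keeps log() finite if a proposal drives lambda*p to underflow
    mean = np.maximum(np.exp(log_lam) * p[data.veg], 1e-290)  # (J, S)
    lp = (
        gammaln(data.n + shape)
        - gammaln(shape)
        - gammaln(data.n + 1.0)
        + shape * np.log(shape / (shape + mean))
        + data.n * np.log(mean / (shape + mean))
    )
    return lp.sum(axis=0)


def _species_loglik(data: _Data, alpha, betas, gamma_full, shape):
    """(S,) marginal log-likelihood per species (constants dropped)."""
    p, ll_multi = _detection_terms(data, alpha, gamma_full)
    return _nb_terms(data, betas, p, shape) + ll_multi


def _normal_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


# -- the sampler -------------------------------------------------------------


class _AdaptiveScale:
    """Robbins-Monro adaptation of a log proposal scale toward a target
    acceptance rate; frozen after warmup."""

    def __init__(self, shape, init=0.1, target=0.3):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.t = 0

    def scale(self):
        return np.exp(self.log_s)

    def update(self, acc_prob):
        self.t += 1
        step = min(0.25, self.t ** -0.6)
        self.log_s = np.clip(
            self.log_s + step * (acc_prob - self.target),
            np.log(1e-4), np.log(20.0),
        )


def _sample_prior_chain(S, V, cfg, seed, variance_prior):
    """Exact i.i.d. draws from the model's priors (no data): used to verify
    the stated prior moments and for prior predictive checks."""
    rng = np.random.default_rng(seed)
    n = cfg["n_draws"]
    hv_shape, hv_rate = cfg["hyper_var_prior"]
    r_shape, r_rate = cfg["r_prior"]
    mu = rng.normal(0.0, 10.0, size=(n, 4))
    g = rng.gamma(hv_shape, 1.0 / hv_rate, size=(n, 4))
    var = g if variance_prior == "variance" else 1.0 / g
    theta = mu[:, None, :] + np.sqrt(var)[:, None, :] * rng.standard_normal((n, S, 4))
    out = {
        "alpha": theta[:, :, 0], "beta0": theta[:, :, 1],
        "beta1": theta[:, :, 2], "beta2": theta[:, :, 3],
        "gamma": np.concatenate(
            [np.zeros((n, 1)), rng.normal(0.0, 10.0, size=(n, V - 1))], axis=1
        ),
        "r": rng.gamma(r_shape, 1.0 / r_rate, size=n),
    }
    for i, k in enumerate(_HYPER_FIELDS):
        out[f"mu_{k}"] = mu[:, i]
        out[f"var_{k}"] = var[:, i]
    return out


def _run_chain(data: _Data, cfg, seed, variance_prior):
    if cfg.get("prior_only"):
        return _sample_prior_chain(data.S, data.V, cfg, seed, variance_prior)
    rng = np.random.default_rng(seed)
    S, V = data.S, data.V
    nb_prior_shape, nb_prior_rate = cfg["r_prior"]
    hv_shape, hv_rate = cfg["hyper_var_prior"]

    # initial values from the priors' typical range (overdispersed but sane)
    mu = rng.normal(0.0, 1.0, size=4)
    mu[0] = np.log(30.0) + rng.normal(0.0, 0.3)  # alpha hyper-mean: plausible sigma
    var = rng.gamma(2.0, 0.5, size=4) + 0.1
    theta = mu[None, :] + rng.normal(0.0, np.sqrt(var), size=(S, 4))
    gamma_free = rng.normal(0.0, 0.1, size=V - 1)
    log_r = float(rng.normal(np.log(2.0), 0.3))

    def gamma_full(gf):
        return np.concatenate([[0.0], gf])

    ll_s = _species_loglik(data, theta[:, 0], theta[:, 1:], gamma_full(gamma_free),
                           np.exp(log_r))
    # an initial draw can be impossible (e.g. sigma too small for the
    # observed far-class counts, likelihood -inf); repair those species
    # with a moment-matched start or the chain can never accept a move
    bad = ~np.isfinite(ll_s)
    if bad.any():
        n_bar = data.n.mean(axis=0)
        theta[bad, 0] = np.log(30.0)
        theta[bad, 1] = np.log((n_bar[bad] + 0.05) / 0.2)
        theta[bad, 2] = 0.0
        theta[bad, 3] = 0.0
        ll_s = _species_loglik(data, theta[:, 0], theta[:, 1:],
                               gamma_full(gamma_free), np.exp(log_r))
        if not np.all(np.isfinite(ll_s)):
            raise RuntimeError("could not find a finite-likelihood start")

    ad_theta = _AdaptiveScale((S, 1), init=1.0, target=0.3)
    ad_gamma = _AdaptiveScale((), init=0.05, target=0.25)
    ad_r = _AdaptiveScale((), init=0.2, target=0.4)
    ad_var = _AdaptiveScale((4,), init=0.4, target=0.4)

    # per-species proposal shape: empirical covariance Cholesky factors
    # (adaptive Metropolis with diminishing adaptation: the estimation
    # window keeps growing, so adjustments vanish asymptotically)
    L = np.tile(0.08 * np.eye(4), (S, 1, 1))
    n_iter_total = cfg["n_warmup"] + cfg["n_draws"] * cfg["thin"]
    hist = np.empty((n_iter_total, S, 4))
    Lg = 0.05 * np.eye(max(V - 1, 1))
    hist_g = np.empty((n_iter_total, max(V - 1, 1)))

    n_iter = cfg["n_warmup"] + cfg["n_draws"] * cfg["thin"]
    keep = cfg["n_draws"]
    out = {
        "alpha": np.empty((keep, S)), "beta0": np.empty((keep, S)),
        "beta1": np.empty((keep, S)), "beta2": np.empty((keep, S)),
        "gamma": np.empty((keep, V)), "r": np.empty(keep),
    }
    for k in _HYPER_FIELDS:
        out[f"mu_{k}"] = np.empty(keep)
        out[f"var_{k}"] = np.empty(keep)
    kept = 0

    for it in range(n_iter):
        warm = it < cfg["n_warmup"]
        r_now = np.exp(log_r)
        gfull = gamma_full(gamma_free)

        hist[it] = theta
        if V > 1:
            hist_g[it] = gamma_free
        if it >= 200 and it % 100 == 0:
            window = hist[it // 2 : it]
            cov = np.einsum(
                "tsk,tsl->skl",
                window - window.mean(axis=0),
                window - window.mean(axis=0),
            ) / (window.shape[0] - 1)
            cov += 1e-6 * np.eye(4)
            L = np.linalg.cholesky(cov) * (2.38 / 2.0)
            if V > 1:
                wg = hist_g[it // 2 : it]
                cg = np.cov(wg.T).reshape(V - 1, V - 1) + 1e-8 * np.eye(V - 1)
                Lg = np.linalg.cholesky(cg) * (2.38 / np.sqrt(V - 1))

        # 1) per-species joint RW on (alpha_s, beta0_s, beta1_s, beta2_s)
        # with the covariance-shaped adaptive proposal; several sweeps per
        # iteration since this block limits mixing (hyper updates are Gibbs)
        for sweep in range(cfg["species_sweeps"]):
            z = rng.standard_normal((S, 4))
            if it % 10 == 9 and sweep == 0:
                # occasional isotropic move guards against a collapsed
                # covariance estimate trapping a species
                prop = theta + 0.05 * z
            else:
                prop = theta + ad_theta.scale() * np.einsum("skl,sl->sk", L, z)
            ll_prop = _species_loglik(data, prop[:, 0], prop[:, 1:], gfull, r_now)
            lprior_cur = _normal_logpdf(theta, mu[None, :], var[None, :]).sum(axis=1)
            lprior_prop = _normal_logpdf(prop, mu[None, :], var[None, :]).sum(axis=1)
            log_acc = (ll_prop + lprior_prop) - (ll_s + lprior_cur)
            acc = np.log(rng.random(S)) < log_acc
            theta[acc] = prop[acc]
            ll_s = np.where(acc, ll_prop, ll_s)
            if warm:
                ad_theta.update(np.exp(np.minimum(0.0, log_acc))[:, None])

        # 2) vegetation offsets (joint RW; reference stays 0); nothing to
        # update when the survey has a single vegetation category
        for _ in range(1 if V > 1 else 0):
            prop_g = gamma_free + ad_gamma.scale() * (Lg @ rng.standard_normal(V - 1))
            ll_prop_s = _species_loglik(data, theta[:, 0], theta[:, 1:],
                                        gamma_full(prop_g), r_now)
            log_acc_g = (
                ll_prop_s.sum() - ll_s.sum()
                + _normal_logpdf(prop_g, 0.0, 100.0).sum()
                - _normal_logpdf(gamma_free, 0.0, 100.0).sum()
            )
            if np.log(rng.random()) < log_acc_g:
                gamma_free = prop_g
                ll_s = ll_prop_s
            if warm:
                ad_gamma.update(min(1.0, np.exp(min(0.0, log_acc_g))))

        # 3) overdispersion shape on the log scale (gamma prior + Jacobian)
        prop_lr = log_r + ad_r.scale() * rng.standard_normal()
        ll_prop_s = _species_loglik(data, theta[:, 0], theta[:, 1:],
                                    gamma_full(gamma_free), np.exp(prop_lr))
        def _r_lp(lr):
            r = np.exp(lr)
            return (nb_prior_shape * lr) - nb_prior_rate * r  # log prior + Jacobian
        log_acc_r = ll_prop_s.sum() - ll_s.sum() + _r_lp(prop_lr) - _r_lp(log_r)
        if np.log(rng.random()) < log_acc_r:
            log_r = prop_lr
            ll_s = ll_prop_s
        if warm:
            ad_r.update(min(1.0, np.exp(min(0.0, log_acc_r))))

        # 4) hyper-means: conjugate normal Gibbs (prior N(0, 100))
        for k in range(4):
            prec = 1.0 / 100.0 + S / var[k]
            m = (theta[:, k].sum() / var[k]) / prec
            mu[k] = rng.normal(m, 1.0 / np.sqrt(prec))

        # 5) hyper-variances: log-scale RW, gamma(0.1, 0.1) prior on the
        #    variance (or on the precision under the documented switch)
        for k in range(4):
            lv = np.log(var[k])
            prop_lv = lv + ad_var.scale()[k] * rng.standard_normal()

            def _var_post(lvk):
                v = np.exp(lvk)
                ll = _normal_logpdf(theta[:, k], mu[k], v).sum()
                if variance_prior == "variance":
                    lp = hv_shape * lvk - hv_rate * v  # gamma prior + Jacobian
                else:  # gamma prior on precision 1/v; Jacobian of log v
                    lp = -hv_shape * lvk - hv_rate / v
                return ll + lp

            la = _var_post(prop_lv) - _var_post(lv)
            if np.log(rng.random()) < la:
                var[k] = np.exp(prop_lv)
            if warm:
                ad_var.log_s[k] += min(0.25, (ad_var.t + 1) ** -0.6) * (
                    min(1.0, np.exp(min(0.0, la))) - ad_var.target
                )
        ad_var.t += 1

        if not warm and (it - cfg["n_warmup"] + 1) % cfg["thin"] == 0:
            out["alpha"][kept] = theta[:, 0]
            out["beta0"][kept] = theta[:, 1]
            out["beta1"][kept] = theta[:, 2]
            out["beta2"][kept] = theta[:, 3]
            out["gamma"][kept] = gamma_full(gamma_free)
            out["r"][kept] = np.exp(log_r)
            for i, k in enumerate(_HYPER_FIELDS):
                out[f"mu_{k}"][kept] = mu[i]
                out[f"var_{k}"][kept] = var[i]
            kept += 1

    return out


class CommunityDistanceSamplingModel:
    """Hierarchical community distance-sampling abundance model.

    Estimator-style interface: configure in ``__init__``, call
    :meth:`fit` on a prepared :class:`~avianiche.data_prep.SurveyDataset`,
    then read fitted attributes (``posterior_``, ``rhat_``,
    ``species_params_``, ``converged_``).

    Parameters
    ----------
    n_chains, n_draws, n_warmup, thin : int
        MCMC schedule; three chains of 3000 retained draws after 1000
        warm-up by default.  ``preset="paper"`` switches to the long
        production schedule.
    seed : int
        Master seed; chains use sub-seeds derived from it.
    variance_prior : {"variance", "precision"}
        Whether the gamma(0.1, 0.1) hyper-prior applies to the precision
        (default; the standard weakly informative choice for this model
        family) or to the variance itself.
    rhat_threshold : float
        Convergence is flagged (not enforced) when any split-Rhat is at
        or above this value.
    """

    def __init__(
        self,
        n_chains: int = 3,
        n_draws: int = 3000,
        n_warmup: int = 1000,
        thin: int = 1,
        seed: int = 0,
        variance_prior: str = "precision",
        r_prior=(0.1, 0.1),
        hyper_var_prior=(0.1, 0.1),
        rhat_threshold: float = 1.1,
        preset: str | None = None,
        species_sweeps: int = 3,
        prior_only: bool = False,
    ):
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.thin = thin
        self.seed = seed
        self.variance_prior = variance_prior
        self.r_prior = r_prior
        self.hyper_var_prior = hyper_var_prior
        self.rhat_threshold = rhat_threshold
        self.preset = preset
        self.species_sweeps = species_sweeps
        self.prior_only = prior_only

    # sklearn-style param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_chains", "n_draws", "n_warmup", "thin", "seed",
                "variance_prior", "r_prior", "hyper_var_prior",
                "rhat_threshold", "preset", "species_sweeps", "prior_only",
            )
        }

    def set_params(self, **params) -> "CommunityDistanceSamplingModel":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _schedule(self) -> dict:
        cfg = dict(n_chains=self.n_chains, n_draws=self.n_draws,
                   n_warmup=self.n_warmup, thin=self.thin)
        if self.preset is not None:
            cfg.update(SAMPLER_PRESETS[self.preset])
        cfg["r_prior"] = tuple(self.r_prior)
        cfg["hyper_var_prior"] = tuple(self.hyper_var_prior)
        cfg["species_sweeps"] = int(self.species_sweeps)
        cfg["prior_only"] = bool(self.prior_only)
        return cfg

    def fit(self, ds: SurveyDataset) -> "CommunityDistanceSamplingModel":
        if self.variance_prior not in ("variance", "precision"):
            raise ValueError("variance_prior must be 'variance' or 'precision'")
        data = _Data(ds)
        cfg = self._schedule()
        ss = np.random.SeedSequence(self.seed)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                       ss.spawn(cfg["n_chains"])]
        chains = [
            _run_chain(data, cfg, cs, self.variance_prior) for cs in chain_seeds
        ]
        draws = {
            k: np.stack([c[k] for c in chains], axis=0) for k in chains[0]
        }
        meta = {
            "n_chains": cfg["n_chains"], "n_draws_per_chain": cfg["n_draws"],
            "n_draws_total": cfg["n_chains"] * cfg["n_draws"],
            "n_warmup": cfg["n_warmup"], "thin": cfg["thin"],
            "seed": self.seed, "chain_seeds": chain_seeds,
            "species": list(ds.species),
            "variance_prior": self.variance_prior,
        }
        self.posterior_ = PosteriorSamples(draws=draws, meta=meta)
        self.species_names_ = list(ds.species)
        self.rhat_ = self.posterior_.rhat()
        self.max_rhat_ = self.posterior_.max_rhat()
        self.converged_ = bool(self.max_rhat_ < self.rhat_threshold)
        if not self.converged_:
            warnings.warn(
                f"convergence not reached: max Rhat = {self.max_rhat_:.3f} "
                f">= {self.rhat_threshold}"
            )
        self.hyper_mean_ = {
            f"mu_{k}": float(self.posterior_.mean(f"mu_{k}")) for k in _HYPER_FIELDS
        }
        self.species_params_ = self.species_param_means()
        return self

    def species_param_means(self) -> list:
        """Posterior-mean SpeciesParams per species (used for the curves)."""
        post = self.posterior_
        a = post.mean("alpha")
        b0, b1, b2 = (post.mean(k) for k in ("beta0", "beta1", "beta2"))
        return [
            SpeciesParams(alpha=float(a[s]), beta0=float(b0[s]),
                          beta1=float(b1[s]), beta2=float(b2[s]))
            for s in range(len(a))
        ]

    def abundance_curves(
        self, scaler: ElevationScaler, elev_range_m, n_grid: int = 1000,
        standardize: bool = True,
    ) -> dict:
        """Per-species expected abundance curves from posterior means."""
        return {
            name: expected_abundance_curve(p, scaler, elev_range_m, n_grid,
                                           standardize)
            for name, p in zip(self.species_names_, self.species_params_)
        }


def fit_community_model(ds: SurveyDataset, **kwargs) -> PosteriorSamples:
    """Functional wrapper over :class:`CommunityDistanceSamplingModel`."""
    return CommunityDistanceSamplingModel(**kwargs).fit(ds).posterior_


def sample_latent_abundance(
    post: PosteriorSamples, ds: SurveyDataset, n_samples: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Draw latent abundances ``N_js`` from their posterior predictive.

    For each retained posterior draw, the gamma multiplier is sampled from
    its conditional ``rho | n ~ gamma(r + n, r + lambda p)`` and the
    undetected remainder from ``Poisson(lambda (1 - p) rho)``, so
    ``N = n + remainder >= n`` always.

    Returns an array of shape (n_samples, n_sites, n_species).
    """
    rng = np.random.default_rng(seed)
    data = _Data(ds)
    total = post.n_chains * post.n_draws
    idx = rng.choice(total, size=min(n_samples, total), replace=False)
    alpha = post.stacked("alpha")[idx]
    b = np.stack([post.stacked(k)[idx] for k in ("beta0", "beta1", "beta2")], axis=-1)
    gamma = post.stacked("gamma")[idx]
    r = post.stacked("r")[idx]
    out = np.empty((len(idx), data.J, data.S), dtype=np.int64)
    for i in range(len(idx)):
        log_sigma = alpha[i][None, :] + gamma[i][data.veg][:, None]
        p = cell_probabilities(np.exp(log_sigma), data.breaks, data.w).p  # (J,S)
        lam = np.exp(data.X @ b[i].T)  # (J, S)
        rho = rng.gamma(r[i] + data.n, 1.0 / (r[i] + lam * p))
        out[i] = data.n + rng.poisson(lam * (1.0 - p) * rho)
    return out
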