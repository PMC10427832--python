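"""Joint species distribution extension of the community model.

For a small set of focal species, the gamma overdispersion multiplier is
replaced by a species-specific, site-level random effect drawn from a
multivariate normal with an unstructured covariance:

    log(lambda_js) = beta0_s + beta1_s x_j + beta2_s x_j^2 + eta_js
    eta_j. ~ MVN(0, Sigma)

so that, conditional on ``eta``, detected totals are Poisson with mean
``lambda_js p_js``.  The species x species covariance ``Sigma`` carries the
residual (after-covariate) associations; standardizing each posterior draw
gives the residual correlation matrix ``R``.  Comparing a null fit (no
elevation terms) with the covariate fit shows how much of the apparent
species association is explained by the shared elevation response.

Priors: ``Sigma`` ~ inverse Wishart (weakly informative: df = S + 1,
identity scale, both configurable); everything else as in
:mod:`avianiche.community_model`.  ``Sigma | eta`` is conjugate and drawn by
Gibbs; ``eta`` rows are updated by vectorized per-site random walks.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .community_model import (
    PosteriorSamples,
    _AdaptiveScale,
    _Data,
    _detection_terms,
    _normal_logpdf,
    _HYPER_FIELDS,
)
from .data_prep import SurveyDataset

__all__ = [
    "JointSpeciesDistributionModel",
    "fit_jsdm",
    "residual_correlations",
    "compare_residuals",
]


def _poisson_terms(data: _Data, betas, eta, p):
    """(S,) Poisson kernel ``sum_j n log m - m`` with m = lambda * p."""
    log_lam = data.X @ betas.T + eta  # (J, S)
    log_m = log_lam + np.log(p[data.veg])
    return (data.n * log_m - np.exp(log_m)).sum(axis=0)


def _species_loglik_jsdm(data: _Data, alpha, betas, eta, gamma_full):
    p, ll_multi = _detection_terms(data, alpha, gamma_full)
    return _poisson_terms(data, betas, eta, p) + ll_multi


def _run_chain_jsdm(data: _Data, cfg, seed, include_elevation):
    rng = np.random.default_rng(seed)
    S, V, J = data.S, data.V, data.J
    coords = (0, 1, 2, 3) if include_elevation else (0, 1)  # alpha, beta0[, beta1, beta2]

    iw_df = cfg["iw_df"]
    iw_scale = cfg["iw_scale"]

    mu = np.zeros(4)
    mu[0] = np.log(30.0) + rng.normal(0.0, 0.3)
    var = rng.gamma(2.0, 0.5, size=4) + 0.1
    theta = np.zeros((S, 4))
    for k in coords:
        theta[:, k] = mu[k] + rng.normal(0.0, np.sqrt(var[k]), size=S)
    gamma_free = rng.normal(0.0, 0.1, size=V - 1)
    Sigma = invwishart.rvs(df=iw_df + S, scale=iw_scale, random_state=rng)
    Sigma = np.atleast_2d(Sigma)
    eta = rng.multivariate_normal(np.zeros(S), Sigma, size=J)

    def gamma_full(gf):
        return np.concatenate([[0.0], gf])

    ll_s = _species_loglik_jsdm(data, theta[:, 0], theta[:, 1:], eta,
                                gamma_full(gamma_free))

    ad_theta = _AdaptiveScale((S, 1), init=1.0, target=0.3)
    L = np.tile(0.08 * np.eye(4), (S, 1, 1))
    n_iter_total = cfg["n_warmup"] + cfg["n_draws"] * cfg["thin"]
    hist = np.empty((n_iter_total, S, 4))
    ad_eta = _AdaptiveScale((J, 1), init=0.3, target=0.3)
    ad_gamma = _AdaptiveScale((), init=0.05, target=0.25)
    ad_var = _AdaptiveScale((4,), init=0.4, target=0.4)

    n_iter = cfg["n_warmup"] + cfg["n_draws"] * cfg["thin"]
    keep = cfg["n_draws"]
    out = {
        "alpha": np.empty((keep, S)), "beta0": np.empty((keep, S)),
        "beta1": np.empty((keep, S)), "beta2": np.empty((keep, S)),
        "gamma": np.empty((keep, V)), "Sigma": np.empty((keep, S, S)),
    }
    for k in _HYPER_FIELDS:
        out[f"mu_{k}"] = np.empty(keep)
        out[f"var_{k}"] = np.empty(keep)
    eta_sum = np.zeros((J, S))
    kept = 0

    for it in range(n_iter):
        warm = it < cfg["n_warmup"]
        gfull = gamma_full(gamma_free)

        hist[it] = theta
        if it >= 200 and it % 100 == 0:
            window = hist[it // 2 : it]
            cov = np.einsum(
                "tsk,tsl->skl",
                window - window.mean(axis=0),
                window - window.mean(axis=0),
            ) / (window.shape[0] - 1)
            cov += 1e-6 * np.eye(4)
            L = np.linalg.cholesky(cov) * (2.38 / 2.0)

        # 1) species-level parameters (only the active coordinates move)
        z = rng.standard_normal((S, 4))
        if it % 10 == 9:
            step = 0.05 * z
        else:
            step = ad_theta.scale() * np.einsum("skl,sl->sk", L, z)
        if not include_elevation:
            step[:, 2:] = 0.0
        prop = theta + step
        ll_prop = _species_loglik_jsdm(data, prop[:, 0], prop[:, 1:], eta, gfull)
        lp_cur = np.zeros(S)
        lp_prop = np.zeros(S)
        for k in coords:
            lp_cur += _normal_logpdf(theta[:, k], mu[k], var[k])
            lp_prop += _normal_logpdf(prop[:, k], mu[k], var[k])
        log_acc = (ll_prop + lp_prop) - (ll_s + lp_cur)
        acc = np.log(rng.random(S)) < log_acc
        theta[acc] = prop[acc]
        ll_s = np.where(acc, ll_prop, ll_s)
        if warm:
            ad_theta.update(np.exp(np.minimum(0.0, log_acc))[:, None])

        # 2) site random effects (vectorized per-site RW; prior MVN(0, Sigma))
        p_det, _ = _detection_terms(data, theta[:, 0], gfull)
        log_lam = data.X @ theta[:, 1:].T
        m = np.exp(log_lam + eta) * p_det[data.veg]  # (J, S)
        prop_eta = eta + ad_eta.scale() * rng.standard_normal((J, S))
        m_prop = m * np.exp(prop_eta - eta)
        Sigma_inv = np.linalg.inv(Sigma)
        q_cur = np.einsum("js,st,jt->j", eta, Sigma_inv, eta)
        q_prop = np.einsum("js,st,jt->j", prop_eta, Sigma_inv, prop_eta)
        log_acc_e = (
            (data.n * (prop_eta - eta) - (m_prop - m)).sum(axis=1)
            - 0.5 * (q_prop - q_cur)
        )
        acc_e = np.log(rng.random(J)) < log_acc_e
        eta[acc_e] = prop_eta[acc_e]
        if warm:
            ad_eta.update(np.exp(np.minimum(0.0, log_acc_e))[:, None])
        ll_s = _species_loglik_jsdm(data, theta[:, 0], theta[:, 1:], eta, gfull)

        # 2b) translation Gibbs along the likelihood-flat ridges: for any
        # abundance coefficient beta_ks, adding delta to it and subtracting
        # delta * c_j (its covariate column) from the species' eta column
        # leaves log lambda unchanged; the conditional for delta under the
        # two Gaussian priors is itself Gaussian, so the ridge is resampled
        # exactly
        Omega = np.linalg.inv(Sigma)
        for k in coords:
            if k == 0:
                continue  # alpha enters detection only, no ridge with eta
            c = data.X[:, k - 1]  # (J,): 1, x or x^2
            c2 = float(c @ c)
            wsum = c @ eta  # (S,)
            for s_i in range(S):
                prec = 1.0 / var[k] + c2 * Omega[s_i, s_i]
                lin = -(theta[s_i, k] - mu[k]) / var[k] + float(Omega[s_i] @ wsum)
                delta = rng.normal(lin / prec, 1.0 / np.sqrt(prec))
                theta[s_i, k] += delta
                eta[:, s_i] -= delta * c
                wsum[s_i] -= delta * c2
        # log lambda is unchanged by the translations, so ll_s is still valid

        # 3) Sigma | eta: conjugate inverse-Wishart Gibbs draw
        Sigma = np.atleast_2d(invwishart.rvs(
            df=iw_df + J, scale=iw_scale + eta.T @ eta, random_state=rng
        ))

        # 4) vegetation offsets
        prop_g = gamma_free + ad_gamma.scale() * rng.standard_normal(V - 1)
        ll_prop_s = _species_loglik_jsdm(data, theta[:, 0], theta[:, 1:], eta,
                                         gamma_full(prop_g))
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

        # 5) hyper-means (Gibbs) and hyper-variances (log-scale RW)
        for k in coords:
            prec = 1.0 / 100.0 + S / var[k]
            mloc = (theta[:, k].sum() / var[k]) / prec
            mu[k] = rng.normal(mloc, 1.0 / np.sqrt(prec))
            lv = np.log(var[k])
            prop_lv = lv + ad_var.scale()[k] * rng.standard_normal()

            def _post(lvk):
                # gamma(0.1, 0.1) prior on the precision, as in the
                # community model; Jacobian of the log-variance walk
                v = np.exp(lvk)
                return (_normal_logpdf(theta[:, k], mu[k], v).sum()
                        - 0.1 * lvk - 0.1 / v)

            la = _post(prop_lv) - _post(lv)
            if np.log(rng.random()) < la:
                var[k] = np.exp(prop_lv)
        ad_var.t += 1

        if not warm and (it - cfg["n_warmup"] + 1) % cfg["thin"] == 0:
            out["alpha"][kept] = theta[:, 0]
            out["beta0"][kept] = theta[:, 1]
            out["beta1"][kept] = theta[:, 2]
            out["beta2"][kept] = theta[:, 3]
            out["gamma"][kept] = gamma_full(gamma_free)
            out["Sigma"][kept] = Sigma
            for i, k in enumerate(_HYPER_FIELDS):
                out[f"mu_{k}"][kept] = mu[i]
                out[f"var_{k}"][kept] = var[i]
            eta_sum += eta
            kept += 1

    out["_eta_mean"] = eta_sum / max(kept, 1)
    return out


class JointSpeciesDistributionModel:
    """Joint species distribution model with latent residual correlations.

    Parameters
    ----------
    include_elevation : bool
        Fit the linear + quadratic elevation terms (the covariate model) or
        drop them (the null model).
    iw_df : int or None
        Inverse-Wishart degrees of freedom; default ``n_species + 1``.
    iw_scale : ndarray or None
        Inverse-Wishart scale matrix; default identity.
    max_species : int
        Guard against unstable covariance estimation: more species than
        this triggers a warning.
    Other parameters as in
    :class:`~avianiche.community_model.CommunityDistanceSamplingModel`.
    """

    def __init__(
        self,
        include_elevation: bool = True,
        n_chains: int = 3,
        n_draws: int = 3000,
        n_warmup: int = 1000,
        thin: int = 1,
        seed: int = 0,
        iw_df: int | None = None,
        iw_scale=None,
        max_species: int = 8,
        rhat_threshold: float = 1.1,
    ):
        self.include_elevation = include_elevation
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.thin = thin
        self.seed = seed
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.max_species = max_species
        self.rhat_threshold = rhat_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "include_elevation", "n_chains", "n_draws", "n_warmup",
                "thin", "seed", "iw_df", "iw_scale", "max_species",
                "rhat_threshold",
            )
        }

    def set_params(self, **params) -> "JointSpeciesDistributionModel":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ds: SurveyDataset) -> "JointSpeciesDistributionModel":
        data = _Data(ds)
        if data.S > self.max_species:
            warnings.warn(
                f"{data.S} species exceeds the guard of {self.max_species}: "
                "an unstructured covariance grows quadratically; restrict to "
                "a small focal set (the family of interest) or raise "
                "max_species explicitly"
            )
        cfg = dict(
            n_chains=self.n_chains, n_draws=self.n_draws,
            n_warmup=self.n_warmup, thin=self.thin,
            iw_df=self.iw_df if self.iw_df is not None else data.S + 1,
            iw_scale=(np.asarray(self.iw_scale, float)
                      if self.iw_scale is not None else np.eye(data.S)),
        )
        ss = np.random.SeedSequence(self.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(cfg["n_chains"])]
        chains = [_run_chain_jsdm(data, cfg, cs, self.include_elevation)
                  for cs in seeds]
        eta_mean = np.mean([c.pop("_eta_mean") for c in chains], axis=0)
        draws = {k: np.stack([c[k] for c in chains], axis=0) for k in chains[0]}
        if not self.include_elevation:
            # elevation terms are fixed at 0 in the null model
            for k in ("beta1", "beta2", "mu_beta1", "mu_beta2",
                      "var_beta1", "var_beta2"):
                del draws[k]
        meta = {
            "model": "jsdm",
            "include_elevation": self.include_elevation,
            "n_chains": cfg["n_chains"], "n_draws_per_chain": cfg["n_draws"],
            "n_warmup": cfg["n_warmup"], "thin": cfg["thin"],
            "seed": self.seed, "species": list(ds.species),
            "iw_df": int(cfg["iw_df"]),
        }
        self.posterior_ = PosteriorSamples(draws=draws, meta=meta)
        self.eta_mean_ = eta_mean
        self.species_names_ = list(ds.species)
        self.rhat_ = self.posterior_.rhat()
        self.max_rhat_ = self.posterior_.max_rhat()
        self.converged_ = bool(self.max_rhat_ < self.rhat_threshold)
        if not self.converged_:
            warnings.warn(
                f"convergence not reached: max Rhat = {self.max_rhat_:.3f}"
            )
        self.correlations_ = residual_correlations(self.posterior_)
        return self


def fit_jsdm(ds: SurveyDataset, include_elevation: bool = True, **kwargs):
    """Functional wrapper over :class:`JointSpeciesDistributionModel`."""
    model = JointSpeciesDistributionModel(
        include_elevation=include_elevation, **kwargs
    )
    return model.fit(ds).posterior_


def _correlation_draws(post: PosteriorSamples) -> np.ndarray:
    """(n_total_draws, S, S) correlation matrices from the Sigma draws."""
    Sigma = post.stacked("Sigma")
    d = np.sqrt(np.einsum("kii->ki", Sigma))
    bad = ~np.all(d > 0, axis=1)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} Sigma draws are not positive definite"
        )
    return Sigma / (d[:, :, None] * d[:, None, :])


def residual_correlations(post: PosteriorSamples) -> pd.DataFrame:
    """Posterior summaries of pairwise residual correlations.

    One row per unordered species pair with the posterior mean, 50% and
    95% credible intervals, and whether the 95% interval excludes zero.
    """
    R = _correlation_draws(post)
    species = post.meta.get("species") or [f"s{i}" for i in range(R.shape[1])]
    rows = []
    for i, j in combinations(range(len(species)), 2):
        r = R[:, i, j]
        lo95, lo50, hi50, hi95 = np.quantile(r, [0.025, 0.25, 0.75, 0.975])
        rows.append({
            "species_a": species[i], "species_b": species[j],
            "mean": float(r.mean()),
            "ci50_lo": float(lo50), "ci50_hi": float(hi50),
            "ci95_lo": float(lo95), "ci95_hi": float(hi95),
            "excludes_zero": bool(lo95 > 0 or hi95 < 0),
        })
    return pd.DataFrame(rows)


def compare_residuals(null_post: PosteriorSamples,
                      cov_post: PosteriorSamples) -> pd.DataFrame:
    """Per-pair change in residual correlation between null and covariate
    fits: difference of posterior means and any change in the
    excludes-zero status of the 95% interval."""
    a = residual_correlations(null_post)
    b = residual_correlations(cov_post)
    if list(a["species_a"]) != list(b["species_a"]) or list(
        a["species_b"]
    ) != list(b["species_b"]):
        raise ValueError("posteriors cover different species sets")
    out = a[["species_a", "species_b"]].copy()
    out["mean_null"] = a["mean"]
    out["mean_covariate"] = b["mean"]
    out["shift"] = b["mean"] - a["mean"]
    out["excludes_zero_null"] = a["excludes_zero"]
    out["excludes_zero_covariate"] = b["excludes_zero"]
    out["status_changed"] = a["excludes_zero"] != b["excludes_zero"]
    return out
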