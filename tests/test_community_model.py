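"""Likelihood, convergence diagnostics, abundance curves and the sampler."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import binom, gamma as gamma_dist, multinomial, nbinom

from avianiche.community_model import (
    CommunityDistanceSamplingModel,
    PosteriorSamples,
    SpeciesParams,
    expected_abundance_curve,
    gelman_rubin,
    sample_latent_abundance,
    site_species_loglik,
)
from avianiche.data_prep import ElevationScaler, SurveyDataset
from avianiche.detection import cell_probabilities

BREAKS = (0.0, 10.0, 20.0, 50.0, 100.0)


def enumeration_loglik(y, lam, p_d, r):
    """Brute-force oracle: sum the latent Poisson-gamma abundance out
    explicitly (N capped at the 0.999999 quantile) with binomial thinning
    and the multinomial class split."""
    p = p_d.sum()
    p_cond = p_d / p
    n = int(np.sum(y))
    cap = int(nbinom.ppf(0.999999, r, r / (r + lam))) + n + 60
    Ns = np.arange(n, cap + 1)
    prob = (nbinom.pmf(Ns, r, r / (r + lam)) * binom.pmf(n, Ns, p)).sum()
    if n > 0:
        prob *= multinomial.pmf(np.asarray(y), n, p_cond)
    return np.log(prob)


class TestSiteSpeciesLoglik:
    @pytest.mark.parametrize("case", range(12))
    def test_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        lam0 = rng.uniform(0.1, 8.0)
        r = rng.uniform(0.3, 5.0)
        alpha = np.log(rng.uniform(10, 60))
        x = rng.normal()
        gam = np.array([0.0, rng.normal(0, 0.2)])
        veg = int(rng.integers(0, 2))
        sp = SpeciesParams(alpha=alpha, beta0=np.log(lam0), beta1=0.3, beta2=-0.2)
        sigma = np.exp(alpha + gam[veg])
        cells = cell_probabilities(sigma, BREAKS, 100.0)
        y = rng.multinomial(int(rng.integers(0, 6)), cells.p_cond)
        lam = np.exp(sp.beta0 + sp.beta1 * x + sp.beta2 * x * x)
        got = site_species_loglik(y, sp, gamma=gam, veg=veg, x=x, overdispersion=r)
        want = enumeration_loglik(y, lam, cells.p_d, r)
        assert got == pytest.approx(want, abs=1e-6)

    def test_zero_counts_equal_nb_at_zero(self):
        sp = SpeciesParams(alpha=np.log(30), beta0=np.log(2.0), beta1=0, beta2=0)
        p = cell_probabilities(30.0, BREAKS, 100.0).p
        got = site_species_loglik([0, 0, 0, 0], sp, gamma=[0.0], veg=0, x=0.0,
                                  overdispersion=1.5)
        want = nbinom.logpmf(0, 1.5, 1.5 / (1.5 + 2.0 * p))
        assert got == pytest.approx(float(want), abs=1e-12)

    def test_single_class_perfect_detection_is_pure_negative_binomial(self):
        # one class spanning [0, w] and sigma -> inf: the multinomial is
        # degenerate and p -> 1, leaving the count likelihood alone
        sp = SpeciesParams(alpha=np.log(1e8), beta0=np.log(3.0), beta1=0, beta2=0)
        got = site_species_loglik([4], sp, gamma=[0.0], veg=0, x=0.0,
                                  overdispersion=2.0, breaks=(0.0, 100.0))
        want = nbinom.logpmf(4, 2.0, 2.0 / (2.0 + 3.0))
        assert got == pytest.approx(float(want), abs=1e-6)

    def test_impossible_data_minus_inf(self):
        sp = SpeciesParams(alpha=np.log(0.05), beta0=0.0, beta1=0, beta2=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = site_species_loglik([0, 0, 0, 3], sp, gamma=[0.0], veg=0,
                                      x=0.0, overdispersion=1.0)
        assert got == -np.inf

    def test_invalid_overdispersion(self):
        sp = SpeciesParams(alpha=1.0, beta0=0.0, beta1=0, beta2=0)
        with pytest.raises(ValueError):
            site_species_loglik([0, 0, 0, 0], sp, gamma=[0.0], veg=0, x=0.0,
                                overdispersion=0.0)


def psrf_by_hand(draws):
    """Direct transcription of the split-chain PSRF formula."""
    draws = np.asarray(draws, float)
    c, n = draws.shape
    half = n // 2
    sub = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n2 = sub.shape
    means = sub.mean(axis=1)
    w = sub.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    return np.sqrt(((n2 - 1) / n2 * w + b_over_n) / w)


class TestGelmanRubin:
    def test_converged_chains_near_one(self, rng):
        draws = rng.normal(size=(3, 10_000))
        assert gelman_rubin(draws) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        assert gelman_rubin(draws) > 3.0

    def test_matches_hand_formula_on_tiny_case(self):
        draws = np.array([[1.0, 2.0, 4.0, 3.0], [2.5, 0.5, 1.5, 5.0]])
        assert gelman_rubin(draws) == pytest.approx(psrf_by_hand(draws), abs=1e-12)

    def test_matches_arviz(self, rng):
        az = pytest.importorskip("arviz")
        draws = np.cumsum(rng.normal(size=(3, 400)), axis=1) * 0.05 + rng.normal(
            size=(3, 400)
        )
        ours = gelman_rubin(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws[..., None]))["x"][0])
        # arviz rank-normalizes before the split-chain formula, so the two
        # agree closely but not to machine precision
        assert ours == pytest.approx(theirs, rel=1e-2)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestAbundanceCurve:
    scaler = ElevationScaler(mean=2850.0, sd=600.0)

    def test_flat_curve(self):
        p = SpeciesParams(alpha=0.0, beta0=np.log(4.0), beta1=0.0, beta2=0.0)
        c = expected_abundance_curve(p, self.scaler, (1800, 3900), 101)
        np.testing.assert_allclose(c.values, 4.0)
        c_std = expected_abundance_curve(p, self.scaler, (1800, 3900), 101,
                                         standardize=True)
        np.testing.assert_allclose(c_std.values, 1.0)

    def test_peak_at_vertex(self):
        p = SpeciesParams(alpha=0.0, beta0=0.0, beta1=-1.0, beta2=-0.5)
        c = expected_abundance_curve(p, self.scaler, (1800, 3900), 5001)
        x_peak = c.grid[np.argmax(c.values)]
        assert x_peak == pytest.approx(-p.beta1 / (2 * p.beta2), abs=2e-3)

    def test_area_matches_quadrature(self):
        p = SpeciesParams(alpha=0.0, beta0=0.3, beta1=-1.0, beta2=-0.45)
        c = expected_abundance_curve(p, self.scaler, (1800, 3900), 1000)
        lo, hi = c.grid[0], c.grid[-1]
        want, _ = quad(lambda x: np.exp(p.beta0 + p.beta1 * x + p.beta2 * x**2),
                       lo, hi, epsabs=1e-12, epsrel=1e-12)
        assert c.area == pytest.approx(want, rel=1e-6)

    def test_standardized_max_is_one(self):
        p = SpeciesParams(alpha=0.0, beta0=2.0, beta1=-1.0, beta2=-0.3)
        c = expected_abundance_curve(p, self.scaler, (1800, 3900), 400,
                                     standardize=True)
        assert c.values.max() == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        p = SpeciesParams(alpha=0.0, beta0=0.0, beta1=0.0, beta2=0.0)
        with pytest.raises(ValueError):
            expected_abundance_curve(p, self.scaler, (1800, 3900), 1)


class TestPosteriorSamples:
    def test_summary_and_io(self, tmp_path, rng):
        post = PosteriorSamples(
            draws={"a": rng.normal(size=(2, 50)), "b": rng.normal(size=(2, 50, 3))},
            meta={"seed": 1},
        )
        s = post.summary()
        assert set(s) == {"a", "b"} and "rhat" in s["a"]
        post.save(tmp_path / "post")
        back = PosteriorSamples.load(tmp_path / "post")
        np.testing.assert_array_equal(back.draws["b"], post.draws["b"])
        assert back.meta["seed"] == 1

    def test_credible_interval_orders(self, rng):
        post = PosteriorSamples(draws={"a": rng.normal(size=(2, 500))})
        lo, hi = post.credible_interval("a")
        assert lo < hi


def tiny_fit(ds, **kw):
    kw.setdefault("n_chains", 2)
    kw.setdefault("n_draws", 400)
    kw.setdefault("n_warmup", 400)
    kw.setdefault("seed", 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CommunityDistanceSamplingModel(**kw).fit(ds)


class TestFit:
    def test_shapes_and_determinism(self, small_survey):
        from avianiche.data_prep import prepare_dataset
        ds, _ = small_survey
        prep, _, kept = prepare_dataset(ds, min_obs=5)
        m1 = tiny_fit(prep)
        m2 = tiny_fit(prep)
        S = len(kept)
        assert m1.posterior_.draws["beta1"].shape == (2, 400, S)
        np.testing.assert_array_equal(
            m1.posterior_.draws["mu_beta1"], m2.posterior_.draws["mu_beta1"]
        )
        assert isinstance(m1.converged_, bool)
        assert set(m1.rhat_) == set(m1.posterior_.draws)

    def test_all_zero_counts_pull_abundance_down(self):
        sites = pd.DataFrame({
            "site_id": [f"p{i}" for i in range(40)],
            "elevation_m": np.linspace(1800, 3900, 40),
            "vegetation": np.zeros(40, dtype=int),
            "elev_std": np.linspace(-1.6, 1.6, 40),
        })
        ds = SurveyDataset(sites=sites, species=["a", "b"],
                           counts=np.zeros((40, 2, 4), dtype=int))
        m = tiny_fit(ds)
        # median of exp(beta0): robust to the heavy upper tail the
        # inverse-gamma hyper-variance prior allows
        lam0 = np.exp(np.median(m.posterior_.stacked("beta0"), axis=0))
        assert np.all(lam0 < 1.0)

    @pytest.mark.parametrize("reading", ["variance", "precision"])
    def test_prior_only_reproduces_priors(self, small_survey, reading):
        from avianiche.data_prep import prepare_dataset
        ds, _ = small_survey
        prep, _, _ = prepare_dataset(ds, min_obs=5)
        m = tiny_fit(prep, n_draws=4000, prior_only=True, seed=8,
                     variance_prior=reading)
        mu = m.posterior_.stacked("mu_beta1")
        assert abs(mu.mean()) < 3 * 10 / np.sqrt(len(mu) / 4)  # autocorr slack
        assert mu.std() == pytest.approx(10.0, rel=0.1)
        var = m.posterior_.stacked("var_beta0")
        # gamma(0.1, 0.1) on the variance itself, or on the precision
        want = gamma_dist.cdf(1.0, 0.1, scale=10.0)
        if reading == "precision":
            want = 1.0 - want
        assert (var < 1.0).mean() == pytest.approx(want, abs=0.03)

    def test_sklearn_style_params(self):
        m = CommunityDistanceSamplingModel(n_draws=10)
        assert m.get_params()["n_draws"] == 10
        m.set_params(n_draws=20, seed=3)
        assert m.n_draws == 20 and m.seed == 3
        with pytest.raises(ValueError):
            m.set_params(bogus=1)

    def test_latent_abundance_dominates_detections(self, small_survey):
        from avianiche.data_prep import prepare_dataset
        ds, _ = small_survey
        prep, _, _ = prepare_dataset(ds, min_obs=5)
        m = tiny_fit(prep)
        N = sample_latent_abundance(m.posterior_, prep, n_samples=20, seed=0)
        assert N.shape[0] == 20
        assert np.all(N >= prep.n_js[None, :, :])
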