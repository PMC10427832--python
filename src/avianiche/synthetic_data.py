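"""Forward simulation of point-count surveys and species trait tables.

The generator reproduces the statistical structure the community
distance-sampling model assumes, so that every downstream stage can be
exercised and its parameter recovery measured without field data:

* species parameters drawn from community-level normal hyperdistributions;
* quadratic log-abundance responses to standardized elevation;
* Poisson-gamma (negative-binomial) overdispersed latent abundance;
* individuals placed at radial distances with the triangular point-transect
  density ``2 r / w^2`` and detected with half-normal probability whose
  scale depends on the site's vegetation category;
* detected individuals binned into the survey's distance classes;
* family-structured compositional diet / foraging-strata traits and
  lognormal body masses.

The generating truth (hyper-parameters, species parameters, latent
abundances) is always attached to the returned dataset for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community_model import CommunityHyper, SpeciesParams
from .data_prep import ElevationScaler, SurveyDataset, TraitTable, DEFAULT_BREAKS

__all__ = [
    "GeneratorConfig",
    "TraitGeneratorConfig",
    "DEFAULT_HYPER",
    "DEFAULT_GAMMA",
    "draw_species_params",
    "design_sites",
    "simulate_survey",
    "simulate_traits",
    "generate_dataset",
    "default_fixture_config",
]

# Community hyper-parameters used as generator defaults.  The abundance
# hyper-means place the community optimum just below the middle of the
# gradient (mu_beta1 = -1.0, mu_beta2 = -0.45 on the standardized scale)
# with moderate between-species spread; mu_alpha = log(30 m) is a typical
# half-normal detection scale for forest point counts.
DEFAULT_HYPER = CommunityHyper(
    mu_alpha=float(np.log(30.0)), mu_beta0=0.0, mu_beta1=-1.0, mu_beta2=-0.45,
    var_alpha=0.04, var_beta0=0.4, var_beta1=0.25, var_beta2=0.04,
)

# Default log-scale detection offsets for 8 vegetation categories (reference
# category first, fixed at 0); spread of about +/-25% in sigma across
# habitats, denser vegetation detecting less far.
DEFAULT_GAMMA = (0.0, -0.25, -0.15, -0.05, 0.05, 0.10, 0.18, 0.25)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the survey forward model.

    Defaults are the package's standard small-community fixture: 15 species
    at 250 point-count stations across a 1800-3900 m gradient with 8
    vegetation categories, negative-binomial shape 2.
    """

    n_species: int = 15
    n_sites: int = 250
    n_families: int = 5
    elevation_range: tuple = (1800.0, 3900.0)
    n_veg_categories: int = 8
    community_hyper: CommunityHyper = DEFAULT_HYPER
    detection_gamma: tuple = DEFAULT_GAMMA
    overdispersion: float = 2.0
    breaks: tuple = DEFAULT_BREAKS
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 1 <= self.n_families <= self.n_species:
            raise ValueError("need 1 <= n_families <= n_species")
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ValueError("elevation_range must satisfy min < max")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be > 0")
        if len(self.detection_gamma) != self.n_veg_categories:
            raise ValueError("detection_gamma length must equal n_veg_categories")
        if self.detection_gamma[0] != 0.0:
            raise ValueError("reference vegetation category must have gamma = 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "community_hyper" in doc:
            doc["community_hyper"] = CommunityHyper(**doc["community_hyper"])
        for k in ("elevation_range", "detection_gamma", "breaks"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["community_hyper"] = asdict(self.community_hyper)
        doc["elevation_range"] = list(self.elevation_range)
        doc["detection_gamma"] = list(self.detection_gamma)
        doc["breaks"] = list(self.breaks)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class TraitGeneratorConfig:
    """Configuration of the trait-table generator.

    ``family_coherence`` is the Dirichlet concentration with which species
    compositions cluster around their family's centre; larger means more
    similar within a family (``inf`` makes them identical).
    """

    family_assignment: dict = field(default_factory=dict)  # species -> family
    diet_categories: int = 6
    strata_categories: int = 5
    family_coherence: float = 50.0
    mass_log_mean: float = float(np.log(20.0))
    mass_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not self.family_assignment:
            raise ValueError("family_assignment must map every species to a family")
        if not self.family_coherence > 0:
            raise ValueError("family_coherence must be > 0")


def draw_species_params(
    hyper: CommunityHyper, n_species: int, seed: int
) -> list:
    """Draw species-level parameters from the community hyperdistributions.

    Each of ``alpha_s, beta0_s, beta1_s, beta2_s`` is an independent normal
    draw with the corresponding hyper-mean and hyper-variance.
    """
    if np.any(hyper.variances() < 0):
        raise ValueError("hyper-variances must be >= 0")
    rng = np.random.default_rng(seed)
    draws = hyper.means()[None, :] + rng.standard_normal((n_species, 4)) * np.sqrt(
        hyper.variances()[None, :]
    )
    return [
        SpeciesParams(alpha=float(a), beta0=float(b0), beta1=float(b1), beta2=float(b2))
        for a, b0, b1, b2 in draws
    ]


def design_sites(
    n_sites: int, elevation_range, n_veg: int, seed: int,
    sectors: int = 1,
) -> pd.DataFrame:
    """Random survey design: elevations uniform over the gradient and
    vegetation categories uniform over ``0..n_veg-1`` (both are free
    configuration; pass an explicit site table to the simulator for any
    other layout)."""
    rng = np.random.default_rng(seed)
    lo, hi = elevation_range
    df = pd.DataFrame(
        {
            "site_id": [f"pt{i + 1:04d}" for i in range(n_sites)],
            "elevation_m": rng.uniform(lo, hi, size=n_sites),
            "vegetation": rng.integers(0, n_veg, size=n_sites),
            "sector": [chr(ord("A") + (i % sectors)) for i in range(n_sites)],
        }
    )
    return df


def simulate_survey(
    design: pd.DataFrame,
    params: list,
    gamma,
    overdispersion: float,
    seed: int,
    breaks=DEFAULT_BREAKS,
    species_names=None,
    hyper: CommunityHyper | None = None,
) -> SurveyDataset:
    """Simulate distance-class counts for a community at the design's sites.

    Per site ``j`` and species ``s``: latent abundance
    ``N_js ~ Poisson(lambda_js * rho_js)`` with
    ``rho_js ~ gamma(shape=r, rate=r)``; each individual is placed at a
    radial distance drawn from the triangular density ``2 r / w^2``,
    retained with half-normal probability ``exp(-r^2 / (2 sigma_js^2))``,
    and retained individuals are binned into the distance classes.

    ``lambda_js`` uses elevation standardized internally over the design's
    sites; the scaler, species parameters and latent truth are attached as
    ``dataset.truth``.
    """
    if not overdispersion > 0:
        raise ValueError("overdispersion must be > 0")
    gamma = np.asarray(gamma, dtype=float)
    veg = design["vegetation"].to_numpy()
    if veg.min() < 0 or veg.max() >= gamma.shape[0]:
        raise KeyError(
            f"vegetation categories {sorted(set(veg))} exceed gamma length {len(gamma)}"
        )
    rng = np.random.default_rng(seed)
    J = len(design)
    S = len(params)
    breaks = np.asarray(breaks, dtype=float)
    w = float(breaks[-1])
    D = len(breaks) - 1

    scaler = ElevationScaler.fit(design["elevation_m"])
    x = scaler.transform(design["elevation_m"])

    alpha = np.array([p.alpha for p in params])
    betas = np.array([[p.beta0, p.beta1, p.beta2] for p in params])  # (S,3)
    lam = np.exp(betas[:, 0][None, :] + betas[:, 1][None, :] * x[:, None]
                 + betas[:, 2][None, :] * x[:, None] ** 2)  # (J,S)
    sigma = np.exp(alpha[None, :] + gamma[veg][:, None])  # (J,S)

    r = overdispersion
    rho = rng.gamma(shape=r, scale=1.0 / r, size=(J, S))
    N = rng.poisson(lam * rho)

    counts = np.zeros((J, S, D), dtype=np.int64)
    for s in range(S):
        total = int(N[:, s].sum())
        if total == 0:
            continue
        site_idx = np.repeat(np.arange(J), N[:, s])
        dist = w * np.sqrt(rng.random(total))  # triangular 2r/w^2
        detect = rng.random(total) < np.exp(
            -(dist**2) / (2.0 * sigma[site_idx, s] ** 2)
        )
        if not detect.any():
            continue
        cls = np.digitize(dist[detect], breaks[1:-1])
        np.add.at(counts[:, s, :], (site_idx[detect], cls), 1)

    if species_names is None:
        species_names = [f"sp{s + 1:02d}" for s in range(S)]
    sites = design.reset_index(drop=True).copy()
    truth = {
        "alpha": alpha, "beta0": betas[:, 0], "beta1": betas[:, 1],
        "beta2": betas[:, 2], "gamma": gamma, "overdispersion": r,
        "N": N, "lambda": lam,
        "scaler_mean": scaler.mean, "scaler_sd": scaler.sd,
        "species": list(species_names), "seed": seed,
    }
    if hyper is not None:
        truth["hyper"] = asdict(hyper)
    return SurveyDataset(
        sites=sites, species=list(species_names), counts=counts,
        breaks=tuple(breaks), w=w, truth=truth,
    )


def simulate_traits(cfg: TraitGeneratorConfig) -> TraitTable:
    """Generate a family-structured trait table.

    Diet and strata compositions are Dirichlet draws centred on a
    family-level composition (itself Dirichlet over the categories), with
    within-family concentration ``family_coherence``; body masses are
    lognormal; all species are marked diurnal.
    """
    species = list(cfg.family_assignment)
    families = sorted(set(cfg.family_assignment.values()))
    rng = np.random.default_rng(cfg.seed)

    def _family_centres(k):
        return {f: rng.dirichlet(np.ones(k)) for f in families}

    centres = {"diet": _family_centres(cfg.diet_categories),
               "strata": _family_centres(cfg.strata_categories)}

    rows = []
    for sp in species:
        fam = cfg.family_assignment[sp]
        row = {"species": sp, "family": fam,
               "mass_g": float(rng.lognormal(cfg.mass_log_mean, cfg.mass_log_sd)),
               "activity": "diurnal"}
        for group, ncat in (("diet", cfg.diet_categories),
                            ("strata", cfg.strata_categories)):
            centre = centres[group][fam]
            if np.isinf(cfg.family_coherence):
                comp = centre
            else:
                # Dirichlet needs strictly positive concentrations
                conc = np.maximum(cfg.family_coherence * centre, 1e-9)
                comp = rng.dirichlet(conc)
            comp = comp / comp.sum()
            for d in range(ncat):
                row[f"{group}_{d + 1}"] = float(comp[d])
        rows.append(row)
    return TraitTable(pd.DataFrame(rows))


def default_fixture_config(seed: int = 0) -> GeneratorConfig:
    """The package's standard fixture: 15 species, 250 sites."""
    return GeneratorConfig(seed=seed)


def generate_dataset(cfg: GeneratorConfig, n_families: int | None = None):
    """Full synthetic study: survey dataset plus matching trait table.

    Species are split as evenly as possible over the families
    (``cfg.n_families`` unless overridden).  Returns
    ``(SurveyDataset, TraitTable)``.
    """
    if n_families is None:
        n_families = cfg.n_families
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    params = draw_species_params(cfg.community_hyper, cfg.n_species, seeds[0])
    design = design_sites(cfg.n_sites, cfg.elevation_range,
                          cfg.n_veg_categories, seeds[1])
    ds = simulate_survey(
        design, params, cfg.detection_gamma, cfg.overdispersion, seeds[2],
        breaks=cfg.breaks, hyper=cfg.community_hyper,
    )
    fam = {
        sp: f"fam{(i % n_families) + 1}" for i, sp in enumerate(ds.species)
    }
    traits = simulate_traits(TraitGeneratorConfig(family_assignment=fam,
                                                  seed=seeds[3]))
    return ds, traits
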