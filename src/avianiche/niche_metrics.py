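"""Multidimensional niche-overlap indices and the within-family pair report.

Implements the niche dimensions used to explain coexistence of ecologically
similar (same-family) species:

* **elevation** — overlap of standardized abundance-elevation curves:
  ``N_AB = Ov_AB / T_A`` where ``Ov_AB`` is the area of intersection of the
  two curves and ``T_A`` the area under species A's curve; pairs are
  classified *similar* (both directions >= 0.5), *no-overlap* (both < 0.1)
  or *partial*;
* **diet / foraging strata** — Pianka's symmetric overlap of compositional
  resource-use vectors;
* **horizontal space** — the spatial site index, shared detection sites
  over the union of detection sites (and a latent-abundance variant that
  uses posterior draws of true abundance instead of raw detections);
* **body size** — the family-level coefficient of variation of body mass;
* **null models** — randomized cross-family species pairs providing the
  expectation of any pair metric in the absence of family structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .community_model import AbundanceCurve
from .data_prep import SurveyDataset, TraitTable

__all__ = [
    "OverlapResult",
    "NullSummary",
    "elevation_overlap",
    "classify_elevation_pair",
    "pianka_overlap",
    "spatial_site_index",
    "SpatialIndex",
    "body_size_cv",
    "latent_co_occurrence",
    "null_pair_distribution",
    "detection_sites",
    "build_pair_table",
    "DEFAULT_THRESHOLDS",
]

# Classification thresholds: "similar" elevation niches need both overlap
# directions >= similar; "no-overlap" needs both < no_overlap; the strata
# partitioning label applies at Pianka overlap <= strata.
DEFAULT_THRESHOLDS = {"similar": 0.5, "no_overlap": 0.1, "strata": 0.6}


@dataclass(frozen=True)
class OverlapResult:
    """Directional elevation-niche overlap between two species.

    ``n_ab`` is the proportion of species A's niche overlapped by B
    (``ov / t_a``); ``n_ba`` the reverse.
    """

    n_ab: float
    n_ba: float
    ov: float
    t_a: float
    t_b: float


def elevation_overlap(curve_a: AbundanceCurve, curve_b: AbundanceCurve) -> OverlapResult:
    """Overlap of two standardized abundance-elevation curves.

    The shared area ``Ov`` is the trapezoidal integral of the pointwise
    minimum of the two curves on their common grid; ``N_AB = Ov / T_A``
    and ``N_BA = Ov / T_B``.
    """
    if not (curve_a.standardized and curve_b.standardized):
        raise ValueError("curves must be standardized (max = 1)")
    if curve_a.grid.shape != curve_b.grid.shape or not np.allclose(
        curve_a.grid, curve_b.grid
    ):
        raise ValueError("curves must share a common elevation grid")
    t_a, t_b = curve_a.area, curve_b.area
    if t_a <= 0 or t_b <= 0:
        raise ValueError("zero-area abundance curve")
    ov = float(np.trapezoid(np.minimum(curve_a.values, curve_b.values), curve_a.grid))
    return OverlapResult(n_ab=ov / t_a, n_ba=ov / t_b, ov=ov, t_a=t_a, t_b=t_b)


def classify_elevation_pair(
    res: OverlapResult,
    similar: float = DEFAULT_THRESHOLDS["similar"],
    no_overlap: float = DEFAULT_THRESHOLDS["no_overlap"],
) -> str:
    """Classify an elevation-overlap result.

    ``"similar"`` when both directions are at least ``similar`` (default
    0.5: each species occupies at least half the other's elevation niche);
    ``"no-overlap"`` when both are below ``no_overlap``; otherwise
    ``"partial"``.
    """
    if res.n_ab >= similar and res.n_ba >= similar:
        return "similar"
    if res.n_ab < no_overlap and res.n_ba < no_overlap:
        return "no-overlap"
    return "partial"


def pianka_overlap(p_a, p_b) -> float:
    """Pianka's symmetric niche-overlap index of two compositions.

    ``O_AB = sum(p_A p_B) / sqrt(sum(p_A^2) sum(p_B^2))``; 0 for disjoint
    resource use, 1 for proportional use.  Scale-invariant in either
    argument.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("compositions must have the same length")
    if np.any(p_a < 0) or np.any(p_b < 0):
        raise ValueError("compositions must be non-negative")
    den = np.sqrt((p_a**2).sum() * (p_b**2).sum())
    if den == 0:
        raise ValueError("all-zero composition")
    return float((p_a * p_b).sum() / den)


@dataclass(frozen=True)
class SpatialIndex:
    """Spatial site index with its counts: shared sites / union of sites."""

    ssi: float
    shared: int
    union: int


def spatial_site_index(sites_a, sites_b) -> SpatialIndex:
    """Within-habitat horizontal segregation index of two species.

    ``SSI = |A intersection B| / |A union B|`` over the sites where each
    species was detected; 0 means complete segregation, 1 complete
    co-occurrence.
    """
    a, b = set(sites_a), set(sites_b)
    union = a | b
    if not union:
        raise ValueError("both detection-site sets are empty")
    shared = len(a & b)
    return SpatialIndex(ssi=shared / len(union), shared=shared, union=len(union))


def body_size_cv(masses) -> float:
    """Coefficient of variation of body masses, in percent.

    ``100 * sd / mean`` with the sample (n-1) standard deviation.
    """
    m = np.asarray(masses, dtype=float)
    if m.size < 2:
        raise ValueError("body-size CV needs at least 2 masses")
    if np.any(m <= 0):
        raise ValueError("masses must be > 0")
    return float(100.0 * m.std(ddof=1) / m.mean())


def latent_co_occurrence(n_draws_a, n_draws_b) -> float:
    """Latent-abundance co-occurrence index for a species pair.

    Given aligned posterior draws of true abundance (draws x sites) for
    species A and B, returns the posterior mean of
    ``|{sites: N_A>0 and N_B>0}| / |{sites: N_A>0 or N_B>0}|``.
    Draws where neither species is present anywhere are skipped with a
    warning.
    """
    a = np.asarray(n_draws_a) > 0
    b = np.asarray(n_draws_b) > 0
    if a.shape != b.shape:
        raise ValueError("posterior draws must be aligned (same draws x sites)")
    both = (a & b).sum(axis=1).astype(float)
    either = (a | b).sum(axis=1).astype(float)
    ok = either > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} draws with no occupied site skipped")
    if not ok.any():
        raise ValueError("no draw has an occupied site")
    return float((both[ok] / either[ok]).mean())


@dataclass(frozen=True)
class NullSummary:
    """Null distribution of a pair metric over random cross-family pairs."""

    metric: str
    draws: np.ndarray
    proportion: float
    n_draws: int
    seed: int
    observed: float | None = None
    pairs: list = field(default_factory=list)


def null_pair_distribution(
    metric,
    species,
    families,
    n_draws: int = 10000,
    seed: int = 0,
    criterion=None,
    observed: float | None = None,
    metric_name: str | None = None,
) -> NullSummary:
    """Null expectation of a pair metric from random cross-family pairs.

    Parameters
    ----------
    metric : callable(species_a, species_b) -> float
    species : sequence of species ids
    families : mapping species -> family
    n_draws : int
        Unordered cross-family pairs are sampled without replacement; if
        fewer exist than ``n_draws``, all are enumerated.
    criterion : callable(value) -> bool, optional
        The reported ``proportion`` is the fraction of null draws meeting
        it (defaults to counting nothing, proportion 0.0 with no criterion
        evaluated -> NaN).
    observed : float, optional
        An observed value to carry alongside the null draws.
    """
    pool = [
        (a, b) for a, b in combinations(sorted(species), 2)
        if families[a] != families[b]
    ]
    if not pool:
        raise ValueError("no cross-family pair available")
    rng = np.random.default_rng(seed)
    if len(pool) > n_draws:
        idx = rng.choice(len(pool), size=n_draws, replace=False)
        pairs = [pool[i] for i in idx]
    else:
        pairs = pool
    values = np.array([metric(a, b) for a, b in pairs], dtype=float)
    if criterion is not None:
        prop = float(np.mean([bool(criterion(v)) for v in values]))
    else:
        prop = float("nan")
    return NullSummary(
        metric=metric_name or getattr(metric, "__name__", "metric"),
        draws=values, proportion=prop, n_draws=len(pairs), seed=seed,
        observed=observed, pairs=pairs,
    )


def detection_sites(ds: SurveyDataset) -> dict:
    """Sites with at least one detection, per species."""
    n = ds.n_js  # (J, S)
    ids = ds.sites["site_id"].to_numpy()
    return {
        sp: set(ids[n[:, s] > 0]) for s, sp in enumerate(ds.species)
    }


def _partition_labels(category: str, strata_overlap, thresholds) -> list:
    """Most-likely partitioning mechanisms for a pair.

    Elevation partitioning whenever the elevation niches are not similar;
    vertical-strata partitioning whenever strata overlap is at or below
    the threshold; horizontal (spatial) partitioning for pairs with
    similar elevation niches (their coexistence must rely on within-
    habitat segregation).
    """
    labels = []
    if category != "similar":
        labels.append("elev")
    if strata_overlap is not None and strata_overlap <= thresholds["strata"]:
        labels.append("strata")
    if category == "similar":
        labels.append("spatial")
    return labels


def build_pair_table(
    curves: dict,
    traits: TraitTable | None,
    detections: dict,
    taxonomy,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """One row per within-family species pair with all overlap indices.

    Parameters
    ----------
    curves : mapping species -> standardized AbundanceCurve
    traits : TraitTable or None
        Missing species (or a missing table) leave the trait-based columns
        NaN and flag the row in ``missing``.
    detections : mapping species -> set of detection sites
    taxonomy : mapping species -> family
        Only families contributing two or more species yield pairs.
    thresholds : dict, optional
        ``similar``, ``no_overlap`` and ``strata`` cutoffs
        (see DEFAULT_THRESHOLDS).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    species = sorted(curves)
    fam_of = {sp: taxonomy[sp] for sp in species}
    by_family: dict = {}
    for sp in species:
        by_family.setdefault(fam_of[sp], []).append(sp)

    trait_index = set(traits.table["species"]) if traits is not None else set()
    fam_cv = {}
    if traits is not None:
        for fam, members in by_family.items():
            masses = [traits.mass(sp) for sp in members if sp in trait_index]
            fam_cv[fam] = body_size_cv(masses) if len(masses) >= 2 else np.nan

    rows = []
    for fam in sorted(by_family):
        members = by_family[fam]
        if len(members) < 2:
            continue
        for a, b in combinations(members, 2):
            res = elevation_overlap(curves[a], curves[b])
            category = classify_elevation_pair(res, thr["similar"], thr["no_overlap"])
            row = {
                "family": fam, "species_a": a, "species_b": b,
                "n_ab": res.n_ab, "n_ba": res.n_ba,
                "elev_category": category,
                "pianka_diet": np.nan, "pianka_strata": np.nan,
                "mass_a_g": np.nan, "mass_b_g": np.nan,
                "family_mass_cv_pct": fam_cv.get(fam, np.nan),
                "activity_match": np.nan,
                "missing": "",
            }
            missing = []
            if traits is not None and a in trait_index and b in trait_index:
                row["pianka_diet"] = pianka_overlap(
                    traits.composition(a, "diet"), traits.composition(b, "diet")
                )
                row["pianka_strata"] = pianka_overlap(
                    traits.composition(a, "strata"), traits.composition(b, "strata")
                )
                row["mass_a_g"] = traits.mass(a)
                row["mass_b_g"] = traits.mass(b)
                t = traits.table.set_index("species")["activity"]
                row["activity_match"] = bool(t[a] == t[b])
            else:
                missing.append("traits")
            if a in detections and b in detections:
                si = spatial_site_index(detections[a], detections[b])
                row["ssi"] = si.ssi
                row["s_ab"] = si.shared
                row["s_d"] = si.union
            else:
                row["ssi"] = row["s_ab"] = row["s_d"] = np.nan
                missing.append("detections")
            strata = row["pianka_strata"]
            row["partitioning"] = ",".join(
                _partition_labels(
                    category, None if np.isnan(strata) else strata, thr
                )
            )
            row["missing"] = ";".join(missing)
            rows.append(row)
    cols = ["family", "species_a", "species_b", "n_ab", "n_ba",
            "elev_category", "pianka_diet", "pianka_strata", "mass_a_g",
            "mass_b_g", "family_mass_cv_pct", "activity_match", "missing",
            "ssi", "s_ab", "s_d", "partitioning"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
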