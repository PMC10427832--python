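"""Survey and trait table containers, CSV I/O, validation and preparation.

The survey unit is a point-count station ("site") with a known elevation and
vegetation category; every detected individual of every species is binned
into one of four radial distance classes (0-10, 10-20, 20-50, 50-100 m by
default).  `SurveyDataset` holds the site table and the site x species x
distance-class count array.  `prepare_dataset` applies the modelling
filters: drop species below a minimum number of detections, standardize
elevation, and optionally collapse vegetation categories.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDataset",
    "ElevationScaler",
    "TraitTable",
    "read_survey",
    "write_survey",
    "read_traits",
    "read_taxonomy",
    "prepare_dataset",
]

DEFAULT_BREAKS = (0.0, 10.0, 20.0, 50.0, 100.0)

_COUNT_COL = re.compile(r"^count_(\d+)_(\d+)$")


@dataclass(frozen=True)
class ElevationScaler:
    """Mean/sd standardization of site elevations (metres).

    Each surveyed site contributes once to the mean and sd, regardless of
    how many observations it produced.
    """

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("elevation sd must be > 0 (constant elevation?)")

    @classmethod
    def fit(cls, elevations) -> "ElevationScaler":
        x = np.asarray(elevations, dtype=float)
        sd = float(x.std(ddof=0))
        if sd == 0:
            raise ValueError("elevation sd must be > 0 (constant elevation?)")
        return cls(mean=float(x.mean()), sd=sd)

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class SurveyDataset:
    """Point-count survey data: sites, species and distance-class counts.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``site_id``, ``elevation_m``,
        ``vegetation`` (integer category codes 0..V-1) and optionally
        ``sector`` and ``elev_std`` (added by :func:`prepare_dataset`).
    species : list of str
    counts : ndarray of shape (n_sites, n_species, n_classes)
        Non-negative integer counts per distance class.
    breaks : tuple of float
        Distance-class breaks, strictly increasing from 0 to ``w``.
    w : float
        Maximum observation radius, metres.
    truth : dict or None
        Generating parameters when the dataset is synthetic; used by
        parameter-recovery tests, ignored by the model.
    meta : dict
        Free-form metadata (e.g. common/rare species classification).
    """

    sites: pd.DataFrame
    species: list
    counts: np.ndarray
    breaks: tuple = DEFAULT_BREAKS
    w: float = 100.0
    truth: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_classes(self) -> int:
        return len(self.breaks) - 1

    @property
    def n_js(self) -> np.ndarray:
        """Total detections per site x species, ``sum_d y_djs``."""
        return self.counts.sum(axis=2)

    @property
    def n_veg(self) -> int:
        return int(self.sites["vegetation"].max()) + 1

    def detections_per_species(self) -> pd.Series:
        return pd.Series(
            self.counts.sum(axis=(0, 2)), index=self.species, name="detections"
        )

    # -- validation ---------------------------------------------------------

    def validate(self):
        req = {"site_id", "elevation_m", "vegetation"}
        missing = req - set(self.sites.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        if self.sites["site_id"].duplicated().any():
            dup = self.sites.loc[self.sites["site_id"].duplicated(), "site_id"]
            raise ValueError(f"duplicate site ids: {dup.tolist()[:5]}")
        veg = self.sites["vegetation"].to_numpy()
        if not np.issubdtype(veg.dtype, np.integer):
            raise ValueError("vegetation must be integer category codes")
        if veg.min() < 0:
            raise ValueError("vegetation codes must be >= 0")
        breaks = np.asarray(self.breaks, dtype=float)
        if breaks[0] != 0 or not np.isclose(breaks[-1], self.w):
            raise ValueError("breaks must run from 0 to w")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.species), self.n_classes):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sites)}, {len(self.species)}, {self.n_classes})"
            )
        if np.any(self.counts < 0):
            j, s, d = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at site {self.sites['site_id'].iloc[j]!r}, "
                f"species {self.species[s]!r}, class {d}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    # -- long-table conversion ----------------------------------------------

    def count_columns(self) -> list:
        b = [int(x) for x in self.breaks]
        return [f"count_{lo}_{hi}" for lo, hi in zip(b[:-1], b[1:])]

    def to_frame(self) -> pd.DataFrame:
        """One row per site x species with the four class-count columns."""
        J, S, D = self.counts.shape
        rep_sites = self.sites.loc[self.sites.index.repeat(S)].reset_index(drop=True)
        out = rep_sites.assign(species=np.tile(self.species, J))
        for d, col in enumerate(self.count_columns()):
            out[col] = self.counts[:, :, d].reshape(-1)
        return out


def write_survey(ds: SurveyDataset, path, truth_sidecar: bool = True) -> None:
    """Write a survey as CSV plus an optional JSON truth sidecar."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    if truth_sidecar and ds.truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(_jsonable(ds.truth), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_survey(path, breaks=None, w: float = 100.0) -> SurveyDataset:
    """Read a survey CSV (one row per site x species, class-count columns).

    Distance-class columns are recognized by name (``count_<lo>_<hi>``) and
    realigned by their breaks, so column order in the file does not matter.
    A ``<path>.truth.json`` sidecar, if present, is loaded into ``truth``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    req = {"site_id", "elevation_m", "vegetation", "species"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")

    cols = {}
    for c in df.columns:
        m = _COUNT_COL.match(c)
        if m:
            cols[(int(m.group(1)), int(m.group(2)))] = c
    if not cols:
        raise ValueError(f"{path.name}: no count_<lo>_<hi> columns found")
    edges = sorted(cols)
    file_breaks = [edges[0][0]] + [hi for _, hi in edges]
    if any(lo != file_breaks[i] for i, (lo, _) in enumerate(edges)):
        raise ValueError(f"{path.name}: distance classes have gaps: {edges}")
    if breaks is not None and list(map(float, breaks)) != list(map(float, file_breaks)):
        raise ValueError(
            f"{path.name}: file breaks {file_breaks} != expected {list(breaks)}"
        )
    breaks = tuple(float(b) for b in file_breaks)
    w = breaks[-1]
    ordered_cols = [cols[e] for e in edges]

    bad = df[ordered_cols].lt(0).any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path.name}: negative counts at file rows {rows[:10]}")

    species = sorted(df["species"].unique())
    site_cols = [
        c for c in ("site_id", "elevation_m", "vegetation", "sector")
        if c in df.columns
    ]
    sites = df[site_cols].drop_duplicates("site_id").reset_index(drop=True)
    if not np.issubdtype(sites["vegetation"].dtype, np.integer):
        raise ValueError(f"{path.name}: vegetation must be integer codes")

    wide = df.pivot_table(
        index="site_id", columns="species", values=ordered_cols,
        aggfunc="sum", fill_value=0,
    )
    counts = np.zeros((len(sites), len(species), len(edges)), dtype=np.int64)
    site_order = sites["site_id"].to_numpy()
    for d, col in enumerate(ordered_cols):
        block = wide[col].reindex(index=site_order, columns=species, fill_value=0)
        counts[:, :, d] = block.to_numpy()

    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return SurveyDataset(
        sites=sites, species=list(species), counts=counts,
        breaks=breaks, w=w, truth=truth,
    )


# -- trait tables -----------------------------------------------------------


@dataclass
class TraitTable:
    """Per-species Eltonian traits: diet and foraging-strata compositions,
    body mass (g), diel activity and family membership.

    ``table`` has one row per species with columns ``species``, ``family``,
    ``mass_g``, ``activity`` plus ``diet_*`` and ``strata_*`` compositional
    columns (each group sums to 1 per row).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        req = {"species", "family", "mass_g", "activity"}
        missing = req - set(t.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        if t["species"].duplicated().any():
            raise ValueError("duplicate species in trait table")
        if (t["mass_g"] <= 0).any():
            raise ValueError("body masses must be > 0")
        for group in ("diet", "strata"):
            cols = self.columns(group)
            if not cols:
                raise ValueError(f"no {group}_* columns in trait table")
            s = t[cols].to_numpy(dtype=float)
            if np.any(s < -1e-12):
                raise ValueError(f"negative {group} proportion")
            if np.any(np.abs(s.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{group} compositions must sum to 1")

    def columns(self, group: str) -> list:
        return [c for c in self.table.columns if c.startswith(group + "_")]

    def composition(self, species: str, group: str) -> np.ndarray:
        row = self.table.loc[self.table["species"] == species]
        if row.empty:
            raise KeyError(f"species {species!r} not in trait table")
        return row[self.columns(group)].to_numpy(dtype=float)[0]

    def mass(self, species: str) -> float:
        row = self.table.loc[self.table["species"] == species, "mass_g"]
        if row.empty:
            raise KeyError(f"species {species!r} not in trait table")
        return float(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    """Read a trait CSV; extra columns beyond the schema are kept but ignored."""
    return TraitTable(pd.read_csv(path))


def read_taxonomy(path) -> pd.Series:
    """Two-column CSV (species, family) -> species-indexed family Series."""
    df = pd.read_csv(path)
    if not {"species", "family"} <= set(df.columns):
        raise ValueError("taxonomy CSV needs columns: species, family")
    return df.set_index("species")["family"]


# -- preparation ------------------------------------------------------------


def prepare_dataset(
    ds: SurveyDataset,
    min_obs: int = 10,
    veg_map: Mapping[int, int] | None = None,
    common_threshold: int = 60,
):
    """Filter and standardize a survey for model fitting.

    Steps, in order: collapse vegetation categories through ``veg_map``
    (identity by default), drop species with fewer than ``min_obs`` total
    detections ("at least ``min_obs``" are retained), and standardize site
    elevation to mean 0 / sd 1 (scaler returned; an ``elev_std`` column is
    added to the site table).  Species retained with at least
    ``common_threshold`` detections are recorded as "common", the rest as
    "rare", in ``meta["abundance_class"]``.

    Returns
    -------
    (SurveyDataset, ElevationScaler, list of kept species)
    """
    sites = ds.sites.copy()
    if veg_map is not None:
        mapped = sites["vegetation"].map(lambda v: veg_map.get(int(v), None))
        if mapped.isna().any():
            missing = sorted(
                sites.loc[mapped.isna(), "vegetation"].unique().tolist()
            )
            raise KeyError(f"veg_map has no entry for categories {missing}")
        codes = mapped.astype(int)
        # re-code to dense 0..V'-1 preserving order of first appearance
        uniq = sorted(codes.unique())
        sites["vegetation"] = codes.map({u: i for i, u in enumerate(uniq)})

    totals = ds.counts.sum(axis=(0, 2))
    keep = totals >= min_obs
    if not keep.any():
        raise ValueError(f"no species has >= {min_obs} detections")
    kept_species = [sp for sp, k in zip(ds.species, keep) if k]
    counts = ds.counts[:, keep, :]

    scaler = ElevationScaler.fit(sites["elevation_m"])
    sites["elev_std"] = scaler.transform(sites["elevation_m"])

    kept_totals = totals[keep]
    abundance_class = {
        sp: ("common" if t >= common_threshold else "rare")
        for sp, t in zip(kept_species, kept_totals)
    }
    meta = dict(ds.meta)
    meta["abundance_class"] = abundance_class
    meta["min_obs"] = int(min_obs)

    out = SurveyDataset(
        sites=sites, species=kept_species, counts=counts,
        breaks=ds.breaks, w=ds.w, truth=ds.truth, meta=meta,
    )
    return out, scaler, kept_species
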