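"""Occurrence preparation: range polygons to cell-centre points, habitat and
elevation filtering, spatial thinning, study-area delimitation, covariate
extraction and the historical temperature adjustment.

Current occurrences are derived from expert range polygons as one point per
grid cell whose centre falls inside the polygon.  Historical records (here,
records of extirpated populations, identifiable only to genus) are kept as
given: habitat filters based on present-day tree cover or human pressure are
meaningless for centuries-old records and are bypassed for them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

from .grids import GridGeometry, GridStack, TEMPERATURE_VARIABLES

__all__ = [
    "SpeciesProfile",
    "FilterConfig",
    "OccurrenceSet",
    "polygons_to_cell_centres",
    "apply_occurrence_filters",
    "thin_occurrences",
    "define_study_area",
    "extract_covariates",
    "adjust_temperatures",
    "load_polygons",
    "SPECIES_ELEVATION_RANGES",
]

GENUS = "genus"

#: known elevation ranges (m) of the five snub-nosed monkey species
SPECIES_ELEVATION_RANGES = {
    "R. avunculus": (200.0, 1200.0),
    "R. brelichi": (570.0, 2300.0),
    "R. roxellana": (1400.0, 2800.0),
    "R. strykeri": (1720.0, 3190.0),
    "R. bieti": (3000.0, 4700.0),
}

_CORE_COLUMNS = ["species", "x", "y", "period"]


@dataclass(frozen=True)
class SpeciesProfile:
    """Elevation limits (m) used to refine a species' range estimate."""

    name: str
    elev_min: float
    elev_max: float

    def __post_init__(self) -> None:
        if not self.elev_min < self.elev_max:
            raise ValueError(f"{self.name}: elev_min must be below elev_max")


def default_profiles() -> dict[str, SpeciesProfile]:
    return {
        name: SpeciesProfile(name, lo, hi)
        for name, (lo, hi) in SPECIES_ELEVATION_RANGES.items()
    }


@dataclass(frozen=True)
class FilterConfig:
    """Habitat/pressure thresholds; values exactly at a threshold are kept
    (the exclusion rules are strictly 'below'/'above')."""

    treecov_min: float = 50.0
    popdens_max: float = 100.0
    hii_max: float = 20.0

    def __post_init__(self) -> None:
        for v in (self.treecov_min, self.popdens_max, self.hii_max):
            if not np.isfinite(v):
                raise ValueError("filter thresholds must be finite")


class OccurrenceSet:
    """Georeferenced occurrence records with optional extracted covariates.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``species, x, y, period`` plus one column per extracted covariate and,
    after extraction, a boolean ``valid`` column flagging records usable for
    modelling (inside the grid and on no-nodata cells).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        bad = set(df["period"].unique()) - {"current", "historical"}
        if bad:
            raise ValueError(f"unknown period values {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "OccurrenceSet":
        return OccurrenceSet(self.df.copy())

    def subset(self, period: str) -> "OccurrenceSet":
        return OccurrenceSet(self.df[self.df["period"] == period].copy())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in _CORE_COLUMNS + ["valid"]]

    def modelling_records(self) -> pd.DataFrame:
        """Records usable for modelling (covariates extracted, not on nodata)."""
        if "valid" not in self.df.columns:
            raise ValueError("covariates not extracted yet")
        return self.df[self.df["valid"]]

    def covariates(self, variables, period=None) -> dict[str, np.ndarray]:
        """Covariate vectors of the valid records, optionally one period only."""
        df = self.modelling_records()
        if period is not None:
            df = df[df["period"] == period]
        return {v: df[v].to_numpy(dtype=float) for v in variables}

    @classmethod
    def from_records(cls, records: list[dict]) -> "OccurrenceSet":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_polygons(path) -> dict[str, shapely.Geometry]:
    """Species range polygons from GeoJSON; the species name is taken from a
    ``species`` (or ``name``) feature property."""
    data = json.loads(Path(path).read_text())
    polys: dict[str, shapely.Geometry] = {}
    for feat in data["features"]:
        props = feat.get("properties") or {}
        name = props.get("species") or props.get("name")
        if name is None:
            raise ValueError("feature lacks a 'species' property")
        geom = _geojson_shape(feat["geometry"])
        polys[name] = geom if name not in polys else polys[name].union(geom)
    return polys


def polygons_to_cell_centres(
    polygons: dict[str, shapely.Geometry], geometry: GridGeometry
) -> OccurrenceSet:
    """One current-period record per grid cell whose centre lies inside the
    species' range polygon."""
    if not polygons:
        raise ValueError("no polygons given")
    xs, ys = geometry.cell_centres()
    frames = []
    for species, geom in polygons.items():
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid or empty polygon for {species!r}")
        inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel())
        if not inside.any():
            warnings.warn(f"range polygon for {species!r} covers no cell centre")
            continue
        frames.append(
            pd.DataFrame(
                {
                    "species": species,
                    "x": xs.ravel()[inside],
                    "y": ys.ravel()[inside],
                    "period": "current",
                }
            )
        )
    if not frames:
        return OccurrenceSet(pd.DataFrame(columns=_CORE_COLUMNS))
    return OccurrenceSet(pd.concat(frames, ignore_index=True))


def extract_covariates(occ: OccurrenceSet, stack: GridStack) -> OccurrenceSet:
    """Annotate every record with the layer values of its containing cell.

    Records outside the grid raise; records falling on a nodata cell in any
    layer are kept but flagged ``valid = False`` and excluded from modelling.
    """
    df = occ.df.copy()
    geom = stack.geometry
    inside = geom.contains(df["x"].to_numpy(), df["y"].to_numpy())
    if not inside.all():
        bad = df.index[~inside].tolist()
        raise ValueError(f"records outside the grid at rows {bad}")
    rows, cols = geom.index_of(df["x"].to_numpy(), df["y"].to_numpy())
    valid = np.ones(len(df), dtype=bool)
    for name, layer in stack.layers.items():
        vals = layer[rows, cols]
        df[name] = vals
        valid &= np.isfinite(vals)
    df["valid"] = valid
    return OccurrenceSet(df)


def apply_occurrence_filters(
    occ: OccurrenceSet,
    stack: GridStack | None,
    profiles: dict[str, SpeciesProfile],
    cfg: FilterConfig = FilterConfig(),
) -> OccurrenceSet:
    """Drop current records outside the species' elevation range or in
    low-tree-cover / high-human-pressure cells; historical records bypass
    every filter (their habitat context centuries ago is unknown).

    ``stack`` may be None if ELEV, TREECOV, POPDENS and HII were already
    extracted onto the records.
    """
    needed = ["ELEV", "TREECOV", "POPDENS", "HII"]
    if any(c not in occ.df.columns for c in needed):
        if stack is None:
            raise ValueError("covariates not extracted and no stack given")
        occ = extract_covariates(occ, stack)
    df = occ.df
    cur = df["period"] == "current"
    for sp in df.loc[cur, "species"].unique():
        if sp not in profiles:
            raise KeyError(f"no species profile for {sp!r}")
    lo = df["species"].map(lambda s: profiles[s].elev_min if s in profiles else -np.inf)
    hi = df["species"].map(lambda s: profiles[s].elev_max if s in profiles else np.inf)
    keep = (
        (df["ELEV"] >= lo)
        & (df["ELEV"] <= hi)
        & (df["TREECOV"] >= cfg.treecov_min)   # "below 50%" excluded, 50 kept
        & (df["POPDENS"] <= cfg.popdens_max)   # "above 100" excluded, 100 kept
        & (df["HII"] <= cfg.hii_max)           # "above 20" excluded, 20 kept
    )
    return OccurrenceSet(df[keep | ~cur].copy())


def _kernel_density(xy: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel density of each point given the others (self excluded)."""
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2.0 * bandwidth**2))
    np.fill_diagonal(k, 0.0)
    return k.sum(1)


def thin_occurrences(
    occ: OccurrenceSet,
    *,
    min_dist: float | None = None,
    target_n: int | None = None,
    seed: int = 0,
    bandwidth: float | None = None,
) -> OccurrenceSet:
    """Reduce spatial sampling bias by removing locally dense records.

    Exactly one of ``min_dist`` (km) or ``target_n`` must be given.  The
    record with the highest Gaussian-kernel local density is removed first
    (ties broken by a seeded random draw), iterating until either no retained
    pair is closer than ``min_dist`` or exactly ``target_n`` records remain.
    Deterministic for a fixed seed.
    """
    if (min_dist is None) == (target_n is None):
        raise ValueError("give exactly one of min_dist or target_n")
    n = len(occ)
    if target_n is not None and target_n > n:
        raise ValueError(f"target_n={target_n} exceeds the {n} records")
    rng = np.random.default_rng(seed)
    df = occ.df
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if bandwidth is None:
        bandwidth = 10.0  # km; ~2 cells at the 5-km analysis resolution
    alive = np.ones(n, dtype=bool)

    def drop_densest(candidates: np.ndarray) -> None:
        dens = _kernel_density(xy[alive], bandwidth)
        dens_full = np.full(n, -np.inf)
        dens_full[alive] = dens
        dens_full[~candidates] = -np.inf
        best = np.flatnonzero(dens_full == dens_full.max())
        alive[rng.choice(best)] = False

    if target_n is not None:
        while alive.sum() > target_n:
            drop_densest(alive.copy())
    else:
        if min_dist > 0:
            while True:
                pts = xy[alive]
                d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                close = (d < min_dist).any(1)
                if not close.any():
                    break
                cand = np.zeros(n, dtype=bool)
                cand[np.flatnonzero(alive)[close]] = True
                drop_densest(cand)
    return OccurrenceSet(df[alive].copy())


def define_study_area(
    ranges: list[shapely.Geometry] | None,
    points: OccurrenceSet | None,
    buffer: float,
) -> tuple[float, float, float, float]:
    """Axis-aligned rectangle enclosing ranges and points with a buffer (km).

    Returns ``(xmin, ymin, xmax, ymax)`` in projected km.
    """
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    boxes = []
    for g in ranges or []:
        boxes.append(g.bounds)
    if points is not None and len(points):
        boxes.append(
            (points.df["x"].min(), points.df["y"].min(),
             points.df["x"].max(), points.df["y"].max())
        )
    if not boxes:
        raise ValueError("no ranges or points to delimit a study area")
    boxes = np.array(boxes)
    return (
        float(boxes[:, 0].min() - buffer),
        float(boxes[:, 1].min() - buffer),
        float(boxes[:, 2].max() + buffer),
        float(boxes[:, 3].max() + buffer),
    )


def adjust_temperatures(occ: OccurrenceSet, delta: float) -> OccurrenceSet:
    """Subtract ``delta`` °C from the temperature covariates of the
    *historical* records only.

    The adjustment compensates for the cooler climate of the period the
    historical records represent; current records and all precipitation
    variables are untouched, and prediction rasters are never adjusted.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    out = occ.copy()
    hist = out.df["period"] == "historical"
    for var in TEMPERATURE_VARIABLES:
        if var in out.df.columns:
            out.df.loc[hist, var] = out.df.loc[hist, var] - delta
    return out
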