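"""Occurrence records: parsing, spatial rarefaction, presence/background design.

Occurrence portals over-sample accessible places; spatial rarefaction thins
records so that no two retained points lie closer than a minimum great-circle
distance (10 km by default), reducing spatial autocorrelation before
presence–background modelling. Thinning is greedy and deterministic (records
visited sorted by longitude then latitude) unless a seed is supplied, in which
case the visit order is shuffled — emulating stochastic thinning toolboxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterStack, extract_at_points, haversine_km


@dataclass
class OccurrenceSet:
    """Presence coordinates plus a provenance tag per record."""

    presences: pd.DataFrame                  # columns lon, lat
    provenance: list[str] = field(default_factory=list)
    thinning_radius_km: float | None = None
    n_dropped_parse: int = 0

    def __len__(self) -> int:
        return len(self.presences)

    @property
    def lons(self) -> np.ndarray:
        return self.presences["lon"].to_numpy()

    @property
    def lats(self) -> np.ndarray:
        return self.presences["lat"].to_numpy()


@dataclass
class DesignTable:
    """Presence (label 1) and background (label 0) rows with extracted
    variable values; rows with any missing extraction have been dropped."""

    table: pd.DataFrame                      # columns: label, lon, lat, <vars>
    variables: list[str]
    background_n: int
    n_dropped_presence: int = 0
    n_dropped_background: int = 0

    @property
    def presence(self) -> pd.DataFrame:
        return self.table[self.table["label"] == 1]

    @property
    def background(self) -> pd.DataFrame:
        return self.table[self.table["label"] == 0]


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV of occurrence records (columns lon, lat; species optional).

    Rows whose coordinates do not parse as finite numbers are dropped and
    counted in ``n_dropped_parse``.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing required columns: "
                         f"{sorted(missing)}")
    if len(df) == 0:
        raise ValueError("no records in occurrence file")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    good = np.isfinite(lon) & np.isfinite(lat)
    n_dropped = int((~good).sum())
    if good.sum() == 0:
        raise ValueError("no records with parseable coordinates")
    out = pd.DataFrame({"lon": lon[good].to_numpy(), "lat": lat[good].to_numpy()})
    prov = (df.loc[good, "species"].astype(str).tolist()
            if "species" in df.columns else [""] * len(out))
    return OccurrenceSet(out, provenance=prov, n_dropped_parse=n_dropped)


def rarefy(occ: OccurrenceSet, radius_km: float = 10.0,
           seed: int | None = None) -> OccurrenceSet:
    """Greedy spatial thinning: keep a record iff it lies at least
    ``radius_km`` (haversine) from every already-kept record.

    Deterministic visit order (lon, then lat) by default; pass ``seed`` for a
    seeded shuffled order. Idempotent: thinning an already-thinned set keeps
    every record.
    """
    if len(occ) == 0:
        raise ValueError("cannot rarefy an empty occurrence set")
    df = occ.presences.reset_index(drop=True)
    order = np.lexsort((df["lat"].to_numpy(), df["lon"].to_numpy()))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(df))
    kept: list[int] = []
    kept_lon = np.empty(len(df))
    kept_lat = np.empty(len(df))
    for i in order:
        lon, lat = df.at[i, "lon"], df.at[i, "lat"]
        if kept:
            d = haversine_km(lon, lat, kept_lon[:len(kept)], kept_lat[:len(kept)])
            if np.min(d) < radius_km:
                continue
        kept_lon[len(kept)] = lon
        kept_lat[len(kept)] = lat
        kept.append(i)
    kept_sorted = sorted(kept)
    prov = [occ.provenance[i] for i in kept_sorted] if occ.provenance else []
    return OccurrenceSet(df.loc[kept_sorted].reset_index(drop=True),
                         provenance=prov, thinning_radius_km=radius_km)


def assemble_design(occ: OccurrenceSet, stack: RasterStack,
                    background_n: int = 10000, seed: int | None = None,
                    exclude_presence_cells: bool = False) -> DesignTable:
    """Extract variables at presences and at a uniform background sample.

    Background cells are drawn uniformly without replacement from the
    non-nodata cells (all of them if fewer than ``background_n``). Presence
    rows falling outside the grid or on nodata cells are dropped and counted.
    Duplicate presence cells are collapsed to one record.
    """
    if background_n < 1:
        raise ValueError("background_n must be >= 1")
    pres = extract_at_points(stack, occ.lons, occ.lats)
    # collapse duplicate cells (standard "remove duplicate records")
    pres = pres.drop_duplicates(subset=["row", "col"])
    ok = pres[stack.codes].notna().all(axis=1) & (pres["row"] >= 0)
    n_dropped_presence = int((~ok).sum())
    pres = pres[ok]
    if len(pres) == 0:
        raise ValueError("no presence records survive extraction")

    rng = np.random.default_rng(seed)
    valid = stack.valid_mask()
    if exclude_presence_cells:
        valid = valid.copy()
        valid[pres["row"].to_numpy(), pres["col"].to_numpy()] = False
    pool = np.flatnonzero(valid.ravel())
    n_bg = min(background_n, len(pool))
    chosen = np.sort(rng.choice(pool, size=n_bg, replace=False))
    rows, cols = np.unravel_index(chosen, valid.shape)
    lons, lats = stack.spec.cell_centers()
    bg = pd.DataFrame({"lon": lons[cols], "lat": lats[rows]})
    for code, grid in stack.layers.items():
        bg[code] = grid.values[rows, cols]
    bg_ok = bg[stack.codes].notna().all(axis=1)
    n_dropped_background = int((~bg_ok).sum())
    bg = bg[bg_ok]

    pres_out = pres[["lon", "lat"] + stack.codes].copy()
    pres_out.insert(0, "label", 1)
    bg.insert(0, "label", 0)
    table = pd.concat([pres_out, bg], ignore_index=True)
    if len(table[table["label"] == 1]) < 2:
        warnings.warn("fewer than 2 presence rows in the design table")
    return DesignTable(table, variables=stack.codes, background_n=len(bg),
                       n_dropped_presence=n_dropped_presence,
                       n_dropped_background=n_dropped_background)
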