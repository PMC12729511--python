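"""Habitat classification, area accounting and centroid migration.

Suitability surfaces (cloglog p in [0, 1]) are cut into habitat classes with
fixed breaks — non-suitable [0, 0.1), low [0.1, 0.3), moderate [0.3, 0.5),
high [0.5, 1] — the classification used for the published range maps of the
study species. Areas are spherical-cell sums reported in 10^4 km^2. The mean
center of the suitable range (area-weighted, optionally suitability-weighted)
is tracked across scenario-tagged surfaces; consecutive centroid shifts are
reported as haversine distances with initial bearings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid, cell_area_rows, haversine_km


@dataclass(frozen=True)
class ZoningScheme:
    """Class names and strictly increasing break values covering [0, 1].

    ``breaks`` has one more entry than ``names``; class i is
    [breaks[i], breaks[i+1]) and the top class is closed at breaks[-1].
    """

    names: tuple[str, ...] = ("non", "low", "moderate", "high")
    breaks: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 1.0)

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.names) + 1:
            raise ValueError("need len(names) + 1 break values")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")


HABITAT_SCHEME = ZoningScheme()


@dataclass
class ZoningMap:
    """Classified raster: integer class index per cell (nodata = NaN)."""

    zones: RasterGrid
    scheme: ZoningScheme


@dataclass
class AreaReport:
    scenario_tag: str
    cell_counts: dict[str, int]
    areas_1e4_km2: dict[str, float]
    fractions: dict[str, float]

    @property
    def total_suitable_1e4_km2(self) -> float:
        """Sum of every class except the first (non-suitable) class."""
        names = list(self.areas_1e4_km2)
        return float(sum(self.areas_1e4_km2[n] for n in names[1:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(self.cell_counts),
            "cells": list(self.cell_counts.values()),
            "area_1e4_km2": list(self.areas_1e4_km2.values()),
            "fraction": list(self.fractions.values()),
        }).assign(scenario=self.scenario_tag)


@dataclass
class CentroidRecord:
    scenario_tag: str
    lon: float
    lat: float
    threshold: float
    weighting: str


def reclassify(surface: RasterGrid, scheme: ZoningScheme = HABITAT_SCHEME) -> ZoningMap:
    """Class index per cell, half-open bins with a closed top; nodata
    propagates. Values outside [breaks[0], breaks[-1]] are a contract error."""
    vals = surface.values
    finite = surface.mask
    bad = finite & ((vals < scheme.breaks[0]) | (vals > scheme.breaks[-1]))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"cell ({r}, {c}) value {vals[r, c]} outside "
                         f"[{scheme.breaks[0]}, {scheme.breaks[-1]}]")
    idx = np.digitize(vals, scheme.breaks[1:-1], right=False)
    out = np.where(finite, idx.astype(float), np.nan)
    return ZoningMap(surface.copy_with(out), scheme)


def area_report(zoning: ZoningMap, scenario_tag: str = "current") -> AreaReport:
    """Per-class cell counts, spherical areas (10^4 km^2) and cell fractions."""
    spec = zoning.zones.spec
    row_area = cell_area_rows(spec)
    zones = zoning.zones.values
    finite = zoning.zones.mask
    counts: dict[str, int] = {}
    areas: dict[str, float] = {}
    n_total = int(finite.sum())
    for i, name in enumerate(zoning.scheme.names):
        m = finite & (zones == i)
        counts[name] = int(m.sum())
        areas[name] = float((m * row_area[:, None]).sum() / 1e4)
    fractions = {n: (counts[n] / n_total if n_total else 0.0) for n in counts}
    return AreaReport(scenario_tag, counts, areas, fractions)


def mean_center(surface: RasterGrid, threshold: float = 0.1,
                weighting: str = "binary",
                scenario_tag: str = "current") -> CentroidRecord:
    """Area-weighted mean center of cells with p >= threshold.

    ``weighting="suitability"`` additionally weights each cell by its p.
    """
    if weighting not in ("binary", "suitability"):
        raise ValueError(f"unknown weighting {weighting!r}")
    spec = surface.spec
    vals = surface.values
    qual = surface.mask & (vals >= threshold)
    if not qual.any():
        raise ValueError(f"no cells at/above threshold {threshold}")
    rows, cols = np.nonzero(qual)
    lons, lats = spec.cell_centers()
    w = cell_area_rows(spec)[rows]
    if weighting == "suitability":
        w = w * vals[rows, cols]
    lon_c = float(np.average(lons[cols], weights=w))
    lat_c = float(np.average(lats[rows], weights=w))
    return CentroidRecord(scenario_tag, lon_c, lat_c, threshold, weighting)


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> float:
    """Initial great-circle bearing from point 1 to point 2, degrees from N."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sin(dl) * math.cos(p2)
    x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return (math.degrees(math.atan2(y, x)) + 360.0) % 360.0


def migration_track(centroids: list[CentroidRecord]) -> pd.DataFrame:
    """Consecutive haversine distances (km) and initial bearings between
    scenario centroids, in the given order."""
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroid records")
    rows = []
    for a, b in zip(centroids, centroids[1:]):
        rows.append({
            "from": a.scenario_tag, "to": b.scenario_tag,
            "distance_km": float(haversine_km(a.lon, a.lat, b.lon, b.lat)),
            "bearing_deg": initial_bearing_deg(a.lon, a.lat, b.lon, b.lat),
        })
    return pd.DataFrame(rows)
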