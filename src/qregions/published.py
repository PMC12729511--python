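"""Published national-scale results for Cyclocarya paliurus.

Worked-example inputs: the reported suitable-habitat centroids and per-class
areas for *C. paliurus* under two CMIP6 shared socioeconomic pathways
(SSP126, SSP585) and two periods (2050s, 2090s), as printed by the
national-scale suitability study of the species. These numbers are inputs to
the distance/area arithmetic in this package (the rasters behind them —
WorldClim climatologies, HWSD soils, portal occurrences — are not
redistributable), letting the spherical-geometry code be checked against the
published migration distances.
"""

from __future__ import annotations

import pandas as pd

# Suitable-habitat mean centers (degrees E / N) and the reported migration
# distance (km) of each step from its predecessor along the same pathway.
CENTROIDS = pd.DataFrame([
    {"scenario": "present", "period": "present", "lon": 110.65, "lat": 27.79,
     "reported_km": None},
    {"scenario": "SSP126", "period": "2050s", "lon": 109.31, "lat": 27.81,
     "reported_km": 132.57},
    {"scenario": "SSP126", "period": "2090s", "lon": 108.90, "lat": 28.00,
     "reported_km": 45.04},
    {"scenario": "SSP585", "period": "2050s", "lon": 108.23, "lat": 27.77,
     "reported_km": 238.58},
    {"scenario": "SSP585", "period": "2090s", "lon": 109.49, "lat": 27.84,
     "reported_km": 124.56},
])

# Per-class suitable areas (10^4 km^2): high / moderate / low classes and the
# reported total suitable area.
CLASS_AREAS = pd.DataFrame([
    {"period": "2050s", "scenario": "SSP126", "high": 61.21, "moderate": 62.58,
     "low": 82.88, "reported_total": 206.67},
    {"period": "2050s", "scenario": "SSP585", "high": 67.99, "moderate": 60.47,
     "low": 83.49, "reported_total": 211.94},
    {"period": "2090s", "scenario": "SSP126", "high": 74.57, "moderate": 60.38,
     "low": 88.40, "reported_total": 223.35},
    {"period": "2090s", "scenario": "SSP585", "high": 46.13, "moderate": 69.15,
     "low": 79.50, "reported_total": 194.77},
])

# Reported fraction of the region that is suitable under SSP585: near-term
# (2050s) and end-of-century (2090s), in percent of the study region.
SSP585_SUITABLE_PERCENT = {"2050s": 22.05, "2090s": 20.27}

# Reported cross-validated AUC of the ecological model (10-fold mean).
REPORTED_AUC = 0.907


def centroid_track(scenario: str) -> pd.DataFrame:
    """Present-day centroid followed by the given pathway's period centroids,
    ready for :func:`qregions.habitat.migration_track`."""
    rows = CENTROIDS[(CENTROIDS["scenario"] == "present")
                     | (CENTROIDS["scenario"] == scenario)]
    return rows.reset_index(drop=True)
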