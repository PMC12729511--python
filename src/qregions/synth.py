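"""Synthetic landscapes with known truth.

Real analyses of this kind rest on bioclimatic rasters (Bio1–Bio19), soil and
topography layers, portal occurrence records, and a small table of
literature-compiled compound concentrations. None of those are reproducible
from an accession number, so this module generates landscapes that carry the
same *statistical* structure the analysis assumes:

* environmental layers = deterministic lon/lat gradient + stationary Gaussian
  random field with a named variogram (spherical/exponential/gaussian),
  realized by circulant embedding on the cell lattice (ranges in cell units);
* a known true suitability law: logistic transform of a linear predictor in
  the layers (linear and squared terms allowed);
* presence records drawn cell-wise with probability proportional to the true
  suitability, without replacement;
* compound concentration surfaces linearly coupled to two named covariates
  (a "Bio18-like" precipitation gradient and an "aspect-like" layer by
  default) plus a spatially correlated residual, sampled at a small number of
  sites with nugget noise — emulating a literature-compiled assay table.

Everything is deterministic under (scenario, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import GridSpec, RasterGrid, RasterStack, write_raster


@dataclass(frozen=True)
class EnvLayerDef:
    """Recipe for one synthetic environmental layer.

    ``gradient`` = (intercept, per-degree-lon slope, per-degree-lat slope);
    the random-field ``range_cells`` is in cell units. ``share_field_of``
    reuses another layer's random field (scaled by ``share_weight``) before
    adding this layer's own field — the mechanism for building collinear
    nuisance variables.
    """

    code: str
    family: str = "exponential"
    sill: float = 1.0
    range_cells: float = 10.0
    nugget: float = 0.0
    gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)
    share_field_of: str | None = None
    share_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sill < 0 or self.nugget < 0 or self.range_cells <= 0:
            raise ValueError(f"layer {self.code}: sill/nugget must be >= 0, "
                             "range > 0")
        if self.family not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"layer {self.code}: unknown family {self.family}")


@dataclass(frozen=True)
class CompoundDef:
    """Concentration law: intercept + b1*cov1 + b2*cov2 + GRF residual,
    truncated at zero. Nugget noise is added to the sampled table only."""

    name: str
    intercept: float
    beta1: float
    beta2: float
    residual_sill: float = 0.1
    residual_range_cells: float = 15.0
    nugget: float = 0.05
    family: str = "exponential"


@dataclass
class SyntheticScenario:
    """Full recipe for a synthetic study region.

    Defaults mirror the study's dimensions at desk scale: a 120x120 grid of
    0.05-degree cells over a subtropical-China-like extent, 8 environmental
    layers (5 informative, 3 mutually collinear nuisance layers with pairwise
    correlation >= 0.9), 170 presence records and 26 compound sites.
    """

    spec: GridSpec = field(default_factory=lambda: GridSpec(
        n_rows=120, n_cols=120, x_min=106.0, y_max=31.0, dx=0.05, dy=0.05))
    env_defs: list[EnvLayerDef] = field(default_factory=lambda: _default_env_defs())
    truth_coeffs: dict[str, float] = field(default_factory=lambda: dict(_TRUTH_COEFFS))
    occurrence_n: int = 170
    compound_defs: list[CompoundDef] = field(default_factory=lambda: list(_COMPOUND_DEFS))
    sample_n: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occurrence_n < 10:
            raise ValueError("occurrence_n must be >= 10")
        if self.sample_n < 4:
            raise ValueError("sample_n must be >= 4")


# Default layers. cov1 emulates a warm-quarter precipitation gradient rising
# northward; cov2 emulates an aspect-like layer rising eastward — together
# they plant the favourable corner in the northeast quadrant. env3..5 are
# informative fields (env3 enters the truth quadratically); noise1..3 are
# copies of one shared field plus small independent noise (pairwise r ~ 0.93).
def _default_env_defs() -> list[EnvLayerDef]:
    return [
        EnvLayerDef("cov1", "exponential", sill=0.35, range_cells=12.0,
                    gradient=(0.0, 0.08, 0.65)),
        EnvLayerDef("cov2", "exponential", sill=0.35, range_cells=12.0,
                    gradient=(0.0, 0.65, 0.08)),
        EnvLayerDef("env3", "spherical", sill=1.0, range_cells=18.0),
        EnvLayerDef("env4", "exponential", sill=1.0, range_cells=10.0),
        EnvLayerDef("env5", "gaussian", sill=1.0, range_cells=14.0),
        EnvLayerDef("noise1", "exponential", sill=1.0, range_cells=10.0),
        EnvLayerDef("noise2", "exponential", sill=0.08, range_cells=5.0,
                    share_field_of="noise1"),
        EnvLayerDef("noise3", "exponential", sill=0.08, range_cells=5.0,
                    share_field_of="noise1"),
    ]


# True suitability law: strong positive response to the two gradient
# covariates (so suitability peaks in the northeast quadrant), a quadratic
# optimum in env3, weak linear effects of env4/env5, and no response at all
# to the nuisance trio.
_TRUTH_COEFFS: dict[str, float] = {
    "intercept": -9.0,
    "cov1": 5.0,
    "cov2": 5.0,
    "env3": 0.8,
    "env3^2": -1.1,
    "env4": 0.6,
    "env5": 0.45,
}

# Compound couplings sized so that the sampled Spearman correlation with each
# covariate is ~0.6 at 26 sites — the magnitude of the stronger published
# flavonoid–environment associations — giving the screen realistic power.
_COMPOUND_DEFS: list[CompoundDef] = [
    CompoundDef("quercetin", intercept=2.0, beta1=1.4, beta2=1.4,
                residual_sill=0.35, residual_range_cells=15.0, nugget=0.10),
    CompoundDef("kaempferol", intercept=3.0, beta1=1.5, beta2=1.4,
                residual_sill=0.45, residual_range_cells=15.0, nugget=0.12),
]


@dataclass
class TruthBundle:
    """Everything a downstream stage may be tested against."""

    scenario: SyntheticScenario
    env: RasterStack
    true_suitability: RasterGrid
    presences: pd.DataFrame            # columns lon, lat
    compound_truth: dict[str, RasterGrid]
    compound_samples: pd.DataFrame     # lon, lat, <compound columns>


# ---------------------------------------------------------------------------
# Gaussian random fields by circulant embedding

def correlogram(family: str, h: np.ndarray, range_: float) -> np.ndarray:
    """Correlation function rho(h) = 1 - gamma(h)/sill for unit sill."""
    from .geostat import variogram_shape
    return 1.0 - variogram_shape(family, np.asarray(h, dtype=float), range_)


def gaussian_random_field(n_rows: int, n_cols: int, family: str, sill: float,
                          range_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean GRF on the cell lattice via circulant embedding.

    The covariance is embedded on a torus of at least twice the grid size
    (and >= 4 ranges), where the 2-D FFT diagonalizes it exactly; small
    negative eigenvalues from imperfect embedding are clipped.
    """
    if sill == 0:
        return np.zeros((n_rows, n_cols))
    m_r = int(2 ** np.ceil(np.log2(max(2 * n_rows, 4 * range_cells, 8))))
    m_c = int(2 ** np.ceil(np.log2(max(2 * n_cols, 4 * range_cells, 8))))
    ir = np.minimum(np.arange(m_r), m_r - np.arange(m_r))
    ic = np.minimum(np.arange(m_c), m_c - np.arange(m_c))
    h = np.hypot(ir[:, None], ic[None, :])
    cov = sill * correlogram(family, h, range_cells)
    eig = np.fft.fft2(cov).real
    neg = eig.min()
    if neg < -1e-6 * sill * m_r * m_c:
        raise RuntimeError(
            f"circulant embedding not positive definite for family={family}, "
            f"range={range_cells} (min eigenvalue {neg:.3g})")
    eig = np.clip(eig, 0.0, None)
    noise = rng.standard_normal((m_r, m_c)) + 1j * rng.standard_normal((m_r, m_c))
    fld = np.fft.fft2(np.sqrt(eig / (m_r * m_c)) * noise)
    return fld.real[:n_rows, :n_cols]


# ---------------------------------------------------------------------------
# Generation operations

def gen_env_stack(scenario: SyntheticScenario,
                  rng: np.random.Generator | None = None) -> RasterStack:
    """Realize the environmental layers of a scenario.

    Each layer is its deterministic gradient plus a stationary GRF (plus, for
    nuisance layers, a shared parent field), with optional iid nugget noise.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    spec = scenario.spec
    lons, lats = spec.cell_centers()
    lon_g, lat_g = np.meshgrid(lons, lats)
    lon0, lat0 = lons.mean(), lats.mean()
    fields: dict[str, np.ndarray] = {}
    layers: dict[str, RasterGrid] = {}
    for d in scenario.env_defs:
        try:
            fld = gaussian_random_field(spec.n_rows, spec.n_cols, d.family,
                                        d.sill, d.range_cells, rng)
        except RuntimeError as exc:
            raise RuntimeError(f"layer {d.code}: {exc}") from exc
        fields[d.code] = fld
        a0, ax, ay = d.gradient
        vals = a0 + ax * (lon_g - lon0) + ay * (lat_g - lat0) + fld
        if d.share_field_of is not None:
            if d.share_field_of not in fields:
                raise ValueError(f"layer {d.code} shares field of undefined "
                                 f"layer {d.share_field_of}")
            vals = vals + d.share_weight * fields[d.share_field_of]
        if d.nugget > 0:
            vals = vals + rng.normal(0.0, np.sqrt(d.nugget), vals.shape)
        layers[d.code] = RasterGrid(spec, vals)
    return RasterStack(layers)


def gen_true_suitability(env: RasterStack, truth_coeffs: dict[str, float]) -> RasterGrid:
    """Logistic transform of a linear predictor in the layers.

    Keys are layer codes for linear terms, ``code^2`` for squared terms, and
    ``intercept``. Values lie strictly in (0, 1); all-zero coefficients give
    the constant 0.5 surface.
    """
    spec = env.spec
    eta = np.full((spec.n_rows, spec.n_cols), float(truth_coeffs.get("intercept", 0.0)))
    for key, coef in truth_coeffs.items():
        if key == "intercept":
            continue
        code, power = (key[:-2], 2) if key.endswith("^2") else (key, 1)
        if code not in env.layers:
            raise KeyError(f"truth coefficient references unknown layer {code!r}")
        eta = eta + coef * env.layers[code].values ** power
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~env.valid_mask()] = np.nan
    return RasterGrid(spec, suit)


def sample_occurrences(truth: RasterGrid, n: int,
                       rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw presence cells without replacement, probability proportional to
    the true suitability; returns cell-center coordinates."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    vals = truth.values.ravel()
    ok = np.isfinite(vals) & (vals > 0)
    if n == 0:
        return pd.DataFrame(columns=["lon", "lat"])
    idx_pool = np.flatnonzero(ok)
    if len(idx_pool) < n:
        import warnings
        warnings.warn(f"only {len(idx_pool)} cells have positive suitability; "
                      f"returning all of them instead of {n}")
        n = len(idx_pool)
    p = vals[idx_pool] / vals[idx_pool].sum()
    chosen = rng.choice(idx_pool, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, truth.values.shape)
    lons, lats = truth.spec.cell_centers()
    return pd.DataFrame({"lon": lons[cols], "lat": lats[rows]})


def gen_compound_samples(scenario: SyntheticScenario, env: RasterStack,
                         rng: np.random.Generator | None = None,
                         covariates: tuple[str, str] = ("cov1", "cov2"),
                         ) -> tuple[dict[str, RasterGrid], pd.DataFrame]:
    """Concentration truth surfaces and a sampled assay table.

    Surface = intercept + beta1*cov1 + beta2*cov2 + correlated residual,
    truncated at zero (concentrations are nonnegative). The table holds
    ``sample_n`` random non-nodata sites with added nugget noise.
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    spec = scenario.spec
    for c in covariates:
        if c not in env.layers:
            raise KeyError(f"covariate layer {c!r} not in stack")
    cov1 = env.layers[covariates[0]].values
    cov2 = env.layers[covariates[1]].values
    truths: dict[str, RasterGrid] = {}
    surfaces: dict[str, np.ndarray] = {}
    for d in scenario.compound_defs:
        resid = gaussian_random_field(spec.n_rows, spec.n_cols, d.family,
                                      d.residual_sill, d.residual_range_cells, rng)
        surf = np.clip(d.intercept + d.beta1 * cov1 + d.beta2 * cov2 + resid, 0.0, None)
        surf[~env.valid_mask()] = np.nan
        surfaces[d.name] = surf
        truths[d.name] = RasterGrid(spec, surf)

    valid = np.flatnonzero(env.valid_mask().ravel())
    sites = rng.choice(valid, size=min(scenario.sample_n, len(valid)), replace=False)
    rows, cols = np.unravel_index(sites, (spec.n_rows, spec.n_cols))
    lons, lats = spec.cell_centers()
    table = pd.DataFrame({"lon": lons[cols], "lat": lats[rows]})
    for d in scenario.compound_defs:
        obs = surfaces[d.name][rows, cols]
        if d.nugget > 0:
            obs = obs + rng.normal(0.0, np.sqrt(d.nugget), len(obs))
        table[d.name] = np.clip(obs, 0.0, None)
    return truths, table


def generate_bundle(scenario: SyntheticScenario) -> TruthBundle:
    """Run the whole generator under the scenario's seed."""
    root = np.random.SeedSequence(scenario.seed)
    s_env, s_occ, s_comp = (np.random.default_rng(s) for s in root.spawn(3))
    env = gen_env_stack(scenario, s_env)
    truth = gen_true_suitability(env, scenario.truth_coeffs)
    presences = sample_occurrences(truth, scenario.occurrence_n, s_occ)
    comp_truth, samples = gen_compound_samples(scenario, env, s_comp)
    return TruthBundle(scenario, env, truth, presences, comp_truth, samples)


def write_scenario_bundle(bundle: TruthBundle, directory: str | Path) -> dict:
    """Serialize a bundle (rasters as .asc, tables as CSV, truth metadata as
    JSON) and return a manifest of the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # manifest paths are relative to the bundle directory, so a bundle is
    # byte-identical wherever it is written
    manifest: dict[str, object] = {"layers": {}, "compound_truth": {}}
    for code, grid in bundle.env.layers.items():
        p = directory / f"env_{code}.asc"
        write_raster(grid, p)
        manifest["layers"][code] = p.name
    p = directory / "true_suitability.asc"
    write_raster(bundle.true_suitability, p)
    manifest["true_suitability"] = p.name
    for name, grid in bundle.compound_truth.items():
        p = directory / f"truth_{name}.asc"
        write_raster(grid, p)
        manifest["compound_truth"][name] = p.name
    p = directory / "presences.csv"
    bundle.presences.to_csv(p, index=False)
    manifest["presences"] = p.name
    p = directory / "compound_samples.csv"
    bundle.compound_samples.to_csv(p, index=False)
    manifest["compound_samples"] = p.name
    meta = {
        "seed": bundle.scenario.seed,
        "occurrence_n": bundle.scenario.occurrence_n,
        "sample_n": bundle.scenario.sample_n,
        "truth_coeffs": bundle.scenario.truth_coeffs,
        "env_defs": [vars(d) | {"gradient": list(d.gradient)}
                     for d in bundle.scenario.env_defs],
        "compound_defs": [vars(d) for d in bundle.scenario.compound_defs],
    }
    p = directory / "scenario.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=2)
    manifest["metadata"] = p.name
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
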