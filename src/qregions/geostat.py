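"""Quality-suitability engine: Spearman screening, variography, ordinary
(co-)kriging and leave-one-out validation.

Compound concentrations measured at a handful of sites are related to
environmental variables by a rank (Spearman) screen, then mapped to the full
grid by ordinary co-kriging under a linear model of coregionalization (LMC):
every direct and cross variogram is a combination of a shared nugget and one
shared structure,

    gamma_ij(h) = B0_ij + B1_ij * g(h; a),

with a common family and range and positive semi-definite coefficient
matrices B0, B1 (enforced by eigenvalue clipping). Distances are great-circle
kilometres, so variogram ranges are in km.

The kriging systems use covariances C_ij(h) = B0_ij*delta(h) + B1_ij*rho(h),
rho = 1 - g, with ordinary-kriging unbiasedness constraints: the primary
variable's weights sum to one, each secondary's to zero. With no secondaries
this is exactly ordinary kriging, an exact interpolator when the nugget is
zero. Leave-one-out validation refits nothing: it re-solves the weights with
the held-out primary datum removed (the variogram stays fixed) and reports
the mean error, RMSE and the standardized RMSE (root mean square of error /
kriging SE — close to 1 when the uncertainty model is well calibrated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, nnls

from .raster import GridSpec, RasterGrid, haversine_km

_FAMILIES = ("spherical", "exponential", "gaussian")


def variogram_shape(family: str, h, a: float) -> np.ndarray:
    """Unit-sill variogram g(h; a) with practical range a."""
    h = np.asarray(h, dtype=float) / a
    if family == "spherical":
        return np.where(h >= 1.0, 1.0, 1.5 * h - 0.5 * h ** 3)
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * h)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * h ** 2)
    raise ValueError(f"unknown variogram family {family!r}")


@dataclass(frozen=True)
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("nugget/sill must be >= 0 and range > 0")

    def __call__(self, h) -> np.ndarray:
        """gamma(h); gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * variogram_shape(
            self.family, h, self.range_km)
        return np.where(h <= 0, 0.0, g)

    def covariance(self, h) -> np.ndarray:
        """C(h) = nugget*delta(h) + partial_sill*(1 - g(h))."""
        h = np.asarray(h, dtype=float)
        c = self.partial_sill * (1.0 - variogram_shape(self.family, h,
                                                       self.range_km))
        return c + np.where(h <= 1e-9, self.nugget, 0.0)


# ---------------------------------------------------------------------------
# Spearman screen

@dataclass
class CorrelationScreen:
    table: pd.DataFrame            # compound, variable, rho, p
    alpha: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def selected(self, compound: str) -> list[str]:
        t = self.table
        m = (t["compound"] == compound) & (t["p"] < self.alpha)
        return t.loc[m, "variable"].tolist()


def spearman_screen(samples: pd.DataFrame, compounds: list[str],
                    variables: list[str], alpha: float = 0.05) -> CorrelationScreen:
    """Tie-corrected Spearman rho with two-sided t-approximation p-values for
    every (compound, variable) pair; constant vectors are skipped."""
    rows = []
    skipped = []
    for comp in compounds:
        z = samples[comp].to_numpy(dtype=float)
        if len(z) < 4:
            raise ValueError("need at least 4 paired observations")
        for v in variables:
            x = samples[v].to_numpy(dtype=float)
            if np.std(z) == 0 or np.std(x) == 0:
                skipped.append((comp, v))
                continue
            rho, p = stats.spearmanr(z, x)
            rows.append({"compound": comp, "variable": v,
                         "rho": float(rho), "p": float(p)})
    if skipped:
        warnings.warn(f"constant vectors skipped in Spearman screen: {skipped}")
    return CorrelationScreen(pd.DataFrame(rows), alpha=alpha, skipped=skipped)


# ---------------------------------------------------------------------------
# Empirical variography

def empirical_variogram(lons, lats, values, values2=None, n_lags: int = 12,
                        max_dist: float | None = None) -> pd.DataFrame:
    """Binned empirical (cross-)semivariogram.

    gamma_hat(bin) = sum (z_i - z_j)(w_i - w_j) / (2 N_bin) over site pairs
    with haversine separation inside the bin (w = z for a direct variogram).
    Returns columns h (bin mean distance), gamma, n_pairs; empty bins are
    dropped. Default max_dist is half the maximum pairwise distance.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    z = np.asarray(values, dtype=float)
    w = z if values2 is None else np.asarray(values2, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 sites")
    iu, ju = np.triu_indices(n, k=1)
    d = np.asarray(haversine_km(lons[iu], lats[iu], lons[ju], lats[ju]))
    cross = (z[iu] - z[ju]) * (w[iu] - w[ju]) / 2.0
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.digitize(d, edges[1:], right=True)
    rows = []
    for b in range(n_lags):
        m = (which == b) & (d <= max_dist)
        if m.sum() == 0:
            continue
        rows.append({"h": float(d[m].mean()), "gamma": float(cross[m].mean()),
                     "n_pairs": int(m.sum())})
    return pd.DataFrame(rows)


def fit_variogram(empirical: pd.DataFrame, family: str = "spherical",
                  ) -> VariogramModel:
    """Weighted least-squares fit (weights N_bin / h^2) of (nugget, partial
    sill, range) with nonnegativity constraints.

    Multiple range starts guard against local minima. If the empirical values
    are all ~0 a nugget-only model is returned with a warning.
    """
    if len(empirical) < 3:
        raise ValueError("need at least 3 nonempty bins to fit a variogram")
    h = empirical["h"].to_numpy(dtype=float)
    g = empirical["gamma"].to_numpy(dtype=float)
    npairs = empirical["n_pairs"].to_numpy(dtype=float)
    if np.allclose(g, 0.0, atol=1e-12):
        warnings.warn("degenerate empirical variogram (all ~0); returning a "
                      "nugget-only model")
        return VariogramModel(family, 0.0, 0.0, float(h.max()))
    wsqrt = np.sqrt(npairs) / np.maximum(h, 1e-9)

    def resid(theta):
        c0, c, a = theta
        return wsqrt * (c0 + c * variogram_shape(family, h, a) - g)

    best = None
    g_max = float(g.max())
    for a0 in (h.max() * f for f in (0.15, 0.3, 0.5, 0.8, 1.2)):
        x0 = [max(float(g.min()), 0.0), max(g_max - float(g.min()), 1e-6), a0]
        try:
            sol = least_squares(resid, x0, bounds=([0, 0, 1e-6],
                                                   [np.inf, np.inf, np.inf]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("variogram fit failed from every start")
    c0, c, a = best.x
    return VariogramModel(family, float(c0), float(c), float(a))


# ---------------------------------------------------------------------------
# Linear model of coregionalization

@dataclass
class CoregionalizationModel:
    variables: list[str]          # primary first
    family: str
    range_km: float
    b0: np.ndarray                # nugget coefficient matrix (PSD)
    b1: np.ndarray                # structure coefficient matrix (PSD)
    psd_adjustment: float = 0.0   # Frobenius distance moved by the projection

    @property
    def primary(self) -> str:
        return self.variables[0]

    def cross_covariance(self, i: int, j: int, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.b1[i, j] * (1.0 - variogram_shape(self.family, h, self.range_km))
        return c + np.where(h <= 1e-9, self.b0[i, j], 0.0)

    def direct_variogram(self, i: int) -> VariogramModel:
        return VariogramModel(self.family, float(self.b0[i, i]),
                              float(self.b1[i, i]), self.range_km)


def _nearest_psd(mat: np.ndarray) -> tuple[np.ndarray, float]:
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    clipped = np.clip(vals, 0.0, None)
    out = vecs @ np.diag(clipped) @ vecs.T
    return out, float(np.linalg.norm(out - sym))


def fit_lmc(samples: pd.DataFrame, primary: str, secondaries: list[str],
            family: str = "spherical", n_lags: int = 12,
            max_dist: float | None = None) -> CoregionalizationModel:
    """Fit the LMC: shared family and range, per-pair (b0, b1) coefficients.

    The shared range is chosen by profiling: for each candidate range the
    per-pair coefficients have a (weighted) linear least-squares solution;
    the range minimizing the total cost wins (golden-section refinement).
    Direct-variogram coefficients are solved under nonnegativity; B0 and B1
    are then projected to the nearest positive semi-definite matrices and the
    Frobenius adjustment recorded.
    """
    variables = [primary] + list(secondaries)
    if len(samples) < 4:
        raise ValueError("need at least 4 shared sites for co-kriging")
    lons = samples["lon"].to_numpy(dtype=float)
    lats = samples["lat"].to_numpy(dtype=float)
    emp: dict[tuple[int, int], pd.DataFrame] = {}
    for i, vi in enumerate(variables):
        for j in range(i, len(variables)):
            vj = variables[j]
            emp[(i, j)] = empirical_variogram(
                lons, lats, samples[vi], None if vi == vj else samples[vj],
                n_lags=n_lags, max_dist=max_dist)

    h_max = max(float(e["h"].max()) for e in emp.values())

    def solve_pairs(a: float):
        cost = 0.0
        coefs = {}
        for (i, j), e in emp.items():
            h = e["h"].to_numpy(dtype=float)
            g = e["gamma"].to_numpy(dtype=float)
            wsqrt = np.sqrt(e["n_pairs"].to_numpy(dtype=float)) / np.maximum(h, 1e-9)
            A = np.column_stack([np.ones_like(h), variogram_shape(family, h, a)])
            Aw = A * wsqrt[:, None]
            gw = g * wsqrt
            if i == j:
                sol, _ = nnls(Aw, gw)
            else:
                sol, *_ = np.linalg.lstsq(Aw, gw, rcond=None)
            coefs[(i, j)] = sol
            cost += float(np.sum((Aw @ sol - gw) ** 2))
        return cost, coefs

    # coarse profile over the range, then golden-section refinement
    grid = np.linspace(0.05 * h_max, 1.5 * h_max, 30)
    costs = [solve_pairs(a)[0] for a in grid]
    k = int(np.argmin(costs))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda a: solve_pairs(a)[0], bounds=(lo, hi),
                          method="bounded")
    a_best = float(res.x)
    _, coefs = solve_pairs(a_best)

    v = len(variables)
    b0 = np.zeros((v, v))
    b1 = np.zeros((v, v))
    for (i, j), (c0, c1) in coefs.items():
        b0[i, j] = b0[j, i] = c0
        b1[i, j] = b1[j, i] = c1
    b0p, d0 = _nearest_psd(b0)
    b1p, d1 = _nearest_psd(b1)
    return CoregionalizationModel(variables=variables, family=family,
                                  range_km=a_best, b0=b0p, b1=b1p,
                                  psd_adjustment=d0 + d1)


def lmc_from_variogram(model: VariogramModel, variable: str) -> CoregionalizationModel:
    """Wrap a single-variable variogram as a degenerate LMC (plain ordinary
    kriging)."""
    return CoregionalizationModel(
        variables=[variable], family=model.family, range_km=model.range_km,
        b0=np.array([[model.nugget]]), b1=np.array([[model.partial_sill]]))


# ---------------------------------------------------------------------------
# (Co-)kriging

def _build_lhs(model: CoregionalizationModel, lons, lats,
               keep_primary: np.ndarray | None = None):
    """Augmented ordinary co-kriging LHS and the data bookkeeping.

    Data vector = primary values at sites in ``keep_primary`` (all by
    default) followed by each secondary's values at every site. Constraints:
    primary weights sum to 1, each secondary's sum to 0.
    """
    n = len(lons)
    v = len(model.variables)
    if keep_primary is None:
        keep_primary = np.arange(n)
    site_idx = [np.asarray(keep_primary)] + [np.arange(n)] * (v - 1)
    var_idx = np.concatenate([np.full(len(s), k) for k, s in enumerate(site_idx)])
    sites = np.concatenate(site_idx)
    nd = len(sites)
    d = np.asarray(haversine_km(lons[sites][:, None], lats[sites][:, None],
                                lons[sites][None, :], lats[sites][None, :]))
    K = np.empty((nd, nd))
    for i in range(v):
        for j in range(v):
            m = (var_idx[:, None] == i) & (var_idx[None, :] == j)
            if m.any():
                K[m] = model.cross_covariance(i, j, d[m])
    A = np.zeros((nd + v, nd + v))
    A[:nd, :nd] = K
    for k in range(v):
        A[nd + k, :nd] = (var_idx == k).astype(float)
        A[:nd, nd + k] = (var_idx == k).astype(float)
    return A, site_idx, sites, var_idx


def _rhs(model: CoregionalizationModel, site_lons, site_lats, sites, var_idx,
         lons0, lats0):
    """Stacked RHS columns for the target points (lons0, lats0)."""
    nd = len(sites)
    v = len(model.variables)
    d = np.asarray(haversine_km(site_lons[sites][:, None],
                                site_lats[sites][:, None],
                                np.asarray(lons0)[None, :],
                                np.asarray(lats0)[None, :]))
    rhs = np.zeros((nd + v, d.shape[1]))
    for k in range(v):
        m = var_idx == k
        rhs[:nd][m] = model.cross_covariance(k, 0, d[m])
    rhs[nd] = 1.0      # primary unbiasedness constraint
    return rhs


def _solve_kriging(A, rhs):
    try:
        return np.linalg.solve(A, rhs), False
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        return sol, True


def krige_points(model: CoregionalizationModel, samples: pd.DataFrame,
                 lons0, lats0, keep_primary: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Co-kriging prediction and kriging SE at arbitrary points."""
    lons = samples["lon"].to_numpy(dtype=float)
    lats = samples["lat"].to_numpy(dtype=float)
    A, site_idx, sites, var_idx = _build_lhs(model, lons, lats, keep_primary)
    z = np.concatenate([samples[v].to_numpy(dtype=float)[s]
                        for v, s in zip(model.variables, site_idx)])
    rhs = _rhs(model, lons, lats, sites, var_idx,
               np.atleast_1d(lons0), np.atleast_1d(lats0))
    sol, _ = _solve_kriging(A, rhs)
    nd = len(sites)
    pred = sol[:nd].T @ z
    c00 = model.b0[0, 0] + model.b1[0, 0]
    var = c00 - np.sum(sol * rhs, axis=0)
    return pred, np.sqrt(np.clip(var, 0.0, None))


def cokrige_grid(model: CoregionalizationModel, samples: pd.DataFrame,
                 spec: GridSpec, mask: np.ndarray | None = None,
                 ) -> tuple[RasterGrid, RasterGrid]:
    """Prediction and kriging-SE surfaces over a grid.

    The co-kriging LHS is identical at every cell (the data configuration
    does not change), so it is factorized once and the per-cell systems are
    solved as one batched right-hand side. ``mask`` (boolean, True = compute)
    restricts the prediction domain; other cells are nodata.
    """
    lons_c, lats_c = spec.cell_centers()
    lon_g, lat_g = np.meshgrid(lons_c, lats_c)
    if mask is None:
        mask = np.ones((spec.n_rows, spec.n_cols), dtype=bool)
    rows, cols = np.nonzero(mask)
    pred, se = krige_points(model, samples, lon_g[rows, cols], lat_g[rows, cols])
    out_p = np.full((spec.n_rows, spec.n_cols), np.nan)
    out_s = np.full((spec.n_rows, spec.n_cols), np.nan)
    out_p[rows, cols] = pred
    out_s[rows, cols] = se
    return RasterGrid(spec, out_p), RasterGrid(spec, out_s)


@dataclass
class LooReport:
    compound: str
    mean_error: float
    rmse: float
    standardized_rmse: float
    errors: np.ndarray = field(repr=False, default=None)


def loo_validate(model: CoregionalizationModel, samples: pd.DataFrame) -> LooReport:
    """Leave-one-out validation of the primary variable.

    For each site the primary datum is removed (secondary covariates, known
    everywhere, stay in), the weights are re-solved with the variogram fixed,
    and the site is predicted. Reports ME, RMSE and standardized RMSE
    (root mean of ((zhat - z) / SE)^2).
    """
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 sites for leave-one-out validation")
    z = samples[model.primary].to_numpy(dtype=float)
    lons = samples["lon"].to_numpy(dtype=float)
    lats = samples["lat"].to_numpy(dtype=float)
    errs = np.empty(n)
    std = np.empty(n)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        pred, se = krige_points(model, samples, [lons[i]], [lats[i]],
                                keep_primary=keep)
        errs[i] = pred[0] - z[i]
        std[i] = errs[i] / se[0] if se[0] > 0 else np.nan
    return LooReport(compound=model.primary,
                     mean_error=float(np.mean(errs)),
                     rmse=float(np.sqrt(np.mean(errs ** 2))),
                     standardized_rmse=float(np.sqrt(np.nanmean(std ** 2))),
                     errors=errs)
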