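"""Integrated quality index: fusion of ecological and quality suitability,
Fisher–Jenks natural-breaks classification, and the final zoning map.

The integrated index is a weighted linear combination C = w_e*E + w_q*Q of
the cloglog ecological-suitability surface E and a quality surface Q built
from min–max-normalized kriged compound maps (cell-wise mean by default).
Equal weights (0.5/0.5) are the default. C is classified with data-driven
Fisher–Jenks breaks (exact dynamic program minimizing within-class sum of
squared deviations over contiguous classes of the sorted values); the top
class is the "core quality region".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .habitat import AreaReport, ZoningMap, ZoningScheme, area_report
from .raster import RasterGrid


@dataclass(frozen=True)
class IntegrationConfig:
    weight_ecological: float = 0.5
    weight_quality: float = 0.5
    fusion_rule: str = "mean"          # "mean" | "min" | "weighted"
    fusion_weights: tuple[float, ...] | None = None
    jenks_k: int = 4

    def __post_init__(self) -> None:
        if self.weight_ecological < 0 or self.weight_quality < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.weight_ecological + self.weight_quality - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.jenks_k < 2:
            raise ValueError("jenks_k must be >= 2")


def normalize01(grid: RasterGrid, mask: np.ndarray | None = None) -> RasterGrid:
    """Min–max rescale to [0, 1] over the masked cells; nodata preserved.

    Affine-invariant: normalize01(a*X + b) == normalize01(X) for a > 0.
    """
    m = grid.mask if mask is None else (grid.mask & mask)
    vals = grid.values[m]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("normalization needs >= 2 distinct finite values")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full_like(grid.values, np.nan)
    out[m] = (grid.values[m] - lo) / (hi - lo)
    return grid.copy_with(out)


def fuse_quality(grids: list[RasterGrid], rule: str = "mean",
                 weights: list[float] | None = None) -> RasterGrid:
    """Combine normalized compound surfaces into one quality layer Q."""
    if not grids:
        raise ValueError("need at least one compound grid")
    spec = grids[0].spec
    if any(g.spec != spec for g in grids):
        raise ValueError("compound grids are not co-registered")
    arr = np.stack([g.values for g in grids])
    if rule == "mean":
        out = arr.mean(axis=0)
    elif rule == "min":
        out = arr.min(axis=0)
    elif rule == "weighted":
        if weights is None or len(weights) != len(grids):
            raise ValueError("weighted fusion needs one weight per grid")
        w = np.asarray(weights, dtype=float)
        out = np.tensordot(w / w.sum(), arr, axes=1)
    else:
        raise ValueError(f"unknown fusion rule {rule!r}")
    return RasterGrid(spec, out)


def integrate(ecological: RasterGrid, quality: RasterGrid,
              config: IntegrationConfig = IntegrationConfig()) -> RasterGrid:
    """C = w_e*E + w_q*Q per cell; nodata in either input propagates."""
    if ecological.spec != quality.spec:
        raise ValueError("suitability and quality grids are not co-registered")
    c = (config.weight_ecological * ecological.values
         + config.weight_quality * quality.values)
    return RasterGrid(ecological.spec, c)


@dataclass
class JenksBreaks:
    k: int
    breaks: list[float]       # k + 1 values: data min, k-1 cuts, data max
    gssd: float               # within-class sum of squared deviations

    def scheme(self, names: list[str] | None = None) -> ZoningScheme:
        names = names or [f"class_{i + 1}" for i in range(self.k)]
        b = list(self.breaks)
        # widen the outer bounds a hair so min/max values classify cleanly
        b[-1] = b[-1] + 1e-12 if b[-1] == b[-2] else b[-1]
        return ZoningScheme(tuple(names), tuple(b))


def jenks_breaks(values, k: int, max_sample: int = 10000,
                 seed: int = 0) -> JenksBreaks:
    """Exact Fisher–Jenks natural breaks by dynamic programming.

    Minimizes the total within-class sum of squared deviations over
    contiguous classes of the sorted values; ties between optimal partitions
    break toward the smaller first-class size. For inputs larger than
    ``max_sample`` a seeded subsample drives the optimization and the breaks
    are applied to all values.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < k:
        raise ValueError(f"need at least k={k} distinct finite values")
    full_min, full_max = float(x.min()), float(x.max())
    if len(x) > max_sample:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_sample, replace=False)
    x = np.sort(x)
    n = len(x)
    # prefix sums for O(1) segment SSD: ssd(i..j) over x[i:j+1]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg(i: np.ndarray, j: int) -> np.ndarray:
        cnt = j - i + 1
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        return s2 - s * s / cnt

    cost = np.full((k, n), np.inf)
    cut = np.zeros((k, n), dtype=int)
    j_all = np.arange(n)
    cost[0] = cs2[1:] - cs[1:] ** 2 / (j_all + 1)
    for c in range(1, k):
        for j in range(c, n):
            starts = np.arange(c, j + 1)
            total = cost[c - 1][starts - 1] + seg(starts, j)
            # argmin takes the first (smallest start) optimum -> the earlier
            # classes stay as small as possible on ties
            m = int(np.argmin(total))
            cost[c][j] = total[m]
            cut[c][j] = starts[m]
    # recover break positions
    bounds = [n - 1]
    j = n - 1
    for c in range(k - 1, 0, -1):
        s = cut[c][j]
        bounds.append(s - 1)
        j = s - 1
    bounds.reverse()
    # half-open upper edges midway between adjacent class extremes, so that
    # classification by digitize reproduces the optimal partition exactly
    cuts = [float((x[b] + x[b + 1]) / 2.0) for b in bounds[:-1]]
    breaks = [full_min] + cuts + [full_max]
    return JenksBreaks(k=k, breaks=breaks, gssd=float(cost[k - 1][n - 1]))


@dataclass
class ClassifiedIndex:
    zoning: ZoningMap
    areas: AreaReport
    breaks: JenksBreaks
    core_class: str


def classify_index(index: RasterGrid, breaks: JenksBreaks,
                   scenario_tag: str = "integrated",
                   class_names: list[str] | None = None) -> ClassifiedIndex:
    """Apply Jenks breaks to the integrated index; the top class is the core
    quality region. Returns the zoning map plus its area ledger."""
    scheme = breaks.scheme(class_names)
    vals = index.values
    finite = index.mask
    clipped = np.clip(vals, scheme.breaks[0], scheme.breaks[-1])
    idx = np.digitize(clipped, scheme.breaks[1:-1], right=False)
    zones = np.where(finite, idx.astype(float), np.nan)
    zmap = ZoningMap(index.copy_with(zones), scheme)
    return ClassifiedIndex(zoning=zmap, areas=area_report(zmap, scenario_tag),
                           breaks=breaks, core_class=scheme.names[-1])
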