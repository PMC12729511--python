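"""Two-step predictor optimization: contribution screen, pairwise correlation
pruning, and a variance-inflation-factor loop.

The protocol mirrors common SDM practice: (1) drop variables that contribute
nothing to a preliminary maximum-entropy fit; (2) for every pair with
|Pearson r| > 0.8, keep the higher-contribution member; (3) iteratively drop
the highest-VIF variable until all VIF < 10. Correlations and VIFs are
computed over the background sample by default — collinearity is a property
of the predictor field, not of the presences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionReport:
    initial_vars: list[str]
    contributions: dict[str, float] = field(default_factory=dict)
    correlation_matrix: pd.DataFrame | None = None
    dropped_zero_contribution: list[str] = field(default_factory=list)
    dropped_pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_vif: list[tuple[str, float]] = field(default_factory=list)
    final_vars: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "initial_vars": self.initial_vars,
            "contributions": self.contributions,
            "dropped_zero_contribution": self.dropped_zero_contribution,
            "dropped_pairwise": [list(t) for t in self.dropped_pairwise],
            "dropped_vif": [list(t) for t in self.dropped_vif],
            "final_vars": self.final_vars,
            "final_vifs": self.final_vifs,
        }


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix over the given columns.

    Zero-variance variables are excluded with a warning (their correlation is
    undefined).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    keep = []
    for v in variables:
        if np.nanstd(table[v].to_numpy()) == 0:
            warnings.warn(f"variable {v!r} has zero variance; excluded from "
                          "correlation matrix")
        else:
            keep.append(v)
    return table[keep].corr(method="pearson")


def contribution_screen(design, settings: dict | None = None) -> dict[str, float]:
    """Percent contributions from a preliminary maximum-entropy fit.

    Variables with zero contribution are candidates for removal. ``settings``
    are passed through to the fit (feature classes etc.).
    """
    from .maxent import build_features, fit

    settings = settings or {}
    feats = build_features(design, classes=settings.get("classes", ("L", "Q", "H")),
                           hinge_knots=settings.get("hinge_knots", 10))
    model = fit(design, feats, rm=settings.get("rm", 1.0),
                tol=settings.get("tol", 1e-5),
                max_iter=settings.get("max_iter", 200))
    return model.percent_contribution()


def prune_pairwise(corr: pd.DataFrame, contributions: dict[str, float],
                   threshold: float = 0.8) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop the lower-contribution member of every |r| > threshold pair.

    Pairs are processed in descending |r|; a pair is only acted on if both
    members are still kept. Ties in contribution drop the lexicographically
    later code. Returns (kept variables, ledger of (dropped, kept, r)).
    """
    vars_ = [v for v in corr.columns if v in contributions]
    pairs = []
    for i, a in enumerate(vars_):
        for b in vars_[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                pairs.append((abs(r), r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[2], t[3]))
    kept = set(vars_)
    ledger: list[tuple[str, str, float]] = []
    for _, r, a, b in pairs:
        if a in kept and b in kept:
            ca, cb = contributions.get(a, 0.0), contributions.get(b, 0.0)
            if ca > cb:
                drop, keep = b, a
            elif cb > ca:
                drop, keep = a, b
            else:
                drop, keep = max(a, b), min(a, b)
            kept.discard(drop)
            ledger.append((drop, keep, r))
    return [v for v in vars_ if v in kept], ledger


def compute_vifs(table: pd.DataFrame, variables: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from OLS of variable j on the others
    (intercept included). Perfect collinearity yields +inf."""
    if len(variables) < 2:
        return {v: 1.0 for v in variables}
    X = table[variables].to_numpy(dtype=float)
    n = X.shape[0]
    vifs: dict[str, float] = {}
    ones = np.ones((n, 1))
    for j, v in enumerate(variables):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs[v] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        vifs[v] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(table: pd.DataFrame, variables: list[str], threshold: float = 10.0,
              contributions: dict[str, float] | None = None,
              ) -> tuple[list[str], list[tuple[str, float]], dict[str, float]]:
    """Iteratively drop the max-VIF variable until all VIF < threshold.

    Ties on VIF are broken by dropping the lower-contribution variable first
    (then lexicographically later). Returns (survivors, drop ledger,
    final VIFs).
    """
    if len(variables) < 2:
        return list(variables), [], {v: 1.0 for v in variables}
    contributions = contributions or {}
    kept = list(variables)
    ledger: list[tuple[str, float]] = []
    while len(kept) >= 2:
        vifs = compute_vifs(table, kept)
        vmax = max(vifs.values())
        if vmax < threshold:
            return kept, ledger, vifs
        worst = [v for v in kept if vifs[v] == vmax]
        worst.sort(key=lambda v: (contributions.get(v, 0.0), [-ord(c) for c in v]))
        drop = worst[0]
        kept.remove(drop)
        ledger.append((drop, vmax))
    return kept, ledger, compute_vifs(table, kept)


def select_variables(design, threshold_r: float = 0.8, threshold_vif: float = 10.0,
                     settings: dict | None = None,
                     contributions: dict[str, float] | None = None,
                     use_background_only: bool = True,
                     retain: list[str] | None = None) -> SelectionReport:
    """Run the full protocol on a design table.

    ``contributions`` may be supplied (e.g. from an earlier fit) to skip the
    preliminary model. ``retain`` lists expert-retained variables that are
    never dropped (the configurable stand-in for "clear ecological
    significance").
    """
    report = SelectionReport(initial_vars=list(design.variables))
    retain = retain or []
    if contributions is None:
        contributions = contribution_screen(design, settings)
    report.contributions = dict(contributions)

    report.dropped_zero_contribution = [
        v for v in design.variables
        if contributions.get(v, 0.0) <= 0.0 and v not in retain]
    vars_ = [v for v in design.variables
             if v not in report.dropped_zero_contribution]

    table = design.background if use_background_only else design.table
    corr = pearson_matrix(table, vars_)
    report.correlation_matrix = corr
    boosted = {v: (np.inf if v in retain else contributions.get(v, 0.0))
               for v in vars_}
    kept, pair_ledger = prune_pairwise(corr, boosted, threshold_r)
    report.dropped_pairwise = pair_ledger

    final, vif_ledger, vifs = vif_prune(table, kept, threshold_vif, boosted)
    report.dropped_vif = vif_ledger
    report.final_vars = final
    report.final_vifs = vifs
    return report
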