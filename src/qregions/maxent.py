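"""Maximum-entropy presence–background species distribution model.

The model is the Gibbs distribution over background cells that maximizes the
L1-penalized log-likelihood of the presence sample:

    J(lambda) = mean_presence[lambda . f(x)] - log Z_B(lambda)
                - sum_j beta_j |lambda_j|,
    Z_B = sum_background exp(lambda . f(x)),

with features f built from each variable scaled to [0, 1] over the design:
linear (L), quadratic (Q) and hinge (H) classes. Per-feature penalties are
beta_j = rm * c_class * sd_j(presences) / sqrt(m) with c_L = c_Q = 1 and
c_H = 0.5, rm the global regularization multiplier (default 1).

Fitting is cyclic coordinate descent with a Newton step soft-thresholded by
the L1 penalty and a backtracking safeguard, so the objective never
decreases. Raw output is q(x) = exp(lambda . f(x)) / Z_B; the cloglog output
p(x) = 1 - exp(-e^H q(x)) uses the entropy H of the fitted raw distribution,
frozen at training time.

Percent contribution is the classical path-dependent bookkeeping: every
accepted coordinate update that improves the objective credits the gain to
the updated feature's parent variable. The jackknife refits with each
variable alone / left out and reports regularized training gain (objective
minus the uniform-model objective -log |B|).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .occurrences import DesignTable
from .raster import RasterGrid, RasterStack


@dataclass(frozen=True)
class Feature:
    variable: str
    kind: str                 # "linear" | "quadratic" | "hinge_fwd" | "hinge_rev"
    knot: float | None = None

    @property
    def cls(self) -> str:
        return {"linear": "L", "quadratic": "Q",
                "hinge_fwd": "H", "hinge_rev": "H"}[self.kind]


@dataclass
class FeatureSet:
    """Scaling bounds per variable plus the feature list."""

    bounds: dict[str, tuple[float, float]]
    features: list[Feature]

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def scale(self, table: pd.DataFrame) -> dict[str, np.ndarray]:
        out = {}
        for v, (lo, hi) in self.bounds.items():
            x = table[v].to_numpy(dtype=float)
            out[v] = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
        return out

    def design_matrix(self, table: pd.DataFrame) -> np.ndarray:
        """Rows x features matrix; every entry in [0, 1] on in-range data."""
        missing = [v for v in self.bounds if v not in table.columns]
        if missing:
            raise KeyError(f"rows are missing model variables {missing}")
        scaled = self.scale(table)
        cols = []
        for f in self.features:
            s = scaled[f.variable]
            if f.kind == "linear":
                cols.append(s)
            elif f.kind == "quadratic":
                cols.append(s ** 2)
            elif f.kind == "hinge_fwd":
                k = f.knot
                cols.append(np.maximum(0.0, (s - k) / (1.0 - k)))
            else:
                k = f.knot
                cols.append(np.maximum(0.0, (k - s) / k))
        return np.column_stack(cols)


def build_features(design: DesignTable, classes=("L", "Q", "H"),
                   hinge_knots: int = 10) -> FeatureSet:
    """Deterministic LQH feature construction from design statistics.

    Hinge knots sit at ``hinge_knots`` evenly spaced sample quantiles of the
    scaled variable, per direction; knots at 0 or 1 are degenerate and
    skipped. Constant variables keep a linear feature only.
    """
    classes = set(classes)
    bounds = {}
    for v in design.variables:
        x = design.table[v].to_numpy(dtype=float)
        bounds[v] = (float(np.min(x)), float(np.max(x)))
    feats: list[Feature] = []
    for v in design.variables:
        lo, hi = bounds[v]
        constant = hi <= lo
        if constant:
            warnings.warn(f"variable {v!r} is constant on the design; "
                          "only a linear feature is built")
        if "L" in classes:
            feats.append(Feature(v, "linear"))
        if constant:
            continue
        if "Q" in classes:
            feats.append(Feature(v, "quadratic"))
        if "H" in classes and hinge_knots > 0:
            x = design.table[v].to_numpy(dtype=float)
            s = (x - lo) / (hi - lo)
            probs = (np.arange(1, hinge_knots + 1)) / (hinge_knots + 1)
            knots = np.quantile(s, probs)
            for k in sorted(set(np.round(knots, 12))):
                if 0.0 < k < 1.0:
                    feats.append(Feature(v, "hinge_fwd", float(k)))
                    feats.append(Feature(v, "hinge_rev", float(k)))
    return FeatureSet(bounds=bounds, features=feats)


@dataclass
class MaxentModel:
    features: FeatureSet
    coefficients: np.ndarray
    penalties: np.ndarray
    regularization_multiplier: float
    log_z: float                      # log partition over the background
    entropy: float                    # H of the fitted raw distribution
    n_background: int
    objective: float
    iterations: int
    final_gain_delta: float
    converged: bool
    contribution_credit: dict[str, float] = field(default_factory=dict)

    @property
    def gain(self) -> float:
        """Regularized training gain: objective minus the uniform model's."""
        return self.objective + np.log(self.n_background)

    def percent_contribution(self) -> dict[str, float]:
        credit = {v: max(0.0, self.contribution_credit.get(v, 0.0))
                  for v in self.features.variables}
        total = sum(credit.values())
        if total == 0:
            n = len(credit)
            return {v: 100.0 / n for v in credit}
        return {v: 100.0 * c / total for v, c in credit.items()}

    def to_json(self) -> str:
        return json.dumps({
            "bounds": {v: list(b) for v, b in self.features.bounds.items()},
            "features": [[f.variable, f.kind, f.knot] for f in self.features.features],
            "coefficients": self.coefficients.tolist(),
            "rm": self.regularization_multiplier,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_background": self.n_background,
        }, indent=2)


def _objective(lam, F_pres_mean, s_bg, beta):
    logz = _logsumexp(s_bg)
    return float(F_pres_mean @ lam - logz - beta @ np.abs(lam)), logz


def _logsumexp(s):
    m = np.max(s)
    return float(m + np.log(np.sum(np.exp(s - m))))


def fit(design: DesignTable, features: FeatureSet, rm: float = 1.0,
        tol: float = 1e-5, max_iter: int = 500,
        init: np.ndarray | None = None) -> MaxentModel:
    """L1-penalized maxent fit by monotone cyclic coordinate descent.

    Stops when a full cycle improves the objective by less than ``tol`` or at
    ``max_iter`` cycles (then the model carries ``converged=False``).
    ``init`` warm-starts the coefficients (the problem is convex, so the
    optimum does not depend on it).
    """
    pres = design.presence
    if len(pres) < 2:
        raise ValueError("need at least 2 presence rows to fit")
    bg = design.background
    F_p = features.design_matrix(pres)
    F_b = features.design_matrix(bg)
    m, n_feat = F_p.shape
    B = len(bg)
    f_pres_mean = F_p.mean(axis=0)

    sd = F_p.std(axis=0, ddof=0)
    cls_const = np.array([0.5 if f.cls == "H" else 1.0
                          for f in features.features])
    beta = rm * cls_const * np.maximum(sd, 1e-4) / np.sqrt(m)

    lam = np.zeros(n_feat) if init is None else np.asarray(init, dtype=float).copy()
    s = F_b @ lam
    obj, logz = _objective(lam, f_pres_mean, s, beta)
    credit: dict[str, float] = {}
    delta_cycle = np.inf
    it = 0
    w = np.exp(s - logz)              # background probabilities q_i
    for it in range(1, max_iter + 1):
        obj_start = obj
        for j in range(n_feat):
            fj = F_b[:, j]
            ew = w @ fj               # E_q[f_j]
            var = w @ (fj * fj) - ew * ew
            g = f_pres_mean[j] - ew   # gradient of the unpenalized loglik
            h = max(var, 1e-12)
            target = lam[j] + g / h
            new = np.sign(target) * max(0.0, abs(target) - beta[j] / h)
            dl = new - lam[j]
            if dl == 0.0:
                continue
            # exact objective change; backtrack if the Newton step overshoots
            for _ in range(30):
                s_new = s + dl * fj
                logz_new = _logsumexp(s_new)
                d_obj = (f_pres_mean[j] * dl - (logz_new - logz)
                         - beta[j] * (abs(lam[j] + dl) - abs(lam[j])))
                if d_obj >= 0:
                    break
                dl *= 0.5
            else:
                continue
            if d_obj <= 0:
                continue
            lam[j] += dl
            s = s_new
            logz = logz_new
            obj += d_obj
            v = features.features[j].variable
            credit[v] = credit.get(v, 0.0) + d_obj
            w = np.exp(s - logz)
        delta_cycle = obj - obj_start
        if delta_cycle < tol:
            break
    converged = delta_cycle < tol
    if not converged:
        warnings.warn(f"maxent fit did not converge in {max_iter} cycles "
                      f"(last cycle gain {delta_cycle:.3g})")
    q = np.exp(s - logz)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentModel(features=features, coefficients=lam, penalties=beta,
                       regularization_multiplier=rm, log_z=logz,
                       entropy=entropy, n_background=B, objective=obj,
                       iterations=it, final_gain_delta=float(delta_cycle),
                       converged=converged, contribution_credit=credit)


def predict(model: MaxentModel, rows: pd.DataFrame,
            output: str = "cloglog") -> np.ndarray:
    """Raw density q(x) = exp(lambda.f)/Z_B or cloglog p = 1 - exp(-e^H q)."""
    F = model.features.design_matrix(rows)
    raw = np.exp(F @ model.coefficients - model.log_z)
    if output == "raw":
        return raw
    if output == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise ValueError(f"unknown output {output!r}")


def auc_presence_background(pres_scores, bg_scores) -> float:
    """Mann–Whitney rank AUC: P(presence score > background score), ties 1/2."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    all_ = np.concatenate([pres_scores, bg_scores])
    ranks = rankdata(all_)
    n1, n2 = len(pres_scores), len(bg_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


@dataclass
class CVReport:
    k: int
    fold_auc: list[float]
    mean_auc: float
    seed: int | None


def evaluate_cv(design: DesignTable, features: FeatureSet | None = None,
                k: int = 10, seed: int | None = None, rm: float = 1.0,
                tol: float = 1e-5, max_iter: int = 500,
                warm_start: np.ndarray | None = None) -> CVReport:
    """k-fold cross-validated AUC.

    Presences are partitioned into k seeded folds; each fold's model is fit
    on the remaining presences (with the full background) and scored by the
    rank AUC of held-out presences against the background.
    """
    pres = design.presence.reset_index(drop=True)
    bg = design.background
    if k > len(pres):
        raise ValueError(f"k={k} exceeds the {len(pres)} presence rows")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pres))
    folds = np.array_split(idx, k)
    aucs = []
    for fold in folds:
        train = pres.drop(index=fold)
        test = pres.loc[fold]
        sub = DesignTable(pd.concat([train, bg], ignore_index=True),
                          variables=design.variables, background_n=len(bg))
        feats = features or build_features(sub)
        model = fit(sub, feats, rm=rm, tol=tol, max_iter=max_iter,
                    init=warm_start)
        sc_test = predict(model, test, "raw")
        sc_bg = predict(model, bg, "raw")
        aucs.append(auc_presence_background(sc_test, sc_bg))
    return CVReport(k=k, fold_auc=aucs, mean_auc=float(np.mean(aucs)), seed=seed)


def evaluate_split(design: DesignTable, features: FeatureSet | None = None,
                   train_fraction: float = 0.75, seed: int | None = None,
                   **fit_kw) -> float:
    """Single random train/test split (default 75/25); returns test AUC."""
    pres = design.presence.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pres))
    n_train = int(round(train_fraction * len(pres)))
    train, test = pres.loc[idx[:n_train]], pres.loc[idx[n_train:]]
    bg = design.background
    sub = DesignTable(pd.concat([train, bg], ignore_index=True),
                      variables=design.variables, background_n=len(bg))
    feats = features or build_features(sub)
    model = fit(sub, feats, **fit_kw)
    return auc_presence_background(predict(model, test, "raw"),
                                   predict(model, bg, "raw"))


@dataclass
class VariableImportance:
    percent_contribution: dict[str, float]
    jackknife: dict[str, tuple[float, float]]   # var -> (only gain, without gain)
    full_gain: float


def variable_importance(design: DesignTable, features: FeatureSet,
                        rm: float = 1.0, tol: float = 1e-5,
                        max_iter: int = 500,
                        model: MaxentModel | None = None) -> VariableImportance:
    """Percent contribution plus jackknife training gains.

    ``only`` gain refits with just one variable's features; ``without`` gain
    refits with that variable's features removed.
    """
    model = model or fit(design, features, rm=rm, tol=tol, max_iter=max_iter)
    jack: dict[str, tuple[float, float]] = {}
    for v in features.variables:
        only = FeatureSet(bounds={v: features.bounds[v]},
                          features=[f for f in features.features if f.variable == v])
        rest_vars = [u for u in features.variables if u != v]
        without = FeatureSet(bounds={u: features.bounds[u] for u in rest_vars},
                             features=[f for f in features.features
                                       if f.variable != v])
        g_only = fit(design, only, rm=rm, tol=tol, max_iter=max_iter).gain
        g_without = (fit(design, without, rm=rm, tol=tol, max_iter=max_iter).gain
                     if rest_vars else 0.0)
        jack[v] = (g_only, g_without)
    return VariableImportance(percent_contribution=model.percent_contribution(),
                              jackknife=jack, full_gain=model.gain)


@dataclass
class ResponseSummary:
    variable: str
    values: np.ndarray
    cloglog: np.ndarray
    suitable_ranges: list[tuple[float, float]]   # maximal intervals with p >= 0.5
    adaptive_threshold: float                    # argmax of p (ties: smallest)


def response_curve(model: MaxentModel, variable: str, design: DesignTable,
                   grid_n: int = 100, p_threshold: float = 0.5) -> ResponseSummary:
    """Marginal response: sweep one variable over its observed range with the
    others held at the background mean; Z and H stay frozen from the fit."""
    if variable not in model.features.bounds:
        raise KeyError(f"variable {variable!r} not in the model")
    lo, hi = model.features.bounds[variable]
    xs = np.linspace(lo, hi, grid_n)
    bg_mean = design.background[model.features.variables].mean()
    rows = pd.DataFrame({v: np.full(grid_n, bg_mean[v])
                         for v in model.features.variables})
    rows[variable] = xs
    p = predict(model, rows, "cloglog")
    above = p >= p_threshold
    ranges: list[tuple[float, float]] = []
    i = 0
    while i < grid_n:
        if above[i]:
            j = i
            while j + 1 < grid_n and above[j + 1]:
                j += 1
            ranges.append((float(xs[i]), float(xs[j])))
            i = j + 1
        else:
            i += 1
    return ResponseSummary(variable=variable, values=xs, cloglog=p,
                           suitable_ranges=ranges,
                           adaptive_threshold=float(xs[int(np.argmax(p))]))


def project_to_raster(model: MaxentModel, stack: RasterStack) -> RasterGrid:
    """Cloglog suitability surface over a raster stack; nodata propagates."""
    missing = [v for v in model.features.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model layers {missing}")
    spec = stack.spec
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    table = pd.DataFrame({v: stack.layers[v].values[rows, cols]
                          for v in model.features.variables})
    p = predict(model, table, "cloglog")
    out = np.full((spec.n_rows, spec.n_cols), np.nan)
    out[rows, cols] = p
    return RasterGrid(spec, out)
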