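"""Configuration-driven orchestration of the full analysis.

Stages, in order: simulate (or load) → thin → select → fit → project →
classify → centroids → screen → krige → integrate. Every intermediate
artifact is written into the run directory; the machine-readable manifest
records, per stage, the parameters, output paths, SHA-256 content hashes,
wall-clock time and warnings — the manifest plus the seed reproduce the run.

A single global seed is expanded into per-stage seeds through a fixed
``SeedSequence`` derivation, so any stage rerun in isolation sees the same
randomness. Quality stages are skipped when no compound table is available.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geostat, habitat, maxent, selection, synth, zoning
from .occurrences import OccurrenceSet, assemble_design, rarefy, read_occurrences
from .raster import RasterGrid, RasterStack, read_raster, write_raster

STAGES = ("simulate", "thin", "select", "fit", "project", "classify",
          "centroids", "screen", "krige", "integrate")


@dataclass
class RunConfig:
    output_dir: str = "run"
    seed: int = 0
    # inputs: either a synthetic scenario or explicit paths
    synthetic: bool = True
    occurrences_csv: str | None = None
    raster_dir: str | None = None
    compound_csv: str | None = None
    # stage parameters (defaults are the study's settings)
    thinning_radius_km: float = 10.0
    background_n: int = 10000
    r_threshold: float = 0.8
    vif_threshold: float = 10.0
    feature_classes: str = "LQH"
    regularization_multiplier: float = 1.0
    convergence_tol: float = 1e-5
    max_iter: int = 500
    cv_folds: int = 10
    habitat_breaks: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 1.0)
    centroid_threshold: float = 0.1
    centroid_weighting: str = "binary"
    alpha: float = 0.05
    variogram_family: str = "spherical"
    max_secondaries: int = 2
    weight_ecological: float = 0.5
    weight_quality: float = 0.5
    fusion_rule: str = "mean"
    jenks_k: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "habitat_breaks" in data:
            data["habitat_breaks"] = tuple(data["habitat_breaks"])
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Every violated precondition, with the module it belongs to."""
    v: list[str] = []
    if config.thinning_radius_km < 0:
        v.append("occurrences: thinning radius must be >= 0")
    if config.background_n < 1:
        v.append("occurrences: background_n must be >= 1")
    if not (0 < config.r_threshold <= 1):
        v.append("selection: |r| threshold must be in (0, 1]")
    if config.vif_threshold <= 1:
        v.append("selection: VIF threshold must be > 1")
    if not set(config.feature_classes) <= {"L", "Q", "H"}:
        v.append("maxent: feature classes must be drawn from {L, Q, H}")
    if config.regularization_multiplier < 0:
        v.append("maxent: regularization multiplier must be >= 0")
    if config.cv_folds < 2:
        v.append("maxent: cv_folds must be >= 2")
    b = config.habitat_breaks
    if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
        v.append("habitat: breaks must be strictly increasing")
    if not (0 < config.alpha < 1):
        v.append("geostat: alpha must be in (0, 1)")
    if config.variogram_family not in ("spherical", "exponential", "gaussian"):
        v.append("geostat: unknown variogram family")
    if config.weight_ecological < 0 or config.weight_quality < 0:
        v.append("zoning: weights must be nonnegative")
    if abs(config.weight_ecological + config.weight_quality - 1.0) > 1e-9:
        v.append("zoning: weights must sum to 1")
    if config.jenks_k < 2:
        v.append("zoning: jenks_k must be >= 2")
    if not config.synthetic:
        for name in ("occurrences_csv", "raster_dir"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                v.append(f"pipeline: input {name} missing")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {"config": asdict(config), "stages": []}

    def stage(self, name: str, params: dict, outputs: dict[str, Path],
              t0: float, warns: list[str], **extra) -> None:
        self.data["stages"].append({
            "stage": name,
            "params": params,
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in outputs.items()},
            "warnings": warns,
            "wall_clock_s": round(time.perf_counter() - t0, 3),
            **extra,
        })

    def skipped(self, name: str, reason: str) -> None:
        self.data["stages"].append({"stage": name, "skipped": True,
                                    "reason": reason})

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)

    def content_hashes(self) -> dict[str, str]:
        """Output hashes keyed by stage/name — the determinism fingerprint."""
        out = {}
        for s in self.data["stages"]:
            for k, rec in s.get("outputs", {}).items():
                out[f"{s['stage']}/{k}"] = rec["sha256"]
        return out


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig, scenario: synth.SyntheticScenario | None = None,
                 ) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure aborts with the stage name in the exception message;
    artifacts written so far are retained.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            if config.synthetic:
                scenario = scenario or synth.SyntheticScenario(
                    seed=_stage_seed(config.seed, "simulate"))
                bundle = synth.generate_bundle(scenario)
                paths = synth.write_scenario_bundle(bundle, out / "inputs")
                stack = bundle.env
                occ = OccurrenceSet(bundle.presences)
                compounds = bundle.compound_samples
                compound_names = [d.name for d in scenario.compound_defs]
                manifest.stage("simulate", {"seed": scenario.seed},
                               {"bundle_manifest": out / "inputs" / "manifest.json"},
                               t0, [str(w.message) for w in wlist])
            else:
                layers = {}
                for p in sorted(Path(config.raster_dir).glob("*")):
                    if p.suffix.lower() in (".asc", ".tif", ".tiff"):
                        layers[p.stem.removeprefix("env_")] = read_raster(p)
                stack = RasterStack(layers)
                occ = read_occurrences(config.occurrences_csv)
                compounds = (pd.read_csv(config.compound_csv)
                             if config.compound_csv else None)
                compound_names = ([c for c in compounds.columns
                                   if c not in ("lon", "lat")]
                                  if compounds is not None else [])
                manifest.stage("simulate", {"loaded": True}, {}, t0,
                               [str(w.message) for w in wlist])

        # ---- thin ------------------------------------------------------
        stage = "thin"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            thinned = rarefy(occ, config.thinning_radius_km)
            p = out / "occurrences_thinned.csv"
            thinned.presences.to_csv(p, index=False)
            manifest.stage("thin", {"radius_km": config.thinning_radius_km,
                                    "n_in": len(occ), "n_out": len(thinned)},
                           {"occurrences": p}, t0,
                           [str(w.message) for w in wlist])

        # ---- select ----------------------------------------------------
        stage = "select"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            design = assemble_design(thinned, stack, config.background_n,
                                     seed=_stage_seed(config.seed, "select"))
            report = selection.select_variables(
                design, threshold_r=config.r_threshold,
                threshold_vif=config.vif_threshold,
                settings={"classes": tuple(config.feature_classes),
                          "rm": config.regularization_multiplier,
                          "max_iter": min(config.max_iter, 200)})
            p = out / "selection_report.json"
            with open(p, "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            manifest.stage("select", {"r": config.r_threshold,
                                      "vif": config.vif_threshold,
                                      "final_vars": report.final_vars},
                           {"report": p}, t0, [str(w.message) for w in wlist])

        # ---- fit -------------------------------------------------------
        stage = "fit"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            sub = _subset_design(design, report.final_vars)
            feats = maxent.build_features(sub, classes=tuple(config.feature_classes))
            model = maxent.fit(sub, feats, rm=config.regularization_multiplier,
                               tol=config.convergence_tol,
                               max_iter=config.max_iter)
            cv = maxent.evaluate_cv(sub, feats, k=config.cv_folds,
                                    seed=_stage_seed(config.seed, "fit"),
                                    rm=config.regularization_multiplier,
                                    tol=config.convergence_tol,
                                    max_iter=config.max_iter,
                                    warm_start=model.coefficients)
            p_model = out / "maxent_model.json"
            p_model.write_text(model.to_json())
            p_cv = out / "cv_report.json"
            with open(p_cv, "w") as fh:
                json.dump({"k": cv.k, "fold_auc": cv.fold_auc,
                           "mean_auc": cv.mean_auc}, fh, indent=2)
            manifest.stage("fit", {"rm": config.regularization_multiplier,
                                   "classes": config.feature_classes,
                                   "mean_auc": cv.mean_auc},
                           {"model": p_model, "cv": p_cv}, t0,
                           [str(w.message) for w in wlist])

        # ---- project ---------------------------------------------------
        stage = "project"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            suit = maxent.project_to_raster(model, stack)
            p = out / "suitability.asc"
            write_raster(suit, p)
            manifest.stage("project", {}, {"suitability": p}, t0,
                           [str(w.message) for w in wlist])

        # ---- classify --------------------------------------------------
        stage = "classify"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            scheme = habitat.ZoningScheme(
                ("non", "low", "moderate", "high"), config.habitat_breaks)
            zmap = habitat.reclassify(suit, scheme)
            areas = habitat.area_report(zmap, "current")
            p_z = out / "habitat_zones.asc"
            write_raster(zmap.zones, p_z)
            p_a = out / "habitat_areas.csv"
            areas.to_frame().to_csv(p_a, index=False)
            manifest.stage("classify", {"breaks": list(config.habitat_breaks)},
                           {"zones": p_z, "areas": p_a}, t0,
                           [str(w.message) for w in wlist],
                           total_suitable_1e4_km2=areas.total_suitable_1e4_km2)

        # ---- centroids -------------------------------------------------
        stage = "centroids"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            t0 = time.perf_counter()
            cen = habitat.mean_center(suit, config.centroid_threshold,
                                      config.centroid_weighting, "current")
            p = out / "centroids.csv"
            pd.DataFrame([vars(cen)]).to_csv(p, index=False)
            manifest.stage("centroids", {"threshold": config.centroid_threshold,
                                         "weighting": config.centroid_weighting},
                           {"centroids": p}, t0,
                           [str(w.message) for w in wlist],
                           lon=cen.lon, lat=cen.lat)

        # ---- quality stages -------------------------------------------
        if compounds is None or len(compound_names) == 0:
            manifest.skipped("screen", "no compound table")
            manifest.skipped("krige", "no compound table")
            manifest.skipped("integrate", "no compound table")
        else:
            stage = "screen"
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                t0 = time.perf_counter()
                from .raster import extract_at_points
                env_at_sites = extract_at_points(stack, compounds["lon"],
                                                 compounds["lat"])
                site_table = pd.concat(
                    [compounds.reset_index(drop=True),
                     env_at_sites[stack.codes].reset_index(drop=True)], axis=1)
                screen = geostat.spearman_screen(site_table, compound_names,
                                                 stack.codes, config.alpha)
                p = out / "spearman_screen.csv"
                screen.table.to_csv(p, index=False)
                manifest.stage("screen", {"alpha": config.alpha},
                               {"screen": p}, t0,
                               [str(w.message) for w in wlist],
                               selected={c: screen.selected(c)
                                         for c in compound_names})

            stage = "krige"
            kriged: dict[str, RasterGrid] = {}
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                t0 = time.perf_counter()
                outputs = {}
                loo_rows = []
                for comp in compound_names:
                    sel = screen.table[(screen.table["compound"] == comp)
                                       & (screen.table["p"] < config.alpha)]
                    sel = sel.reindex(sel["rho"].abs().sort_values(
                        ascending=False).index)
                    secondaries = sel["variable"].tolist()[:config.max_secondaries]
                    lmc = geostat.fit_lmc(site_table, comp, secondaries,
                                          family=config.variogram_family)
                    pred, se = geostat.cokrige_grid(lmc, site_table, stack.spec,
                                                    mask=stack.valid_mask())
                    loo = geostat.loo_validate(lmc, site_table)
                    loo_rows.append({"compound": comp,
                                     "mean_error": loo.mean_error,
                                     "rmse": loo.rmse,
                                     "standardized_rmse": loo.standardized_rmse,
                                     "secondaries": ";".join(secondaries)})
                    kriged[comp] = pred
                    pp = out / f"kriged_{comp}.asc"
                    ps = out / f"kriged_{comp}_se.asc"
                    write_raster(pred, pp)
                    write_raster(se, ps)
                    outputs[f"{comp}_pred"] = pp
                    outputs[f"{comp}_se"] = ps
                p_loo = out / "loo_report.csv"
                pd.DataFrame(loo_rows).to_csv(p_loo, index=False)
                outputs["loo"] = p_loo
                manifest.stage("krige", {"family": config.variogram_family},
                               outputs, t0, [str(w.message) for w in wlist])

            stage = "integrate"
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                t0 = time.perf_counter()
                normed = [zoning.normalize01(kriged[c]) for c in compound_names]
                quality = zoning.fuse_quality(normed, config.fusion_rule)
                cfg = zoning.IntegrationConfig(
                    weight_ecological=config.weight_ecological,
                    weight_quality=config.weight_quality,
                    fusion_rule=config.fusion_rule, jenks_k=config.jenks_k)
                index = zoning.integrate(suit, quality, cfg)
                jb = zoning.jenks_breaks(index.values, config.jenks_k,
                                         seed=_stage_seed(config.seed, "integrate"))
                classified = zoning.classify_index(index, jb)
                p_i = out / "integrated_index.asc"
                p_z = out / "quality_zones.asc"
                p_a = out / "quality_areas.csv"
                write_raster(index, p_i)
                write_raster(classified.zoning.zones, p_z)
                classified.areas.to_frame().to_csv(p_a, index=False)
                manifest.stage("integrate",
                               {"weights": [config.weight_ecological,
                                            config.weight_quality],
                                "fusion": config.fusion_rule,
                                "jenks_k": config.jenks_k,
                                "breaks": jb.breaks},
                               {"index": p_i, "zones": p_z, "areas": p_a},
                               t0, [str(w.message) for w in wlist])
    except Exception as exc:
        manifest.data["failed_stage"] = stage
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest.data


def _subset_design(design, variables: list[str]):
    from .occurrences import DesignTable
    cols = ["label", "lon", "lat"] + list(variables)
    return DesignTable(design.table[cols].copy(), variables=list(variables),
                       background_n=design.background_n)
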