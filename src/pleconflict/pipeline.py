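"""End-to-end orchestration: synthetic landscape -> PLE accounting ->
conflict measurement -> calibration -> multi-scenario simulation ->
conflict-transition zoning.

Every stage is an ordinary function usable on its own; :func:`run_pipeline`
chains them, writes all artifacts (TIFF rasters, CSV tables, YAML scenario
dumps) under an output directory and records a JSON manifest with seeds and
content hashes so a rerun with the same configuration is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import conflict_metrics as cm
from . import flus_core as flus
from . import ple_accounting as ple
from . import scenarios_zoning as sz
from .raster import Raster, write_raster
from .synthetic_landscape import (
    SynthConfig,
    evolve_landuse,
    gen_drivers,
    gen_landuse,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run on a synthetic landscape."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    date_t1: str = "t1"
    date_t2: str = "t2"
    date_future: str = "t3"
    scenarios: tuple = ("ND", "CL", "EP")
    zoning_scenario: str = "CL"
    unit_size_m: float = 1000.0
    connectivity: int = 8
    pool: str = "joint"
    ann_hidden: int = 12
    ann_sample_n: int | None = None
    ca_window: int = 3
    ca_max_iter: int = 300
    inertia_convention: str = "printed"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        if "true_transition" in synth_raw:
            synth_raw["true_transition"] = np.asarray(synth_raw["true_transition"])
        if "grid_shape" in synth_raw:
            synth_raw["grid_shape"] = tuple(synth_raw["grid_shape"])
        if "class_proportions" in synth_raw:
            synth_raw["class_proportions"] = tuple(synth_raw["class_proportions"])
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(synth=SynthConfig(**synth_raw), **raw)


def restriction_mask(lu: Raster, kind: str | None, seed: int = 0) -> np.ndarray:
    """Synthetic stand-in for a planning restriction layer.

    ``ecological_reserve`` protects woodland and grassland cells;
    ``basic_farmland`` protects the spatially coherent half of the
    cultivated cells (selected by a smoothed seeded field, mimicking a
    contiguous protection zone).  These are synthetic constructions, not
    read from any planning database.
    """
    if kind is None:
        return np.zeros(lu.shape, dtype=bool)
    if kind == "ecological_reserve":
        return np.isin(lu.data, (2, 3))
    if kind == "basic_farmland":
        rng = np.random.default_rng(seed + 0xFA2)
        smooth = ndimage.gaussian_filter(rng.standard_normal(lu.shape), sigma=10)
        cultivated = lu.data == 1
        cut = np.quantile(smooth[cultivated], 0.5)
        return cultivated & (smooth >= cut)
    raise ValueError(f"unknown restriction kind {kind!r}")


def scenario_demand(
    tm: flus.TransitionMatrix, spec: sz.ScenarioSpec, state: np.ndarray, steps: int = 1
) -> np.ndarray:
    """Demand vector (cells) for one scenario from a calibrated Markov model.

    The calibrated matrix is masked by the scenario's allowance matrix:
    probability on forbidden moves is returned to the diagonal (the cell
    stays put), then the state is projected.  The resulting demand is
    exactly realizable by allowed conversions, which keeps the allocation
    problem feasible under every scenario's rules.
    """
    P = tm.P * spec.allowance
    np.fill_diagonal(P, np.diag(P) + (1.0 - P.sum(axis=1)))
    masked = flus.TransitionMatrix(P, tm.interval_years)
    demand = flus.project_demand(masked, state, tm.interval_years * steps)
    # integerize conserving the total
    total = int(round(demand.sum()))
    cells = np.floor(demand).astype(int)
    order = np.argsort(-(demand - cells))
    cells[order[: total - cells.sum()]] += 1
    return cells


def simulate_scenario(
    lu_base: Raster,
    drivers: np.ndarray,
    model: flus.SuitabilityModel,
    tm: flus.TransitionMatrix,
    spec: sz.ScenarioSpec,
    cfg: RunConfig,
) -> flus.AllocationResult:
    """Run the CA for one scenario from the base-date raster."""
    demand = scenario_demand(tm, spec, lu_base.class_counts())
    restriction = restriction_mask(lu_base, spec.restriction, seed=cfg.seed)
    sp = model.predict(drivers)
    return flus.allocate(
        lu_base,
        sp,
        demand,
        spec.allowance,
        np.asarray(spec.neighborhood_weights),
        restriction=restriction,
        window=cfg.ca_window,
        max_iter=cfg.ca_max_iter,
        inertia_convention=cfg.inertia_convention,
        seed=cfg.seed + 211,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    def _save_raster(raster, name):
        path = write_raster(raster, out / name)
        artifacts[name] = str(path.relative_to(out))

    def _save_csv(frame, name):
        frame.to_csv(out / name)
        artifacts[name] = name

    try:
        stage = _stage("synth")
        scfg = replace(cfg.synth, seed=cfg.seed)
        drivers = gen_drivers(scfg)
        lu_t1 = gen_landuse(scfg, drivers)
        lu_t2 = evolve_landuse(lu_t1, scfg.true_transition, scfg, drivers, seed=cfg.seed + 1)
        _save_raster(lu_t1, f"landuse_{cfg.date_t1}.tif")
        _save_raster(lu_t2, f"landuse_{cfg.date_t2}.tif")
        np.save(out / "drivers.npy", drivers)
        artifacts["drivers.npy"] = "drivers.npy"
        _done(stage)

        stage = _stage("ple")
        ple_t1 = ple.classify_ple(lu_t1)
        ple_t2 = ple.classify_ple(lu_t2)
        _save_raster(ple_t1, f"ple_{cfg.date_t1}.tif")
        _save_raster(ple_t2, f"ple_{cfg.date_t2}.tif")
        lu_areas = ple.area_table({cfg.date_t1: lu_t1, cfg.date_t2: lu_t2})
        ple_areas = ple.area_table({cfg.date_t1: ple_t1, cfg.date_t2: ple_t2}, kind="ple")
        _save_csv(lu_areas, "landuse_areas_km2.csv")
        _save_csv(ple.change_table(lu_areas), "landuse_changes.csv")
        _save_csv(ple_areas, "ple_areas_km2.csv")
        _save_csv(ple.proportion_table(ple_areas), "ple_proportions_pct.csv")
        _done(stage)

        stage = _stage("conflict")
        units = {
            cfg.date_t1: cm.conflict_units(ple_t1, cfg.unit_size_m, cfg.connectivity),
            cfg.date_t2: cm.conflict_units(ple_t2, cfg.unit_size_m, cfg.connectivity),
        }
        _done(stage)

        stage = _stage("calibrate")
        tm = flus.fit_markov(lu_t1, lu_t2)
        model = flus.train_suitability(
            lu_t2,
            drivers,
            sample_n=cfg.ann_sample_n,
            seed=cfg.seed + 7,
            hidden=cfg.ann_hidden,
        )
        pd.DataFrame(tm.P).to_csv(out / "transition_matrix.csv")
        artifacts["transition_matrix.csv"] = "transition_matrix.csv"
        _done(stage)

        stage = _stage("simulate")
        specs = sz.builtin_scenarios()
        sim_results: dict[str, flus.AllocationResult] = {}
        for name in cfg.scenarios:
            spec = specs[name]
            result = simulate_scenario(lu_t2, drivers, model, tm, spec, cfg)
            sim_results[name] = result
            _save_raster(result.landuse, f"sim_{cfg.date_future}_{name}.tif")
            trace = pd.DataFrame(
                [
                    {
                        "iteration": h["iteration"],
                        **{f"gap_{c}": g for c, g in enumerate(h["gap"], start=1)},
                        **{
                            f"inertia_{c}": v
                            for c, v in enumerate(h["inertia"], start=1)
                        },
                    }
                    for h in result.history
                ]
            )
            _save_csv(trace.set_index("iteration"), f"trace_{name}.csv")
            (out / f"scenario_{name}.yaml").write_text(
                yaml.safe_dump(sz.scenario_to_dict(spec))
            )
            artifacts[f"scenario_{name}.yaml"] = f"scenario_{name}.yaml"
        _done(stage)

        stage = _stage("conflict_future")
        for name, result in sim_results.items():
            ple_sim = ple.classify_ple(result.landuse)
            units[f"{cfg.date_future}_{name}"] = cm.conflict_units(
                ple_sim, cfg.unit_size_m, cfg.connectivity
            )
        units = cm.normalize_scci(units, pool=cfg.pool)
        for date, frame in units.items():
            _save_csv(frame, f"conflict_units_{date}.csv")
            _save_csv(cm.level_summary(frame), f"conflict_levels_{date}.csv")
            _save_csv(cm.level_by_ple_summary(frame), f"conflict_by_ple_{date}.csv")
            _save_raster(cm.level_raster(frame, cfg.unit_size_m), f"levels_{date}.tif")
        _done(stage)

        stage = _stage("zone")
        manifest_zoning = {}
        if cfg.zoning_scenario in sim_results:
            future_key = f"{cfg.date_future}_{cfg.zoning_scenario}"
            codes = sz.transition_codes(
                units[cfg.date_t2]["level"], units[future_key]["level"]
            )
            zones = sz.assign_zones(codes)
            _save_csv(sz.transition_count_matrix(codes), "transition_counts.csv")
            _save_csv(zones, "zones.csv")
            _save_csv(
                sz.zone_summary(zones, unit_area_km2=(cfg.unit_size_m / 1000.0) ** 2),
                "zone_summary.csv",
            )
            manifest_zoning = {"scenario": cfg.zoning_scenario}
        _done(stage)
    except Exception as exc:  # re-raise with stage context, per contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _jsonable_config(cfg),
        "seed": cfg.seed,
        "artifacts": artifacts,
        "hashes": {name: _sha256(out / name) for name in artifacts},
        "simulation": {
            name: {
                "converged": r.converged,
                "iterations": r.iterations,
                "residual": r.residual.tolist(),
            }
            for name, r in sim_results.items()
        },
        "zoning": manifest_zoning,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable_config(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["synth"]["true_transition"] = np.asarray(
        d["synth"]["true_transition"]
    ).tolist()
    d["synth"]["grid_shape"] = list(d["synth"]["grid_shape"])
    d["synth"]["class_proportions"] = list(d["synth"]["class_proportions"])
    d["scenarios"] = list(d["scenarios"])
    return d
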