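"""End-to-end survey analysis pipeline with file-based stage artifacts.

Stages communicate only through serialized artifacts under the output
directory, so any stage can be re-run in isolation:

    inputs/       observations.csv, transects.csv, landscape.geojson,
                  grid.csv, extras.csv, truth ledgers (simulate mode)
    detection/    detection_<epoch>.json
    density/      density_report.csv, estimates.json
    change/       change_report.json
    spatial/      hotspots.csv, kriged_surface.csv
    gam/          covariates_<epoch>.csv, gam_report.csv, partial_effects.csv
    manifest.json, report.md
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import covariates as cov
from . import density as dens
from . import detection as det
from . import gam as gammod
from . import hotspots as hot
from . import kriging as krig
from .covariates import Landscape
from .io import (read_landscape_geojson, read_survey, pool_by_location,
                 write_landscape_geojson)
from .simulate import SimulationConfig, simulate_two_epoch_survey

log = logging.getLogger("ituri")

ARTIFACTS = [
    "detection/detection_1995.json",
    "detection/detection_2006.json",
    "density/density_report.csv",
    "change/change_report.json",
    "spatial/hotspots.csv",
    "spatial/kriged_surface.csv",
    "gam/gam_report.csv",
    "gam/partial_effects.csv",
]


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (JSON-serializable).

    In simulate mode the synthetic generator provides the inputs; otherwise
    ``observations`` / ``transects`` / ``landscape`` / ``grid`` paths must
    exist. Thresholds default to the conventional values: 1.96 hotspot
    z-cutoff, 0.6 collinearity cutoff, 0.1 "same-change" tolerance (density
    units per ha), alpha 0.05.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    observations: str | None = None
    transects: str | None = None
    landscape: str | None = None
    grid: str | None = None
    extras: str | None = None
    epochs: tuple[str, str] = ("1995", "2006")
    truncation_w: float | None = None
    epsilon_same: float = 0.1
    alpha: float = 0.05
    hotspot_z: float = 1.96
    collinearity_r: float = 0.6
    kriging_step_km: float = 10.0
    gistar_band_km: float | None = None
    gam_smooth_terms: tuple[str, ...] = ("deforestation_index", "dist_hq",
                                         "dist_town", "dist_boundary", "dist_road")
    gam_linear_terms: tuple[str, ...] = ("slope", "hab_hill", "hab_swamp")
    gam_k: int = 5
    conversion: dens.ConversionParams = field(default_factory=dens.ConversionParams)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "sim" in d and d["sim"] is not None:
            d["sim"] = SimulationConfig(**{**d["sim"]})
        if "conversion" in d:
            d["conversion"] = dens.ConversionParams(**d["conversion"])
        for key in ("epochs", "gam_smooth_terms", "gam_linear_terms"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if not cfg.simulate:
            for p in (cfg.observations, cfg.transects):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def resolved_sim(self) -> SimulationConfig:
        if self.sim is not None:
            return dataclasses.replace(self.sim, seed=self.seed)
        return SimulationConfig(seed=self.seed)


def _outdir(cfg: PipelineConfig, *parts) -> Path:
    p = Path(cfg.out_dir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_inputs(cfg: PipelineConfig) -> None:
    """Materialize inputs: simulate-and-write, or verify supplied paths."""
    if not cfg.simulate:
        return
    sim = cfg.resolved_sim()
    world = simulate_two_epoch_survey(sim)
    ds1, ds2 = world["ds1"], world["ds2"]
    obs_rows = [
        {"transect_id": o.transect_id, "epoch": o.epoch,
         "perpendicular_distance_m": f"{o.perpendicular_distance:.4f}"}
        for ds in (ds1, ds2) for o in ds.observations
    ]
    pd.DataFrame(obs_rows, columns=["transect_id", "epoch", "perpendicular_distance_m"]
                 ).to_csv(_outdir(cfg, "inputs", "observations.csv"), index=False)
    tr_rows = [
        {"transect_id": t.transect_id, "location_id": t.location_id,
         "x_km": f"{t.origin[0]:.4f}", "y_km": f"{t.origin[1]:.4f}",
         "bearing_deg": f"{t.bearing:.4f}", "length_km": f"{t.length:.4f}"}
        for t in ds1.transects
    ]
    pd.DataFrame(tr_rows).to_csv(_outdir(cfg, "inputs", "transects.csv"), index=False)

    land = world["landscape"]
    write_landscape_geojson(
        {"park_boundary": land.park_boundary, "road": land.roads,
         "village": land.villages, "town": land.towns,
         "headquarters": land.headquarters},
        _outdir(cfg, "inputs", "landscape.geojson"),
    )
    land.deforestation_grid.to_csv(_outdir(cfg, "inputs", "grid.csv"), index=False)
    world["extras"].to_csv(_outdir(cfg, "inputs", "extras.csv"))
    for key in ("ledger1", "ledger2"):
        _outdir(cfg, "inputs", f"{key}.json").write_text(world[key].to_json())


def _input_paths(cfg: PipelineConfig) -> dict:
    if cfg.simulate:
        base = Path(cfg.out_dir) / "inputs"
        return {"observations": base / "observations.csv",
                "transects": base / "transects.csv",
                "landscape": base / "landscape.geojson",
                "grid": base / "grid.csv",
                "extras": base / "extras.csv"}
    return {"observations": cfg.observations, "transects": cfg.transects,
            "landscape": cfg.landscape, "grid": cfg.grid, "extras": cfg.extras}


def _load_epoch(cfg: PipelineConfig, epoch: str):
    paths = _input_paths(cfg)
    return read_survey(paths["observations"], paths["transects"], epoch=epoch)


def _load_landscape(cfg: PipelineConfig) -> Landscape:
    paths = _input_paths(cfg)
    roles = read_landscape_geojson(paths["landscape"])
    extras = None
    if paths["extras"] and Path(paths["extras"]).exists():
        extras = pd.read_csv(paths["extras"], index_col="transect_id")
    return Landscape(
        park_boundary=roles["park_boundary"][0],
        roads=roles.get("road", []),
        villages=roles.get("village", []),
        towns=roles.get("town", []),
        headquarters=roles.get("headquarters", [None])[0],
        deforestation_grid=pd.read_csv(paths["grid"]),
        extra_covariates=extras,
    )


def stage_detect(cfg: PipelineConfig) -> None:
    """Fit the three detection families per epoch; keep the AIC winner."""
    for epoch in cfg.epochs:
        ds = _load_epoch(cfg, epoch)
        x = ds.distances()
        candidates = []
        for fam in det.FAMILIES:
            try:
                candidates.append(det.fit_detection(x, fam, w=cfg.truncation_w))
            except det.DetectionFitError as exc:  # pragma: no cover - diagnostic path
                log.warning("detection fit failed for %s/%s: %s", epoch, fam, exc)
        best = det.select_model(candidates)
        _outdir(cfg, "detection", f"detection_{epoch}.json").write_text(best.to_json())
        log.info("epoch %s: selected %s detection (ESW %.2f m)", epoch, best.family, best.esw)


def _load_detection(cfg: PipelineConfig, epoch: str) -> det.DetectionModel:
    return det.DetectionModel.from_json(
        _outdir(cfg, "detection", f"detection_{epoch}.json").read_text()
    )


def stage_density(cfg: PipelineConfig) -> None:
    """Per-epoch density estimates and the survey-report table."""
    estimates = []
    for epoch in cfg.epochs:
        ds = _load_epoch(cfg, epoch)
        model = _load_detection(cfg, epoch)
        pooled = pool_by_location(ds)
        est = dens.estimate_from_pooled(pooled, esw_m=model.esw,
                                        cv_esw_percent=100.0 * model.cv_esw,
                                        epoch=epoch, alpha=cfg.alpha)
        estimates.append(est)
    dens.density_report_table(estimates).to_csv(
        _outdir(cfg, "density", "density_report.csv"), index=False)
    _outdir(cfg, "density", "estimates.json").write_text(
        json.dumps([dataclasses.asdict(e) for e in estimates], indent=2))


def _load_estimates(cfg: PipelineConfig) -> list[dens.DensityEstimate]:
    raw = json.loads(_outdir(cfg, "density", "estimates.json").read_text())
    return [dens.DensityEstimate(**{**r, "ci": tuple(r["ci"])}) for r in raw]


def stage_change(cfg: PipelineConfig) -> None:
    """Two-survey z-test, per-location change classes, conversions."""
    e1, e2 = _load_estimates(cfg)
    z, p, pct = dens.ztest_change(e1, e2)
    pooled = {}
    for epoch in cfg.epochs:
        ds = _load_epoch(cfg, epoch)
        model = _load_detection(cfg, epoch)
        tab = pool_by_location(ds)
        pooled[epoch] = tab["count"] / (2.0 * model.esw * tab["effort_km"] * 0.1)
    d1, d2 = pooled[cfg.epochs[0]].align(pooled[cfg.epochs[1]], join="inner")
    deltas = (d2 - d1).to_numpy()
    counts, chi2, p_chi = dens.classify_changes(deltas, epsilon=cfg.epsilon_same)
    conv = cfg.conversion
    eleph1 = dens.dung_to_elephants(e1.density, conv)
    eleph2 = dens.dung_to_elephants(e2.density, conv)
    pop1 = dens.extrapolate_population(eleph1, conv.area)
    pop2 = dens.extrapolate_population(eleph2, conv.area)
    report = {
        "epochs": list(cfg.epochs),
        "z": z, "p_one_sided": p, "percent_decline": pct,
        "per_location": {"declined": counts[0], "same": counts[1],
                         "increased": counts[2], "epsilon": cfg.epsilon_same},
        "chi_square": chi2, "p_chi": p_chi,
        "elephants_per_km2": [eleph1, eleph2],
        "population": [pop1, pop2],
        "population_loss": pop1 - pop2,
    }
    _outdir(cfg, "change", "change_report.json").write_text(json.dumps(report, indent=2))


def stage_spatial(cfg: PipelineConfig) -> None:
    """Gi* hotspot tables and ordinary-kriging surfaces per epoch."""
    hot_frames, krig_frames = [], []
    for epoch in cfg.epochs:
        ds = _load_epoch(cfg, epoch)
        model = _load_detection(cfg, epoch)
        tab = pool_by_location(ds)
        d_loc = (tab["count"] / (2.0 * model.esw * tab["effort_km"] * 0.1)).to_numpy()
        pts = tab[["x_km", "y_km"]].to_numpy()
        gi = hot.getis_ord_gistar(pts, d_loc, band_km=cfg.gistar_band_km,
                                  crit_z=cfg.hotspot_z, location_ids=tab.index)
        gi.insert(0, "epoch", epoch)
        hot_frames.append(gi)
        ok = krig.OrdinaryKriging().fit(pts, d_loc)
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        grid = krig.regular_grid(xmin, xmax, ymin, ymax, cfg.kriging_step_km)
        surf = ok.surface(grid).to_frame()
        surf.insert(0, "epoch", epoch)
        krig_frames.append(surf)
    pd.concat(hot_frames).to_csv(_outdir(cfg, "spatial", "hotspots.csv"), index=False)
    pd.concat(krig_frames).to_csv(_outdir(cfg, "spatial", "kriged_surface.csv"),
                                  index=False)


def stage_covariates(cfg: PipelineConfig) -> None:
    """Per-transect covariate tables (epoch-specific deforestation column)."""
    landscape = _load_landscape(cfg)
    for i, epoch in enumerate(cfg.epochs):
        ds = _load_epoch(cfg, epoch)
        col = "nonforest_t1_km2" if i == 0 else "nonforest_t2_km2"
        tab = cov.covariate_table(ds, landscape, epoch_col=col)
        tab.to_csv(_outdir(cfg, "gam", f"covariates_{epoch}.csv"))


def stage_dsm(cfg: PipelineConfig) -> None:
    """Density-surface GAMs: univariate ranking, composites, partial effects."""
    gam_rows, pe_frames = [], []
    for epoch in cfg.epochs:
        ds = _load_epoch(cfg, epoch)
        model = _load_detection(cfg, epoch)
        tab = pd.read_csv(_outdir(cfg, "gam", f"covariates_{epoch}.csv"),
                          index_col="transect_id")
        counts = pd.Series(0, index=tab.index, dtype=float)
        for ob in ds.observations:
            counts[ob.transect_id] += 1
        lengths = pd.Series({t.transect_id: t.length for t in ds.transects})
        offset = gammod.effort_offset(model.esw, lengths.reindex(tab.index))
        numeric = [c for c in (*cfg.gam_smooth_terms, *cfg.gam_linear_terms)
                   if c in tab.columns]
        retained, _ = cov.collinearity_screen(tab[numeric], r_max=cfg.collinearity_r,
                                              priority=tuple(numeric))
        uni = [gammod.s(c, k=cfg.gam_k) if c in cfg.gam_smooth_terms
               else gammod.linear(c) for c in retained]
        human = [t for t in uni if t.name in cfg.gam_smooth_terms]
        composite = {f"{epoch} human covariates only": human,
                     f"{epoch} minimal adequate incl habitat": uni}
        rep = gammod.model_comparison_table(tab, counts.to_numpy(), offset,
                                   univariate=uni, composite=composite)
        rep.insert(0, "epoch", epoch)
        gam_rows.append(rep)
        if human:
            design = gammod.build_design(tab, human)
            _, fit = gammod.select_smoothing(counts.to_numpy(), offset, design)
            for t in human:
                pe = fit.partial_effect(t.name)
                pe.insert(0, "covariate", t.name)
                pe.insert(0, "epoch", epoch)
                pe_frames.append(pe)
    pd.concat(gam_rows).to_csv(_outdir(cfg, "gam", "gam_report.csv"), index=False)
    pd.concat(pe_frames).to_csv(_outdir(cfg, "gam", "partial_effects.csv"), index=False)


def stage_report(cfg: PipelineConfig) -> None:
    """Regenerate the human-readable report from cached artifacts only."""
    lines = ["# Survey analysis report", ""]
    dens_csv = _outdir(cfg, "density", "density_report.csv")
    if dens_csv.exists():
        lines += ["## Density estimates", "", pd.read_csv(dens_csv).to_markdown(index=False), ""]
    chg = _outdir(cfg, "change", "change_report.json")
    if chg.exists():
        r = json.loads(chg.read_text())
        lines += [
            "## Change between surveys", "",
            f"- z = {r['z']:.3f}, one-sided p = {r['p_one_sided']:.3f}",
            f"- percent decline = {r['percent_decline']:.0f}%",
            f"- per-location changes (declined/same/increased): "
            f"{r['per_location']['declined']}/{r['per_location']['same']}/"
            f"{r['per_location']['increased']}, chi-square = {r['chi_square']:.4f} "
            f"(p = {r['p_chi']:.3f})",
            f"- elephants per km^2: {r['elephants_per_km2'][0]:.2f} -> "
            f"{r['elephants_per_km2'][1]:.2f}",
            f"- population: {r['population'][0]} -> {r['population'][1]} "
            f"(loss {r['population_loss']})", "",
        ]
    gam_csv = _outdir(cfg, "gam", "gam_report.csv")
    if gam_csv.exists():
        lines += ["## Density-surface models", "",
                  pd.read_csv(gam_csv).to_markdown(index=False), ""]
    _outdir(cfg, "report.md").write_text("\n".join(lines))


STAGES = {
    "simulate": stage_inputs,
    "detect": stage_detect,
    "density": stage_density,
    "change": stage_change,
    "hotspots": stage_spatial,
    "krige": stage_spatial,
    "covariates": stage_covariates,
    "dsm": stage_dsm,
    "report": stage_report,
}

_ORDER = ["simulate", "detect", "density", "change", "hotspots", "covariates",
          "dsm", "report"]


def _write_manifest(cfg: PipelineConfig) -> None:
    import ituri

    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "ituri",
        "version": getattr(ituri, "__version__", "0"),
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "artifacts": ARTIFACTS,
    }
    _outdir(cfg, "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory.

    A stage failure aborts with the stage name and cause; artifacts from
    completed stages are retained alongside a ``FAILED`` marker.
    """
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    for name in _ORDER:
        try:
            log.info("stage %s", name)
            STAGES[name](cfg)
        except Exception as exc:
            _outdir(cfg, "FAILED").write_text(f"stage {name}: {exc}")
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    _write_manifest(cfg)
    return Path(cfg.out_dir)
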