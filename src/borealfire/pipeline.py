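"""End-to-end pipeline: simulate -> track -> filter -> grid -> cluster ->
drivers -> report.

Every stage reads the previous stage's declared artifacts from the
output directory and writes its own, so any prefix is re-runnable in
isolation. A JSON manifest lists all files with checksums and a config
echo. All randomness flows from the single config seed via named
per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from borealfire import io as bfio
from borealfire.drivers import (
    annual_max_month_vpd,
    annual_trend,
    climatological_max_vpd,
    driver_correlations,
    fit_regime_models,
    interannual_sensitivity,
    tukey_hsd,
)
from borealfire.filters import FilterConfig, apply_filters
from borealfire.pyroregions import (
    assign_clusters,
    build_features,
    fit_gmm_bic,
    name_clusters,
)
from borealfire.regime import (
    AggregationMode,
    aggregate_regime,
    make_grid,
    raster_to_cells,
)
from borealfire.synthetic import (
    LandCoverGrid,
    WorldConfig,
    gen_detections,
    gen_driver_stack,
    gen_flares,
    gen_landcover,
    gen_truth_fires,
)
from borealfire.synthetic.drivers_gen import DriverStack
from borealfire.tracking import TrackerConfig, bin_timesteps, track_events

log = logging.getLogger(__name__)

STAGES = ["simulate", "track", "filter", "grid", "cluster", "drivers", "report"]

DRIVER_COLUMNS = ["vpd_max_month", "lightning", "biomass",
                  "wilderness_pct", "crop_pasture_pct"]


@dataclass(frozen=True)
class GridSection:
    radius_km: float = 250.0
    overlap_fraction: float = 0.30


@dataclass(frozen=True)
class ClusterSection:
    k_min: int = 1
    k_max: int = 9
    n_init: int = 10
    rule: str = "max"          # "max" | "elbow:<eps>" | "fixed:<k>"
    min_fires: int = 1

    def select_rule(self):
        if self.rule == "max":
            return "max"
        kind, _, arg = self.rule.partition(":")
        if kind == "elbow":
            return ("elbow", float(arg))
        if kind == "fixed":
            return ("fixed", int(arg))
        raise ValueError(f"unknown cluster rule {self.rule!r}")


@dataclass(frozen=True)
class DriverSection:
    min_fires: int = 5
    min_years: int = 3


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    synthetic: WorldConfig = field(default_factory=WorldConfig)
    tracker: TrackerConfig | None = None     # None: scaled to the lattice
    filters: FilterConfig = field(default_factory=FilterConfig)
    grid: GridSection = field(default_factory=GridSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    drivers: DriverSection = field(default_factory=DriverSection)

    def resolved_tracker(self) -> TrackerConfig:
        if self.tracker is not None:
            return self.tracker
        return TrackerConfig.for_spacing(self.synthetic.pixel_spacing)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["tracker"] = dataclasses.asdict(self.resolved_tracker())
        return out

    @classmethod
    def from_toml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        sections = {
            "synthetic": WorldConfig, "tracker": TrackerConfig,
            "filters": FilterConfig, "grid": GridSection,
            "cluster": ClusterSection, "drivers": DriverSection,
        }
        known = set(sections) | {"seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if seed is not None:
            kwargs["seed"] = int(seed)
        for name, klass in sections.items():
            if name not in raw:
                continue
            body = dict(raw[name])
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(body) - fields
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            for k, v in body.items():
                if isinstance(v, list):
                    body[k] = tuple(v)
            kwargs[name] = klass(**body)
        cfg = cls(**kwargs)
        # the pipeline seed overrides the synthetic section's seed
        return dataclasses.replace(
            cfg, synthetic=cfg.synthetic.with_(seed=kwargs.get("seed", cfg.seed)))


# ---------------------------------------------------------------------------

def _need(out: Path, fname: str, stage: str) -> Path:
    p = out / fname
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {fname!r}: run stage {stage!r} first")
    return p


# world rasters are stored as individual .npy files (bit-deterministic,
# unlike zipped archives whose entries carry wall-clock timestamps)
_WORLD_FIELDS = ["temperature", "dewpoint", "lightning", "biomass",
                 "wilderness", "crop_pasture"]


def _save_world(out: Path, lc, stack: DriverStack) -> list[str]:
    wdir = out / "world"
    wdir.mkdir(exist_ok=True)
    np.save(wdir / "lc_codes.npy", lc.codes)
    for name in _WORLD_FIELDS:
        np.save(wdir / f"{name}.npy", getattr(stack, name))
    for k, v in stack.fire_weather.items():
        np.save(wdir / f"fw_{k}.npy", v)
    for k, v in stack.tree_fractions.items():
        np.save(wdir / f"tree_{k}.npy", v)
    meta = {"lc_res": lc.res, "start_year": stack.start_year}
    (wdir / "meta.json").write_text(json.dumps(meta, sort_keys=True))
    return sorted(f"world/{p.name}" for p in wdir.iterdir())


def _load_world(out: Path, stage_hint: str = "simulate"):
    wdir = out / "world"
    if not (wdir / "meta.json").exists():
        raise FileNotFoundError(
            f"missing artifact 'world/': run stage {stage_hint!r} first")
    meta = json.loads((wdir / "meta.json").read_text())
    lc = LandCoverGrid(codes=np.load(wdir / "lc_codes.npy"),
                       res=float(meta["lc_res"]))
    fields = {n: np.load(wdir / f"{n}.npy") for n in _WORLD_FIELDS}
    fw = {p.stem[3:]: np.load(p) for p in wdir.glob("fw_*.npy")}
    tree = {p.stem[5:]: np.load(p) for p in wdir.glob("tree_*.npy")}
    return lc, DriverStack(res=float(meta["lc_res"]),
                           start_year=int(meta["start_year"]),
                           fire_weather=fw, tree_fractions=tree, **fields)


def stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    wc = cfg.synthetic
    lc = gen_landcover(wc)
    stack = gen_driver_stack(wc, lc)
    fires = gen_truth_fires(wc, lc, stack)
    flares = gen_flares(wc, lc)
    det = gen_detections(fires, flares, lc, wc)
    log.info("stage=simulate seed=%d fires=%d flares=%d detections=%d",
             wc.seed, len(fires), len(flares), len(det))
    bfio.write_detections(det, out / "detections.csv", out / "truth_labels.csv")
    flares.to_csv(out / "flares.csv", index=False)
    world_files = _save_world(out, lc, stack)
    pd.DataFrame([{
        "fid": f.fid, "x": f.x, "y": f.y, "year": f.year, "cause": f.cause,
        "final_area_km2": float(f.areas[-1]), "n_steps": f.n_steps,
    } for f in fires]).to_csv(out / "truth_fires.csv", index=False)
    return ["detections.csv", "truth_labels.csv", "flares.csv",
            "truth_fires.csv"] + world_files


def stage_track(cfg: PipelineConfig, out: Path) -> list[str]:
    det, rejects = bfio.read_detections(_need(out, "detections.csv", "simulate"))
    if len(rejects):
        rejects.to_csv(out / "detection_rejects.csv", index=False)
    lc, _ = _load_world(out)
    tracker = cfg.resolved_tracker()
    binned = bin_timesteps(det)
    atlas = track_events(binned, tracker, lc=lc, with_fireline=False)
    atlas.summarize(lc)
    frame = atlas.to_frame()
    log.info("stage=track seed=%d detections=%d events=%d",
             cfg.seed, len(det), len(frame))
    bfio.write_atlas_geojson(frame, out / "atlas.geojson")
    bfio.write_ignitions_geojson(atlas, out / "ignitions.geojson")
    return ["atlas.geojson", "ignitions.geojson"]


def stage_filter(cfg: PipelineConfig, out: Path) -> list[str]:
    frame = bfio.read_atlas_geojson(_need(out, "atlas.geojson", "track"))
    flares = pd.read_csv(_need(out, "flares.csv", "simulate"))
    filtered, report = apply_filters(frame, flares, cfg.filters)
    log.info("stage=filter seed=%d input=%d removed=%d survivors=%d",
             cfg.seed, report.n_input, sum(report.rule_counts.values()),
             len(report.survivors))
    bfio.write_atlas_geojson(filtered, out / "atlas_filtered.geojson")
    report.trace.to_csv(out / "filter_report.csv", index=False)
    with open(out / "filter_summary.json", "w") as fh:
        json.dump({"rule_counts": report.rule_counts,
                   "n_input": report.n_input,
                   "n_survivors": len(report.survivors)}, fh, indent=2)
    return ["atlas_filtered.geojson", "filter_report.csv", "filter_summary.json"]


def stage_grid(cfg: PipelineConfig, out: Path) -> list[str]:
    frame = bfio.read_atlas_geojson(_need(out, "atlas_filtered.geojson", "filter"))
    lc, _ = _load_world(out)
    wc = cfg.synthetic
    grid = make_grid(wc.domain_km, wc.cell_size, lc)
    radius = aggregate_regime(
        frame, grid, AggregationMode("radius", radius_km=cfg.grid.radius_km),
        n_years=wc.n_years, lc=lc)
    overlap = aggregate_regime(
        frame, grid,
        AggregationMode("overlap", overlap_fraction=cfg.grid.overlap_fraction),
        n_years=wc.n_years, lc=lc, per_year=True)
    log.info("stage=grid seed=%d cells=%d fires=%d", cfg.seed, len(grid), len(frame))
    radius.table.to_csv(out / "regime_radius.csv", index=False)
    overlap.table.to_csv(out / "regime_overlap.csv", index=False)
    overlap.per_year.to_csv(out / "regime_per_year.csv", index=False)
    bfio.write_regime_tidy(radius.table, out / "regime_tidy.csv",
                           per_year=overlap.per_year)
    return ["regime_radius.csv", "regime_overlap.csv", "regime_per_year.csv",
            "regime_tidy.csv"]


def stage_cluster(cfg: PipelineConfig, out: Path) -> list[str]:
    table = pd.read_csv(_need(out, "regime_radius.csv", "grid"))
    X, cell_ids, mean, scale = build_features(table, min_fires=cfg.cluster.min_fires)
    from borealfire.regime import REGIME_PROPERTIES

    model = fit_gmm_bic(
        X, k_range=range(cfg.cluster.k_min, cfg.cluster.k_max + 1),
        n_init=cfg.cluster.n_init, seed=cfg.seed,
        select_rule=cfg.cluster.select_rule(),
        feature_names=REGIME_PROPERTIES)
    model.scaler_mean, model.scaler_scale = mean, scale
    # assignments on raw features (transform reapplies the scaler)
    raw = table.set_index("cell_id").loc[cell_ids].reset_index()
    assignments = assign_clusters(
        model, raw[REGIME_PROPERTIES].to_numpy(dtype=float), cell_ids=cell_ids)
    names = name_clusters(model, table, assignments)
    label_to_code = dict(zip(names["label"], names["code"]))
    assignments["code"] = assignments["label"].map(label_to_code).fillna("NA")
    log.info("stage=cluster seed=%d n_cells=%d k=%d family=%s",
             cfg.seed, len(X), model.k, model.family)
    model.bic_table.to_csv(out / "bic_table.csv", index=False)
    assignments.to_csv(out / "assignments.csv", index=False)
    names.to_csv(out / "pyroregion_names.csv", index=False)
    return ["bic_table.csv", "assignments.csv", "pyroregion_names.csv"]


def stage_drivers(cfg: PipelineConfig, out: Path) -> list[str]:
    overlap = pd.read_csv(_need(out, "regime_overlap.csv", "grid"))
    per_year = pd.read_csv(_need(out, "regime_per_year.csv", "grid"))
    assignments = pd.read_csv(_need(out, "assignments.csv", "cluster"))
    lc, stack = _load_world(out)
    wc = cfg.synthetic
    grid = make_grid(wc.domain_km, wc.cell_size, lc)

    vmax, _ = climatological_max_vpd(stack.monthly_vpd())
    table = overlap.copy()
    table["vpd_max_month"] = raster_to_cells(vmax, lc.res, grid)[table["cell_id"]]
    table["lightning"] = raster_to_cells(stack.lightning, lc.res, grid)[table["cell_id"]]
    table["biomass"] = raster_to_cells(stack.biomass, lc.res, grid)[table["cell_id"]]
    table["wilderness_pct"] = 100 * raster_to_cells(
        stack.wilderness, lc.res, grid)[table["cell_id"]]
    table["crop_pasture_pct"] = 100 * raster_to_cells(
        stack.crop_pasture, lc.res, grid)[table["cell_id"]]
    table.to_csv(out / "driver_table.csv", index=False)

    groups = table["cell_id"].map(
        assignments.set_index("cell_id")["code"]).rename("group")
    corr = driver_correlations(
        table, DRIVER_COLUMNS,
        ["burned_pct_yr", "fire_density", "mean_size_km2",
         "mean_duration_d", "mean_frp95_wm2"],
        groups=groups)
    corr.to_csv(out / "correlations.csv", index=False)

    responses = [r for r in ("burned_pct_yr", "fire_density", "mean_size_km2")
                 if len(table[[r] + DRIVER_COLUMNS].dropna())
                 >= 10 * len(DRIVER_COLUMNS)]
    skipped = {"burned_pct_yr", "fire_density", "mean_size_km2"} - set(responses)
    if skipped:
        log.info("stage=drivers skipping undersized model responses: %s",
                 sorted(skipped))
    models = (fit_regime_models(table, responses, DRIVER_COLUMNS)
              if responses else pd.DataFrame())
    models.to_csv(out / "regime_models.csv", index=False)

    tuk_rows = []
    labelled = groups.notna() & (groups != "NA")
    for drv in DRIVER_COLUMNS:
        try:
            t = tukey_hsd(table.loc[labelled, drv], groups[labelled])
        except ValueError:
            continue
        t.insert(0, "variable", drv)
        tuk_rows.append(t)
    (pd.concat(tuk_rows, ignore_index=True) if tuk_rows else pd.DataFrame()
     ).to_csv(out / "tukey.csv", index=False)

    vpd_annual = annual_max_month_vpd(stack.monthly_vpd())
    ann_rows = []
    for yidx in range(stack.n_years):
        vals = raster_to_cells(vpd_annual[yidx], lc.res, grid)
        ann_rows.append(pd.DataFrame({
            "cell_id": np.arange(len(vals)),
            "year": stack.start_year + yidx,
            "vpd_max_month": vals,
        }))
    ann_vpd = pd.concat(ann_rows, ignore_index=True)
    annual = per_year.merge(ann_vpd, on=["cell_id", "year"], how="right")
    annual["n_fires"] = annual["n_fires"].fillna(0)
    annual["burned_pct"] = annual["burned_pct"].fillna(0.0)
    cell_groups = assignments.set_index("cell_id")["code"]
    inter = interannual_sensitivity(
        annual, cell_groups,
        properties=["burned_pct", "n_fires", "mean_size_km2"],
        min_fires=cfg.drivers.min_fires, min_years=cfg.drivers.min_years)
    inter.to_csv(out / "interannual.csv", index=False)

    counts = per_year.groupby("year")["n_fires"].sum()
    trend = {}
    if len(counts) >= 3:
        slope, p = annual_trend(counts)
        trend = {"fire_number_trend_per_yr": slope, "p": p}
    with open(out / "trend.json", "w") as fh:
        json.dump(trend, fh, indent=2)
    log.info("stage=drivers seed=%d cells=%d correlations=%d",
             cfg.seed, len(table), len(corr))
    return ["driver_table.csv", "correlations.csv", "regime_models.csv",
            "tukey.csv", "interannual.csv", "trend.json"]


def stage_report(cfg: PipelineConfig, out: Path) -> list[str]:
    names = pd.read_csv(_need(out, "pyroregion_names.csv", "cluster"))
    summary = pd.read_csv(_need(out, "regime_radius.csv", "grid"))
    with open(_need(out, "filter_summary.json", "filter")) as fh:
        fsum = json.load(fh)
    lines = ["# Pyroregion summary", "",
             f"Tracked events: {fsum['n_input']}; analysed wildfires: "
             f"{fsum['n_survivors']}.", "",
             "| Pyroregion | Cells | Burned area (% yr-1) | Fire density "
             "(km-2 yr-1) | Size (km2) | Duration (d) | FRP95 (W m-2) | "
             "Start (DOY) |",
             "|---|---|---|---|---|---|---|---|"]
    for _, r in names.sort_values("code").iterrows():
        lines.append(
            f"| {r['code']} ({r['name']}) | {r['n_cells']} | "
            f"{r['burned_pct_yr']:.2f} | {r['fire_density']:.2e} | "
            f"{r['mean_size_km2']:.1f} | {r['mean_duration_d']:.1f} | "
            f"{r['mean_frp95_wm2']:.1f} | {r['mean_start_doy']:.0f} |")
    lines += ["", f"Grid cells with fires: {(summary['n_fires'] > 0).sum()} "
              f"of {len(summary)}."]
    (out / "report.md").write_text("\n".join(lines))
    return ["report.md"]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "track": stage_track, "filter": stage_filter,
    "grid": stage_grid, "cluster": stage_cluster, "drivers": stage_drivers,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, out_dir, stages=None) -> Path:
    """Run the pipeline (or a subset of stages) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGES
    if isinstance(stages, str):
        stages = [stages]
    written: list[str] = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        written += _STAGE_FUNCS[stage](cfg, out)
    manifest_files = sorted({*written, *(p.name for p in out.iterdir()
                                         if p.is_file() and p.name != "manifest.json")})
    bfio.write_manifest(out, manifest_files, cfg.echo())
    return out
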