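"""File formats: detection CSV, atlas GeoJSON, regime CSV, manifest.

Detection CSVs use the columns ``lat_or_y, lon_or_x, acq_datetime,
frp_mw, daynight`` (planar km in the synthetic frame; an ingestion shim
may project real lon/lat). Truth labels live in a sidecar CSV keyed by
row id and never in the detection columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from borealfire.synthetic.detections import DetectionTable

CSV_COLUMNS = ["lat_or_y", "lon_or_x", "acq_datetime", "frp_mw", "daynight"]

_ATLAS_PROPS = ["event_id", "start_date", "duration_d", "size_km2",
                "frp95_wm2", "n_ignitions", "fire_type"]


def write_detections(det: DetectionTable, path, truth_path=None) -> None:
    df = pd.DataFrame({
        "lat_or_y": det.frame["y"],
        "lon_or_x": det.frame["x"],
        "acq_datetime": pd.to_datetime(det.frame["time"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ"),
        "frp_mw": det.frame["frp"],
        "daynight": det.frame["daynight"],
    })
    df.to_csv(path, index=True, index_label="row_id")
    if truth_path is not None:
        det.truth.to_csv(truth_path, index=True, index_label="row_id")


def read_detections(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a detection CSV.

    Returns (detections, rejects): bad rows (unparseable timestamp,
    negative FRP, unknown day/night flag) are collected in the rejects
    frame with a ``reason`` column rather than failing the read. A
    missing mandatory column is an error naming it.
    """
    raw = pd.read_csv(path)
    for col in CSV_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    if "row_id" not in raw.columns:
        raw.insert(0, "row_id", np.arange(len(raw)))
    times = pd.to_datetime(raw["acq_datetime"], errors="coerce", utc=True,
                           format="mixed")
    times = times.dt.tz_localize(None)
    frp = pd.to_numeric(raw["frp_mw"], errors="coerce")
    dn = raw["daynight"].astype(str).str.upper()
    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[times.isna()] = "unparseable acq_datetime"
    reasons[frp.isna()] = "non-numeric frp_mw"
    reasons[frp < 0] = "negative frp_mw"
    reasons[~dn.isin(["D", "N"]) & (reasons == "")] = "daynight not D|N"
    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects["reason"] = reasons[bad]
    good = raw.loc[~bad]
    out = pd.DataFrame({
        "row_id": good["row_id"].to_numpy(),
        "x": pd.to_numeric(good["lon_or_x"]).to_numpy(dtype=float),
        "y": pd.to_numeric(good["lat_or_y"]).to_numpy(dtype=float),
        "time": times[~bad].to_numpy(),
        "frp": frp[~bad].to_numpy(dtype=float),
        "daynight": dn[~bad].to_numpy(),
    })
    return out, rejects


def write_atlas_geojson(frame: pd.DataFrame, path) -> None:
    """Write an atlas frame (perimeter layer) as GeoJSON."""
    feats = []
    for _, row in frame.iterrows():
        props = {}
        for k in _ATLAS_PROPS:
            v = row[k]
            if isinstance(v, pd.Timestamp):
                v = v.isoformat()
            elif isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            props[k] = v
        feats.append({"type": "Feature", "geometry": mapping(row["geometry"]),
                      "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_atlas_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        data = json.load(fh)
    rows = []
    for feat in data["features"]:
        row = dict(feat["properties"])
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    df = pd.DataFrame(rows, columns=_ATLAS_PROPS + ["geometry"])
    if len(df):
        df["start_date"] = pd.to_datetime(df["start_date"])
    return df[["event_id", "geometry", "size_km2", "duration_d", "start_date",
               "frp95_wm2", "n_ignitions", "fire_type"]]


def write_ignitions_geojson(atlas, path) -> None:
    feats = []
    for ev in atlas.events:
        for x, y, t in ev.ignitions:
            feats.append({
                "type": "Feature",
                "geometry": mapping(shapely.Point(x, y)),
                "properties": {"event_id": ev.event_id,
                               "time": pd.Timestamp(t).isoformat()},
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_regime_tidy(regime_table: pd.DataFrame, path,
                      per_year: pd.DataFrame | None = None) -> None:
    """Tidy long-format CSV: cell_id, year (empty = climatology), property, value."""
    long_rows = regime_table.melt(id_vars=["cell_id"], var_name="property",
                                  value_name="value")
    long_rows.insert(1, "year", "")
    if per_year is not None and len(per_year):
        py = per_year.melt(id_vars=["cell_id", "year"], var_name="property",
                           value_name="value")
        long_rows = pd.concat([long_rows, py], ignore_index=True)
    long_rows.to_csv(path, index=False)


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, files: list[str], config_echo: dict,
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "coordinate_frame": "planar km, origin at domain lower-left, y northward",
        "files": {f: sha256(out_dir / f) for f in files if (out_dir / f).exists()},
        "config": config_echo,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
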