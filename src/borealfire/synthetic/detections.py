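"""Active-fire detection simulation.

For each overpass during a fire's life, the lattice points (at
``pixel_spacing``) inside the step's newly burning ring are emitted as
detections with probability ``p_detect``; FRP is lognormal with median
equal to the fire's per-step intensity level. Gas flares emit
near-daily stationary detections and agricultural burns emit small
short-lived clusters in cropland. Every detection row carries a hidden
truth label in a sidecar table, never in the columns the tracker reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from borealfire._rng import rng_for
from borealfire.synthetic.config import WorldConfig
from borealfire.synthetic.fires import TruthFire
from borealfire.synthetic.landcover import LandCover, LandCoverGrid
from borealfire.synthetic.timebase import (
    day_number,
    overpass_timestamp,
    year_overpass_range,
)

#: columns of the detection frame the tracker is allowed to read
DETECTION_COLUMNS = ["x", "y", "time", "frp", "daynight"]


@dataclass(frozen=True)
class DetectionTable:
    """Detections plus a sidecar of hidden truth labels, row-aligned.

    ``frame`` has columns x, y (planar km), time (UTC), frp (MW per
    pixel) and daynight ('D'|'N'). ``truth`` has a ``label`` column:
    ``fire:<fid>``, ``flare:<site>`` or ``ag:<burn>``.
    """

    frame: pd.DataFrame
    truth: pd.DataFrame

    def __post_init__(self):
        if len(self.frame) != len(self.truth):
            raise ValueError("frame and truth sidecar must be row-aligned")

    def __len__(self) -> int:
        return len(self.frame)


def gen_flares(cfg: WorldConfig, lc: LandCoverGrid) -> pd.DataFrame:
    """Gas-flare site list: clustered stationary points ("flaring districts")."""
    rng = rng_for(cfg.seed, "flares")
    w, h = cfg.domain_km
    n = int(round(cfg.flares_per_1e4km2 * w * h / 1e4))
    if n == 0:
        return pd.DataFrame(columns=["site_id", "x", "y"])
    n_centers = max(1, n // 8)
    cx = rng.uniform(0.05 * w, 0.95 * w, size=n_centers)
    cy = rng.uniform(0.05 * h, 0.95 * h, size=n_centers)
    which = rng.integers(0, n_centers, size=n)
    x = np.clip(cx[which] + rng.normal(0, 15.0, size=n), 0, w)
    y = np.clip(cy[which] + rng.normal(0, 15.0, size=n), 0, h)
    return pd.DataFrame({"site_id": np.arange(n), "x": x, "y": y})


def _daynight(hours: np.ndarray) -> np.ndarray:
    return np.where((hours >= 6.0) & (hours < 18.0), "D", "N")


def gen_detections(truth: list[TruthFire], flares: pd.DataFrame,
                   lc: LandCoverGrid, cfg: WorldConfig) -> DetectionTable:
    """Emit the detection table a sensor would record over the world."""
    rng = rng_for(cfg.seed, "detections")
    ps = cfg.pixel_spacing
    w, h = cfg.domain_km
    hours = np.asarray(cfg.overpass_hours)
    n_slots = len(hours)
    nx_lat = int(np.floor(w / ps))
    ny_lat = int(np.floor(h / ps))

    xs_parts, ys_parts, g_parts, frp_parts, labels = [], [], [], [], []

    # --- wildfires ---------------------------------------------------
    for fire in truth:
        prev_inside = None
        for t in range(fire.n_steps):
            a, _ = fire.semi_axes(t)
            j0 = max(int(np.floor((fire.x - a) / ps - 0.5)), 0)
            j1 = min(int(np.ceil((fire.x + a) / ps - 0.5)) + 1, nx_lat)
            i0 = max(int(np.floor((fire.y - a) / ps - 0.5)), 0)
            i1 = min(int(np.ceil((fire.y + a) / ps - 0.5)) + 1, ny_lat)
            if j1 <= j0 or i1 <= i0:
                prev_inside = None
                continue
            jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
            px = (jj.ravel() + 0.5) * ps
            py = (ii.ravel() + 0.5) * ps
            inside = fire.contains(t, px, py)
            if t > 0:
                ring = inside & ~fire.contains(t - 1, px, py)
            else:
                ring = inside
            idx = np.nonzero(ring)[0]
            if idx.size == 0:
                continue
            if cfg.p_detect < 1.0:
                idx = idx[rng.random(idx.size) < cfg.p_detect]
            if idx.size == 0:
                continue
            frp = np.exp(np.log(fire.frp_level[t]) +
                         rng.normal(0.0, cfg.frp_sigma, size=idx.size))
            xs_parts.append(px[idx])
            ys_parts.append(py[idx])
            g_parts.append(np.full(idx.size, fire.step0 + t, dtype=np.int64))
            frp_parts.append(frp)
            labels.append(np.full(idx.size, f"fire:{fire.fid}", dtype=object))

    # --- gas flares ----------------------------------------------------
    if len(flares):
        g_lo, _ = year_overpass_range(cfg.start_year, cfg.start_year, n_slots)
        _, g_hi = year_overpass_range(cfg.start_year + cfg.n_years - 1,
                                      cfg.start_year, n_slots)
        n_days = (g_hi - g_lo) // n_slots
        day_slot = int(np.argmax(hours >= 6.0)) if np.any(hours >= 6.0) else 0
        for site_id, sx, sy in flares[["site_id", "x", "y"]].itertuples(index=False):
            emit = rng.random(n_days) < cfg.flare_daily_prob
            days = np.nonzero(emit)[0]
            if days.size == 0:
                continue
            g = days * n_slots + day_slot
            xs_parts.append(np.clip(sx + rng.uniform(-0.45, 0.45, days.size) * ps, 0, w))
            ys_parts.append(np.clip(sy + rng.uniform(-0.45, 0.45, days.size) * ps, 0, h))
            g_parts.append(g)
            frp_parts.append(rng.lognormal(np.log(15.0), 0.5, size=days.size))
            labels.append(np.full(days.size, f"flare:{int(site_id)}", dtype=object))

    # --- agricultural burns --------------------------------------------
    crop_i, crop_j = np.nonzero(lc.codes == LandCover.CROPLAND)
    burn_id = 0
    if crop_i.size and cfg.ag_burns_per_cropcell_yr > 0:
        for yidx in range(cfg.n_years):
            year = cfg.start_year + yidx
            d0 = day_number(year, 3, 1, cfg.start_year)
            d1 = day_number(year, 10, 31, cfg.start_year)
            counts = rng.poisson(cfg.ag_burns_per_cropcell_yr, size=crop_i.size)
            for k in np.nonzero(counts)[0]:
                for _ in range(counts[k]):
                    cx = (crop_j[k] + rng.random()) * lc.res
                    cy = (crop_i[k] + rng.random()) * lc.res
                    day = int(rng.integers(d0, d1 + 1))
                    slot = int(rng.integers(0, n_slots))
                    npts = int(rng.integers(1, 5))
                    jj = int(cx / ps) + np.array([0, 1, 0, 1])[:npts]
                    ii = int(cy / ps) + np.array([0, 0, 1, 1])[:npts]
                    keep = (jj >= 0) & (jj < nx_lat) & (ii >= 0) & (ii < ny_lat)
                    if not keep.any():
                        continue
                    jj, ii = jj[keep], ii[keep]
                    xs_parts.append((jj + 0.5) * ps)
                    ys_parts.append((ii + 0.5) * ps)
                    g_parts.append(np.full(jj.size, day * n_slots + slot, dtype=np.int64))
                    frp_parts.append(rng.lognormal(np.log(3.0), 0.5, size=jj.size))
                    labels.append(np.full(jj.size, f"ag:{burn_id}", dtype=object))
                    burn_id += 1

    if not xs_parts:
        frame = pd.DataFrame({
            "x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
            "time": pd.Series(dtype="datetime64[ns]"),
            "frp": pd.Series(dtype=float), "daynight": pd.Series(dtype=object),
        })
        return DetectionTable(frame=frame, truth=pd.DataFrame({"label": pd.Series(dtype=object)}))

    x = np.concatenate(xs_parts)
    y = np.concatenate(ys_parts)
    g = np.concatenate(g_parts)
    frp = np.concatenate(frp_parts)
    lab = np.concatenate(labels)
    times = overpass_timestamp(g, cfg.overpass_hours, cfg.start_year)
    slot_hours = np.asarray(cfg.overpass_hours)[g % n_slots]
    frame = pd.DataFrame({
        "x": x, "y": y, "time": pd.DatetimeIndex(times),
        "frp": frp, "daynight": _daynight(slot_hours),
    })
    order = np.lexsort((x, y, g))
    frame = frame.iloc[order].reset_index(drop=True)
    truth_df = pd.DataFrame({"label": lab[order]})
    return DetectionTable(frame=frame, truth=truth_df)
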