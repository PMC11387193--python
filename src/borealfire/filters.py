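"""Non-wildfire event filtering.

A cascade of six rules removes agricultural burns, other small
human-caused fires and gas-flare artefacts from a tracked atlas:

R1  final fire type Cropland, Grassland, Urban or Other;
R2  start month January, February, November or December;
R3  events < 20 km^2 overlapping known gas-flare sites and smaller than
    a size cutoff predicted from the number of overlapping flares
    (upper prediction bound of an OLS size-vs-overlap-count model);
R4  events < 20 km^2 lasting > 100 days with mean daily spread
    < 1 km^2 d^-1;
R5  events < 20 km^2 whose perimeter overlaps co-located small events
    in more than 2 distinct calendar years (repeated burns);
R6  final size < 1 km^2.

Rules apply in order; the report records the first matching rule for
every removed event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

RULES = ["R1", "R2", "R3", "R4", "R5", "R6"]


@dataclass(frozen=True)
class FilterConfig:
    nonwildfire_types: tuple = ("CROPLAND", "GRASSLAND", "URBAN", "Other")
    excluded_start_months: tuple = (1, 2, 11, 12)
    small_fire_km2: float = 20.0          # domain of the flare/repeat filters
    long_duration_days: float = 100.0
    min_daily_spread_km2: float = 1.0
    max_overlap_years: int = 2
    min_size_km2: float = 1.0
    prediction_interval: float = 0.95     # level of the flare-cutoff bound
    fallback_cutoff_km2: float = 2.5      # used when the model cannot be fitted


@dataclass
class FlareCutoffModel:
    """Fire-size cutoff as a function of overlapping gas-flare count.

    OLS of final size on flare-overlap count over calibration events
    (< 20 km^2, >= 1 overlap); the cutoff at ``n`` flares is the upper
    bound of the observation prediction interval, monotonized over the
    integer grid and capped at the 20 km^2 domain of applicability.
    """

    slope: float
    intercept: float
    level: float
    sigma2: float          # residual variance
    n_obs: int
    x_mean: float
    sxx: float
    cap_km2: float = 20.0

    def cutoff(self, n_flares) -> np.ndarray:
        from scipy import stats

        n = np.asarray(n_flares, dtype=float)
        grid = np.arange(1.0, max(float(np.max(n)), 1.0) + 1.0)
        pred = self.intercept + self.slope * grid
        if self.n_obs > 2 and self.sigma2 > 0:
            t = stats.t.ppf(0.5 + self.level / 2.0, self.n_obs - 2)
            se = np.sqrt(self.sigma2 * (1.0 + 1.0 / self.n_obs
                                        + (grid - self.x_mean) ** 2 / self.sxx))
            upper = pred + t * se
        else:
            upper = pred
        upper = np.minimum(np.maximum.accumulate(upper), self.cap_km2)
        idx = np.clip(np.round(n).astype(int) - 1, 0, len(grid) - 1)
        out = upper[idx]
        return float(out) if np.isscalar(n_flares) else out


@dataclass
class FilterReport:
    """Per-rule removal bookkeeping for one cascade application."""

    rule_counts: dict = field(default_factory=dict)
    trace: pd.DataFrame | None = None          # event_id, rule, detail
    survivors: list = field(default_factory=list)
    n_input: int = 0
    flare_model: FlareCutoffModel | None = None

    def check(self) -> bool:
        return sum(self.rule_counts.values()) + len(self.survivors) == self.n_input


def fit_flare_cutoff(events: pd.DataFrame, flares: pd.DataFrame,
                     level: float = 0.95,
                     small_fire_km2: float = 20.0) -> FlareCutoffModel:
    """Fit the flare-count size model on qualifying calibration events.

    ``events`` needs ``size_km2`` and ``geometry``; qualifying events are
    smaller than 20 km^2 and overlap at least one flare site. Fewer than
    10 qualifying events is an error (configure a fixed fallback cutoff
    instead).
    """
    n_overlaps = count_flare_overlaps(events, flares)
    mask = (events["size_km2"].to_numpy() < small_fire_km2) & (n_overlaps >= 1)
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} events < {small_fire_km2} km2 overlap a "
            "flare site; need >= 10 - fall back to a fixed cutoff "
            "(FilterConfig.fallback_cutoff_km2)")
    x = n_overlaps[mask].astype(float)
    y = events.loc[mask, "size_km2"].to_numpy(dtype=float)
    n = x.size
    x_mean = float(x.mean())
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0:
        slope, intercept = 0.0, float(y.mean())
        resid = y - intercept
    else:
        slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * x_mean)
        resid = y - (intercept + slope * x)
    sigma2 = float((resid**2).sum() / max(n - 2, 1))
    return FlareCutoffModel(slope=slope, intercept=intercept, level=level,
                            sigma2=sigma2, n_obs=n, x_mean=x_mean,
                            sxx=max(sxx, 1e-12), cap_km2=small_fire_km2)


def count_flare_overlaps(events: pd.DataFrame, flares: pd.DataFrame) -> np.ndarray:
    """Number of flare sites inside each event's final perimeter."""
    counts = np.zeros(len(events), dtype=int)
    if flares is None or len(flares) == 0 or len(events) == 0:
        return counts
    pts = shapely.points(flares["x"].to_numpy(), flares["y"].to_numpy())
    tree = STRtree(pts)
    for i, geom in enumerate(events["geometry"]):
        cand = tree.query(geom, predicate="covers")
        counts[i] = len(cand)
    return counts


def apply_filters(events: pd.DataFrame, flares: pd.DataFrame | None,
                  cfg: FilterConfig = FilterConfig(),
                  flare_model: FlareCutoffModel | None = None,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the R1-R6 cascade to an atlas frame.

    ``events`` is the frame from :meth:`FireAtlas.to_frame` (one row per
    finalized event with shapely geometry). Returns the surviving frame
    and a :class:`FilterReport`. Pass a prefitted ``flare_model`` to
    reuse a calibration (e.g. when re-applying the cascade).
    """
    ev = events.reset_index(drop=True).copy()
    n_input = len(ev)
    removed_rule = pd.Series(pd.NA, index=ev.index, dtype=object)
    detail = pd.Series("", index=ev.index, dtype=object)
    alive = np.ones(n_input, dtype=bool)

    size = ev["size_km2"].to_numpy(dtype=float)
    duration = ev["duration_d"].to_numpy(dtype=float)
    start = pd.to_datetime(ev["start_date"])
    month = start.dt.month.to_numpy()
    year = start.dt.year.to_numpy()
    ftype = ev["fire_type"].astype(str).str.upper()

    # R1: non-wildfire final fuel type, any size
    bad_types = {t.upper() for t in cfg.nonwildfire_types}
    hit = alive & ftype.isin(bad_types).to_numpy()
    removed_rule[hit] = "R1"
    detail[hit] = ev.loc[hit, "fire_type"].astype(str)
    alive &= ~hit

    # R2: winter starts
    hit = alive & np.isin(month, cfg.excluded_start_months)
    removed_rule[hit] = "R2"
    detail[hit] = [f"start month {m}" for m in month[hit]]
    alive &= ~hit

    # R3: gas-flare size cutoff on small fires
    small = size < cfg.small_fire_km2
    n_overlaps = count_flare_overlaps(ev, flares)
    if flare_model is None and flares is not None and len(flares):
        calib = ev.loc[alive]
        try:
            flare_model = fit_flare_cutoff(calib, flares,
                                           level=cfg.prediction_interval,
                                           small_fire_km2=cfg.small_fire_km2)
        except ValueError as exc:
            log.warning("flare cutoff model not fitted (%s); using fixed "
                        "fallback %.2f km2", exc, cfg.fallback_cutoff_km2)
            flare_model = None
    if flares is not None and len(flares):
        if flare_model is not None:
            cut = flare_model.cutoff(np.maximum(n_overlaps, 1))
        else:
            cut = np.full(n_input, cfg.fallback_cutoff_km2)
        hit = alive & small & (n_overlaps >= 1) & (size < cut)
        removed_rule[hit] = "R3"
        detail[hit] = [f"{n} flares, cutoff {c:.2f} km2"
                       for n, c in zip(n_overlaps[hit], np.asarray(cut)[hit])]
        alive &= ~hit

    # R4: long-lasting smoulder-like events with little spread
    spread = np.divide(size, duration, out=np.full_like(size, np.inf),
                       where=duration > 0)
    hit = (alive & small & (duration > cfg.long_duration_days)
           & (spread < cfg.min_daily_spread_km2))
    removed_rule[hit] = "R4"
    detail[hit] = [f"{d:.0f} d, {s:.3f} km2/d"
                   for d, s in zip(duration[hit], spread[hit])]
    alive &= ~hit

    # R5: repeated burns of the same footprint across > 2 years
    idx_small = np.nonzero(alive & small)[0]
    if idx_small.size:
        geoms = ev.loc[idx_small, "geometry"].to_list()
        tree = STRtree(geoms)
        years_by_event = []
        qi, qj = tree.query(geoms, predicate="intersects")
        overlap_years: dict[int, set] = {int(k): {int(year[idx_small[k]])}
                                         for k in range(len(idx_small))}
        for a, b in zip(qi, qj):
            if a == b:
                continue
            ga, gb = geoms[a], geoms[b]
            inter = shapely.intersection(ga, gb)
            if inter.area > 0:
                overlap_years[int(a)].add(int(year[idx_small[b]]))
        hit_local = [k for k, ys in overlap_years.items()
                     if len(ys) > cfg.max_overlap_years]
        hit_idx = idx_small[hit_local]
        removed_rule[hit_idx] = "R5"
        detail[hit_idx] = [f"overlaps in years {sorted(overlap_years[k])}"
                           for k in hit_local]
        alive[hit_idx] = False

    # R6: below the minimum wildfire size
    hit = alive & (size < cfg.min_size_km2)
    removed_rule[hit] = "R6"
    detail[hit] = [f"{s:.3f} km2" for s in size[hit]]
    alive &= ~hit

    trace = pd.DataFrame({
        "event_id": ev.loc[~alive, "event_id"].to_numpy(),
        "rule": removed_rule[~alive].to_numpy(),
        "detail": detail[~alive].to_numpy(),
    })
    counts = {r: int((trace["rule"] == r).sum()) for r in RULES}
    report = FilterReport(rule_counts=counts, trace=trace,
                          survivors=ev.loc[alive, "event_id"].tolist(),
                          n_input=n_input, flare_model=flare_model)
    return ev.loc[alive].reset_index(drop=True), report
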