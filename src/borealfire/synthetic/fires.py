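"""Ground-truth wildfire simulation.

Ignitions follow an inhomogeneous Poisson point process whose
log-intensity is linear in standardized max-month VPD and (log)
lightning density, restricted to ignitable fuels (forest, shrub/tundra
and peatland). Each fire grows as a discrete-step ellipse: per-overpass
area increments are proportional to ``exp(beta_vpd_growth * z_VPD)``
with lognormal noise, so footprints are nested and monotone by
construction. In pixels with a low wilderness fraction fires are
truncated early with a stated probability, emulating suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity

from borealfire._rng import rng_for
from borealfire.drivers import climatological_max_vpd
from borealfire.synthetic.config import WorldConfig
from borealfire.synthetic.drivers_gen import DriverStack
from borealfire.synthetic.landcover import (
    NON_WILDFIRE_FUEL,
    LandCoverGrid,
)
from borealfire.synthetic.timebase import season_overpass_range


@dataclass(frozen=True)
class TruthFire:
    """One simulated fire with its full per-step growth history."""

    fid: int
    x: float                 # ignition, km
    y: float
    step0: int               # global overpass index of ignition
    year: int
    cause: str               # "lightning" | "human"
    axis_ratio: float        # ellipse a/b >= 1
    phi: float               # orientation, radians
    areas: np.ndarray        # cumulative area per step, km^2
    frp_level: np.ndarray    # per-step FRP intensity level, MW per pixel

    @property
    def n_steps(self) -> int:
        return len(self.areas)

    def semi_axes(self, t: int) -> tuple[float, float]:
        a_sq = self.areas[t] * self.axis_ratio / np.pi
        return float(np.sqrt(a_sq)), float(np.sqrt(self.areas[t] / (np.pi * self.axis_ratio)))

    def footprint(self, t: int) -> shapely.Geometry:
        """Footprint polygon at step ``t`` (ellipse, 64-segment)."""
        a, b = self.semi_axes(t)
        e = shapely.Point(0.0, 0.0).buffer(1.0, quad_segs=16)
        e = affinity.scale(e, a, b)
        e = affinity.rotate(e, np.degrees(self.phi), origin=(0, 0))
        return affinity.translate(e, self.x, self.y)

    def contains(self, t: int, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Analytic point-in-ellipse test for footprint at step ``t``."""
        a, b = self.semi_axes(t)
        dx = xs - self.x
        dy = ys - self.y
        c, s = np.cos(self.phi), np.sin(self.phi)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ignition_intensity(cfg: WorldConfig, lc: LandCoverGrid,
                       drivers: DriverStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel, per-year expected ignitions plus standardized covariates.

    Returns (lambda, z_vpd, z_lightning) where ``lambda`` and ``z_vpd``
    have shape (n_years, ny, nx): the VPD covariate is each year's VPD
    in the climatological maximum-VPD month, standardized against the
    climatology over ignitable pixels, so both the spatial gradient and
    the interannual anomalies couple to fire. Lambda is zero on
    non-ignitable fuels and calibrated so the expected domain total per
    year equals ``ignition_rate_per_1e4km2_yr x ignitable area / 1e4``.
    """
    from borealfire.drivers import annual_max_month_vpd

    ignitable = np.ones(lc.shape, dtype=bool)
    for c in NON_WILDFIRE_FUEL:
        ignitable &= lc.codes != c
    if not ignitable.any():
        raise ValueError("zero ignitable (burnable, non-agricultural) area in domain")
    monthly = drivers.monthly_vpd()
    vclim, _ = climatological_max_vpd(monthly)
    vann = annual_max_month_vpd(monthly)                      # (n_years, ny, nx)
    mu, sd = vclim[ignitable].mean(), max(vclim[ignitable].std(), 1e-12)
    z_v = (vann - mu) / sd
    logl = np.log(np.clip(drivers.lightning, 1e-12, None))
    z_l = (logl - logl[ignitable].mean()) / max(logl[ignitable].std(), 1e-12)
    w = np.exp(cfg.beta_vpd_ignition * z_v + cfg.beta_lightning_ignition * z_l)
    w = np.where(ignitable[None, ...], w, 0.0)
    total = cfg.ignition_rate_per_1e4km2_yr * ignitable.sum() * lc.pixel_area_km2 / 1e4
    lam = total * w / w.sum(axis=(1, 2), keepdims=True)
    return lam, z_v, z_l


def gen_truth_fires(cfg: WorldConfig, lc: LandCoverGrid,
                    drivers: DriverStack) -> list[TruthFire]:
    """Simulate the ground-truth fire list; identical for a fixed seed."""
    rng = rng_for(cfg.seed, "fires")
    lam, z_v, z_l = ignition_intensity(cfg, lc, drivers)
    ny, nx = lc.shape
    res = lc.res
    n_slots = len(cfg.overpass_hours)

    z_b = (drivers.biomass - drivers.biomass.mean()) / max(drivers.biomass.std(), 1e-12)
    p_lightning = 1.0 / (1.0 + np.exp(-z_l))

    fires: list[TruthFire] = []
    fid = 0
    for yidx in range(cfg.n_years):
        year = cfg.start_year + yidx
        g0, g1 = season_overpass_range(year, cfg.fire_season_months,
                                       cfg.start_year, n_slots)
        counts = rng.poisson(lam[yidx])
        px_i, px_j = np.nonzero(counts)
        reps = counts[px_i, px_j]
        px_i = np.repeat(px_i, reps)
        px_j = np.repeat(px_j, reps)
        n_ign = px_i.size
        if n_ign == 0:
            continue
        xs = (px_j + rng.random(n_ign)) * res
        ysv = (px_i + rng.random(n_ign)) * res
        steps0 = rng.integers(g0, g1, size=n_ign)
        causes = rng.random(n_ign) < p_lightning[px_i, px_j]
        ratios = rng.uniform(1.2, 2.5, size=n_ign)
        phis = rng.uniform(0.0, np.pi, size=n_ign)
        durations = np.maximum(
            1, np.round(rng.gamma(2.0, cfg.mean_duration_steps / 2.0, size=n_ign))
        ).astype(int)
        # suppression: early truncation in low-wilderness pixels
        low_wild = drivers.wilderness[px_i, px_j] < cfg.wilderness_suppression_threshold
        suppressed = low_wild & (rng.random(n_ign) < cfg.suppression_prob)
        supp_caps = rng.integers(1, cfg.suppression_max_steps + 1, size=n_ign)
        durations = np.where(suppressed, np.minimum(durations, supp_caps), durations)

        frp_base = cfg.frp_median_mw * np.exp(
            0.3 * z_b[px_i, px_j] + rng.normal(0.0, 0.5, size=n_ign)
        )
        growth_scale = cfg.base_growth_km2_per_step * np.exp(
            cfg.beta_vpd_growth * z_v[yidx, px_i, px_j]
        )
        # deterministic iteration order: sort by ignition step then position
        order = np.lexsort((xs, ysv, steps0))
        for idx in order:
            d = int(durations[idx])
            incr = growth_scale[idx] * rng.lognormal(0.0, cfg.growth_sigma, size=d)
            incr[0] *= 0.5  # ignition half-step: the fire starts small
            areas = np.cumsum(incr)
            frp = np.full(d, frp_base[idx])
            fires.append(TruthFire(
                fid=fid,
                x=float(xs[idx]), y=float(ysv[idx]),
                step0=int(steps0[idx]), year=year,
                cause="lightning" if causes[idx] else "human",
                axis_ratio=float(ratios[idx]), phi=float(phis[idx]),
                areas=areas, frp_level=frp,
            ))
            fid += 1
    return fires
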