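"""World configuration for the synthetic Arctic-boreal fire simulator.

The defaults describe the study conditions the downstream analysis
assumes: a large high-latitude domain gridded into 100-km analysis
cells, a 375-m detection lattice sampled at two fixed daily overpass
times, a decade of fire seasons, wildfire ignition and growth coupled
positively to vapour-pressure deficit (VPD) and lightning, size
suppression where the wilderness fraction is low, and background
nuisance sources (gas flares, agricultural burns) that the filter
cascade must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    Coordinates are planar kilometres with the origin at the domain's
    lower-left corner and y increasing northward ("north" is high y).
    There is no geographic CRS; an equal-area planar frame preserves
    all the geometry the analysis uses.
    """

    # --- domain ------------------------------------------------------
    domain_km: tuple[float, float] = (2400.0, 2400.0)  # (width, height)
    pixel_spacing: float = 0.375  # km, detection lattice spacing
    cell_size: float = 100.0      # km, analysis grid cell
    lc_res_km: float = 12.0       # land-cover / driver raster resolution
    n_years: int = 10
    start_year: int = 2012
    seed: int = 0

    # --- land-cover class abundance targets (fraction of domain) -----
    water_frac: float = 0.06
    barren_frac: float = 0.04
    cropland_frac: float = 0.06   # concentrated in the southern band
    grassland_frac: float = 0.06
    urban_frac: float = 0.004
    peatland_frac: float = 0.07

    # --- driver fields -----------------------------------------------
    corr_length_km: float = 150.0   # spatial correlation length of noise fields
    vpd_gradient_kpa: float = 0.5   # planted south-minus-north max-month VPD difference

    # --- ignition model: log-intensity linear in standardized drivers
    ignition_rate_per_1e4km2_yr: float = 1.5
    beta_vpd_ignition: float = 0.6
    beta_lightning_ignition: float = 0.5

    # --- growth model -------------------------------------------------
    base_growth_km2_per_step: float = 2.0
    beta_vpd_growth: float = 0.8     # per SD of max-month VPD
    growth_sigma: float = 0.4        # lognormal noise on step increments
    mean_duration_steps: float = 10.0

    # --- suppression ---------------------------------------------------
    wilderness_suppression_threshold: float = 0.2
    suppression_prob: float = 0.85
    suppression_max_steps: int = 2

    # --- detection model ----------------------------------------------
    p_detect: float = 0.95
    frp_median_mw: float = 8.0     # median FRP per pixel at average fuel load
    frp_sigma: float = 0.7         # lognormal sigma of per-detection FRP
    overpass_hours: tuple[float, ...] = (1.5, 13.5)  # UTC, S-NPP-like

    # --- nuisance sources ----------------------------------------------
    flares_per_1e4km2: float = 0.2
    flare_daily_prob: float = 0.8
    ag_burns_per_cropcell_yr: float = 0.6

    # --- season ---------------------------------------------------------
    fire_season_months: tuple[int, int] = (5, 9)  # inclusive

    def __post_init__(self) -> None:
        w, h = self.domain_km
        if min(w, h) < 4 * self.cell_size:
            raise ValueError(
                f"domain_km={self.domain_km} too small: each side must be at "
                f"least 4 x cell_size = {4 * self.cell_size:g} km"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.lc_res_km <= 0:
            raise ValueError("lc_res_km must be > 0")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in (
            "water_frac", "barren_frac", "cropland_frac", "grassland_frac",
            "urban_frac", "peatland_frac", "ignition_rate_per_1e4km2_yr",
            "flares_per_1e4km2", "flare_daily_prob", "ag_burns_per_cropcell_yr",
            "p_detect",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fracs = (self.water_frac + self.barren_frac + self.cropland_frac
                 + self.grassland_frac + self.urban_frac + self.peatland_frac)
        if fracs > 0.9:
            raise ValueError("special land-cover fractions must leave room for forest classes")
        lo, hi = self.fire_season_months
        if not (1 <= lo <= hi <= 12):
            raise ValueError("fire_season_months must satisfy 1 <= lo <= hi <= 12")

    # convenience -------------------------------------------------------
    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_spacing**2

    def with_(self, **kwargs) -> "WorldConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def desk(cls, seed: int = 0, **kwargs) -> "WorldConfig":
        """Desk-scale preset used in the worked examples and tests.

        Keeps the full 2400-km domain (576 analysis cells) but samples
        detections on a 1-km lattice over 4 fire seasons, which keeps a
        complete simulate-track-filter-grid-correlate run to tens of
        seconds. All couplings and rates are the standard defaults.
        """
        base = dict(pixel_spacing=1.0, n_years=4, seed=seed)
        base.update(kwargs)
        return cls(**base)
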