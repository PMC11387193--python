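"""Synthetic climatic, fuel and anthropogenic driver fields.

All fields live on the land-cover raster. Monthly temperature and
dewpoint carry a seasonal cycle, a latitudinal gradient, smooth spatial
noise and a smooth interannual anomaly; the dewpoint depression is
non-negative by construction so dewpoint never exceeds temperature.
A configurable south-minus-north gradient in the dewpoint depression
plants a latitudinal VPD gradient of roughly ``cfg.vpd_gradient_kpa``.
Wilderness fraction is anti-correlated with the cropland+pasture
fraction, emulating the human-footprint structure of high-latitude
landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from borealfire._rng import rng_for
from borealfire.drivers import saturation_vapour_pressure as tetens
from borealfire.drivers import vpd
from borealfire.synthetic.config import WorldConfig
from borealfire.synthetic.landcover import LandCover, LandCoverGrid, smooth_field

# biomass level by land-cover class, Mg/ha
_BIOMASS_BY_CLASS = {
    LandCover.EVERGREEN_FOREST: 80.0,
    LandCover.DECIDUOUS_NEEDLE_FOREST: 55.0,
    LandCover.BROADLEAF_FOREST: 90.0,
    LandCover.SHRUB_TUNDRA: 12.0,
    LandCover.GRASSLAND: 8.0,
    LandCover.CROPLAND: 5.0,
    LandCover.URBAN: 2.0,
    LandCover.WATER: 0.0,
    LandCover.BARREN: 0.0,
    LandCover.PEATLAND: 25.0,
}

def _inv_tetens(p_kpa: np.ndarray) -> np.ndarray:
    """Temperature (degC) whose Tetens saturation pressure is ``p_kpa``."""
    r = np.log(np.asarray(p_kpa, dtype=float) / 0.61078)
    return 237.15 * r / (17.27 - r)


_TREE_CLASSES = {
    "broadleaf": LandCover.BROADLEAF_FOREST,
    "evergreen_needle": LandCover.EVERGREEN_FOREST,
    "deciduous_needle": LandCover.DECIDUOUS_NEEDLE_FOREST,
}


@dataclass(frozen=True)
class DriverStack:
    """Driver rasters on the land-cover grid.

    ``temperature`` and ``dewpoint`` have shape (n_years, 12, ny, nx) in
    degrees Celsius; all other fields are static rasters of shape
    (ny, nx).
    """

    res: float                      # km
    start_year: int
    temperature: np.ndarray         # degC
    dewpoint: np.ndarray            # degC
    lightning: np.ndarray           # strikes / km^2 / day, Mar-Oct climatology
    biomass: np.ndarray             # Mg / ha
    wilderness: np.ndarray          # fraction in [0, 1]
    crop_pasture: np.ndarray        # fraction in [0, 1]
    fire_weather: dict = field(default_factory=dict)   # unitless index rasters
    tree_fractions: dict = field(default_factory=dict)  # per-type fraction rasters

    @property
    def n_years(self) -> int:
        return self.temperature.shape[0]

    def monthly_vpd(self) -> np.ndarray:
        """VPD (kPa) for every (year, month) layer."""
        return vpd(self.temperature, self.dewpoint)


def gen_driver_stack(cfg: WorldConfig, lc: LandCoverGrid) -> DriverStack:
    """Generate the full driver stack; bit-identical for a fixed seed."""
    rng = rng_for(cfg.seed, "drivers")
    shape = lc.shape
    ny, nx = shape
    sigma = cfg.corr_length_km / cfg.lc_res_km

    ys = (np.arange(ny) + 0.5) / ny
    south = np.broadcast_to((1.0 - ys)[:, None], shape)  # 1 at south edge

    months = np.arange(1, 13)
    # peaks in July (~+6 degC base), troughs in January (~-30 degC)
    seasonal = -12.0 + 18.0 * np.cos(2 * np.pi * (months - 7) / 12.0)

    t_spatial = 10.0 * south + 2.0 * smooth_field(shape, sigma, rng)
    temperature = np.empty((cfg.n_years, 12, ny, nx))
    dewpoint = np.empty_like(temperature)

    # VPD is planted directly (latitudinal gradient in kPa plus smooth
    # spatial and interannual anomalies) and the dewpoint is recovered by
    # inverting the Tetens curve, so the gradient knob controls VPD alone
    # and the temperature field's own gradient cannot leak into it
    vpd_spatial = 0.2 * smooth_field(shape, sigma, rng)

    for yidx in range(cfg.n_years):
        t_anom = 1.5 * smooth_field(shape, sigma, rng)
        v_anom = 0.15 * smooth_field(shape, sigma, rng)
        for m in range(12):
            warm = max(0.0, float(np.cos(2 * np.pi * (months[m] - 7) / 12.0)))
            t = seasonal[m] + t_spatial + t_anom
            vpd_target = np.clip(
                0.05 + warm * (0.45 + cfg.vpd_gradient_kpa * south
                               + vpd_spatial + v_anom),
                0.01, None,
            )
            svp = tetens(t)
            avp = np.clip(svp - vpd_target, 0.05 * svp, None)
            temperature[yidx, m] = t
            dewpoint[yidx, m] = _inv_tetens(avp)

    # lightning climatology: log-normal field, mid-southern maximum
    mid_south = np.exp(-((south - 0.65) / 0.35) ** 2)
    lightning = 3e-5 * np.exp(
        0.8 * smooth_field(shape, sigma, rng) + 1.5 * mid_south
    )

    biomass_base = np.vectorize(_BIOMASS_BY_CLASS.__getitem__)(
        np.vectorize(LandCover)(lc.codes)
    ).astype(float)
    biomass = np.clip(
        biomass_base * (1.0 + 0.35 * smooth_field(shape, sigma, rng)), 0.0, None
    )

    # cropland+pasture fraction: smoothed class indicators
    crop_ind = (lc.codes == LandCover.CROPLAND).astype(float)
    grass_ind = (lc.codes == LandCover.GRASSLAND).astype(float)
    crop_pasture = np.clip(
        gaussian_filter(crop_ind + 0.5 * grass_ind, sigma=2.0, mode="reflect"),
        0.0, 1.0,
    )

    # wilderness: anti-correlated with agriculture and urban influence
    urban_ind = gaussian_filter(
        (lc.codes == LandCover.URBAN).astype(float), sigma=3.0, mode="reflect"
    )
    human = (2.5 * crop_pasture + 8.0 * urban_ind
             + 0.5 * south * np.abs(smooth_field(shape, sigma, rng)))
    wilderness = np.clip(1.0 - human, 0.0, 1.0)

    # opaque fire-weather indices: monotone transforms of summer dryness
    july = temperature[:, 6].mean(axis=0) - dewpoint[:, 6].mean(axis=0)
    fire_weather = {
        "ffmc": 75.0 + 2.0 * july + 2.0 * smooth_field(shape, sigma, rng),
        "dmc": 15.0 + 4.0 * july + 4.0 * smooth_field(shape, sigma, rng),
        "fwi": 5.0 + 1.5 * july + 1.5 * smooth_field(shape, sigma, rng),
    }

    tree_fractions = {}
    for name, cls in _TREE_CLASSES.items():
        frac = gaussian_filter(
            (lc.codes == cls).astype(float), sigma=2.0, mode="reflect"
        )
        tree_fractions[name] = np.clip(frac, 0.0, 1.0)
    total = sum(tree_fractions.values())
    scale = np.where(total > 1.0, total, 1.0)
    tree_fractions = {k: v / scale for k, v in tree_fractions.items()}

    return DriverStack(
        res=lc.res,
        start_year=cfg.start_year,
        temperature=temperature,
        dewpoint=dewpoint,
        lightning=lightning,
        biomass=biomass,
        wilderness=wilderness,
        crop_pasture=crop_pasture,
        fire_weather=fire_weather,
        tree_fractions=tree_fractions,
    )
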