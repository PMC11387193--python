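"""Synthetic land-cover raster.

Classes are assigned from smooth seeded random fields combined with a
latitudinal zonation (tundra in the north, forest belts in the middle,
an agricultural band in the south), so every class forms contiguous
patches and anthropogenic gradients exist for the driver analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.ndimage import gaussian_filter

from borealfire._rng import rng_for
from borealfire.synthetic.config import WorldConfig


class LandCover(IntEnum):
    EVERGREEN_FOREST = 0
    DECIDUOUS_NEEDLE_FOREST = 1
    BROADLEAF_FOREST = 2
    SHRUB_TUNDRA = 3
    GRASSLAND = 4
    CROPLAND = 5
    URBAN = 6
    WATER = 7
    BARREN = 8
    PEATLAND = 9


#: classes that cannot carry fire; everything else is burnable
NON_BURNABLE = (LandCover.WATER, LandCover.BARREN)

#: classes in which the generator does not ignite wildfires
NON_WILDFIRE_FUEL = (
    LandCover.CROPLAND,
    LandCover.GRASSLAND,
    LandCover.URBAN,
    LandCover.WATER,
    LandCover.BARREN,
)


@dataclass(frozen=True)
class LandCoverGrid:
    """Raster of land-cover class labels on the planar domain.

    ``codes[i, j]`` is the class of the pixel whose lower-left corner is
    ``(j * res, i * res)`` km; row index increases northward.
    """

    codes: np.ndarray  # int8, shape (ny, nx)
    res: float         # km

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def pixel_area_km2(self) -> float:
        return self.res**2

    def burnable_mask(self) -> np.ndarray:
        m = np.ones(self.codes.shape, dtype=bool)
        for c in NON_BURNABLE:
            m &= self.codes != c
        return m

    def burnable_area_km2(self) -> float:
        return float(self.burnable_mask().sum()) * self.pixel_area_km2

    def total_area_km2(self) -> float:
        return float(self.codes.size) * self.pixel_area_km2

    def class_fraction(self, cls: LandCover) -> float:
        return float((self.codes == cls).mean())

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Raster indices (row, col) of planar points, clipped to the grid."""
        j = np.clip((np.asarray(x) / self.res).astype(int), 0, self.codes.shape[1] - 1)
        i = np.clip((np.asarray(y) / self.res).astype(int), 0, self.codes.shape[0] - 1)
        return i, j

    def class_at(self, x, y) -> np.ndarray:
        i, j = self.index_of(x, y)
        return self.codes[i, j]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.codes.shape
        xs = (np.arange(nx) + 0.5) * self.res
        ys = (np.arange(ny) + 0.5) * self.res
        return xs, ys


def smooth_field(shape: tuple[int, int], sigma_px: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation scale ``sigma_px``.

    ``sigma_px == 0`` degenerates to white noise, which is what the
    variogram tests exploit.
    """
    z = rng.standard_normal(shape)
    if sigma_px > 0:
        z = gaussian_filter(z, sigma=sigma_px, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def _take_top(score: np.ndarray, free: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the ``n`` highest-scoring currently-free pixels."""
    sel = np.zeros(score.shape, dtype=bool)
    if n <= 0:
        return sel
    masked = np.where(free, score, -np.inf)
    flat = np.argsort(masked, axis=None, kind="stable")[::-1][:n]
    sel.flat[flat] = True
    sel &= free
    return sel


def gen_landcover(cfg: WorldConfig) -> LandCoverGrid:
    """Generate the seeded land-cover raster.

    Deterministic for a given seed. Raises if the domain cannot host a
    contiguous patch of every class with a nonzero abundance target.
    """
    rng = rng_for(cfg.seed, "landcover")
    w, h = cfg.domain_km
    nx = max(int(round(w / cfg.lc_res_km)), 1)
    ny = max(int(round(h / cfg.lc_res_km)), 1)
    if min(nx, ny) < 16:
        raise ValueError(
            "domain too small to host all land-cover classes: need at least "
            f"{16 * cfg.lc_res_km:g} km per side at lc_res_km={cfg.lc_res_km:g}"
        )
    shape = (ny, nx)
    n_cells = nx * ny
    # patch scale fixed at 60 km: large enough for contiguity, small
    # enough that a 400-km domain still hosts several patches per class
    sigma = 60.0 / cfg.lc_res_km

    ys = (np.arange(ny) + 0.5) / ny          # 0 at south edge, 1 at north
    y_frac = np.broadcast_to(ys[:, None], shape)

    codes = np.full(shape, -1, dtype=np.int8)
    free = np.ones(shape, dtype=bool)

    def assign(cls: LandCover, mask: np.ndarray) -> None:
        codes[mask & free] = int(cls)
        free[mask] = False

    # water: lakes anywhere
    assign(LandCover.WATER,
           _take_top(smooth_field(shape, sigma, rng), free,
                     int(round(cfg.water_frac * n_cells))))
    # barren: mostly far north
    assign(LandCover.BARREN,
           _take_top(smooth_field(shape, sigma, rng) + 2.5 * y_frac, free,
                     int(round(cfg.barren_frac * n_cells))))
    # peatland lowlands
    assign(LandCover.PEATLAND,
           _take_top(smooth_field(shape, sigma, rng), free,
                     int(round(cfg.peatland_frac * n_cells))))
    # agricultural band in the south
    south = np.exp(-((y_frac - 0.0) / 0.18) ** 2)
    assign(LandCover.CROPLAND,
           _take_top(smooth_field(shape, sigma, rng) + 4.0 * south, free,
                     int(round(cfg.cropland_frac * n_cells))))
    assign(LandCover.GRASSLAND,
           _take_top(smooth_field(shape, sigma, rng) + 3.0 * south, free,
                     int(round(cfg.grassland_frac * n_cells))))
    assign(LandCover.URBAN,
           _take_top(smooth_field(shape, sigma / 3, rng) + 3.0 * south, free,
                     int(round(cfg.urban_frac * n_cells))))

    # remaining pixels: forest belts by effective latitude
    y_eff = y_frac + 0.12 * smooth_field(shape, sigma, rng)
    belts = [
        (LandCover.BROADLEAF_FOREST, y_eff < 0.30),
        (LandCover.EVERGREEN_FOREST, (y_eff >= 0.30) & (y_eff < 0.58)),
        (LandCover.DECIDUOUS_NEEDLE_FOREST, (y_eff >= 0.58) & (y_eff < 0.80)),
        (LandCover.SHRUB_TUNDRA, y_eff >= 0.80),
    ]
    for cls, mask in belts:
        assign(cls, mask)
    assert not free.any()

    grid = LandCoverGrid(codes=codes, res=cfg.lc_res_km)
    targets = {
        LandCover.WATER: cfg.water_frac, LandCover.BARREN: cfg.barren_frac,
        LandCover.PEATLAND: cfg.peatland_frac, LandCover.CROPLAND: cfg.cropland_frac,
        LandCover.GRASSLAND: cfg.grassland_frac, LandCover.URBAN: cfg.urban_frac,
    }
    missing = [cls.name for cls in LandCover
               if targets.get(cls, 1.0) > 0 and not (codes == cls).any()]
    if missing:
        raise ValueError(
            f"domain too small to host classes {missing}; smallest feasible "
            f"extent is about {16 * cfg.lc_res_km:g} km per side"
        )
    return grid
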