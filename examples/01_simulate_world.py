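"""Generate a synthetic high-latitude fire world and look at its pieces.

Builds a 1000-km planar domain with land cover, climate/fuel/human
driver rasters, ground-truth fires and the active-fire detections a
twice-daily polar-orbiting sensor would record.
"""

import numpy as np

import borealfire as bf
from borealfire.synthetic import LandCover

cfg = bf.WorldConfig(domain_km=(1000.0, 1000.0), pixel_spacing=0.75,
                     lc_res_km=10.0, n_years=2, seed=42)
lc = bf.gen_landcover(cfg)
stack = bf.gen_driver_stack(cfg, lc)
fires = bf.gen_truth_fires(cfg, lc, stack)
flares = bf.gen_flares(cfg, lc)
det = bf.gen_detections(fires, flares, lc, cfg)

print(f"domain: {cfg.domain_km[0]:.0f} x {cfg.domain_km[1]:.0f} km, "
      f"{cfg.n_years} fire seasons")
print(f"burnable fraction: {lc.burnable_area_km2() / lc.total_area_km2():.2f} "
      "(everything except water and barren)")
print(f"cropland fraction: {lc.class_fraction(LandCover.CROPLAND):.3f} "
      "(concentrated in the southern band)")
sizes = np.array([f.areas[-1] for f in fires])
print(f"truth fires: {len(fires)}, median final size {np.median(sizes):.1f} km2, "
      f"largest {sizes.max():.0f} km2")
print(f"gas flare sites: {len(flares)}")
print(f"detections: {len(det)} rows "
      f"({(det.truth['label'].str.startswith('fire:')).mean():.0%} from wildfires; "
      "the rest are flare and agricultural nuisance that the filter "
      "cascade must remove)")
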