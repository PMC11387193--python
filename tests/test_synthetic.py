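"""Synthetic world generator: determinism, couplings and emission rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import borealfire as bf
from borealfire.synthetic import LandCover, smooth_field
from borealfire.synthetic.fires import TruthFire
from borealfire.drivers import climatological_max_vpd


def _fire_summary(fires):
    return pd.DataFrame([
        {"fid": f.fid, "x": f.x, "y": f.y, "step0": f.step0,
         "area": f.areas[-1], "n": f.n_steps} for f in fires])


class TestDeterminism:
    def test_landcover_seeded_rerun_identical(self, small_cfg):
        a = bf.gen_landcover(small_cfg)
        b = bf.gen_landcover(small_cfg)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_driver_stack_bit_identical(self, small_cfg, small_world):
        again = bf.gen_driver_stack(small_cfg, small_world["lc"])
        np.testing.assert_array_equal(again.temperature,
                                      small_world["stack"].temperature)
        np.testing.assert_array_equal(again.wilderness,
                                      small_world["stack"].wilderness)

    def test_fires_and_detections_identical(self, small_world):
        cfg, lc, stack = (small_world["cfg"], small_world["lc"],
                          small_world["stack"])
        fires2 = bf.gen_truth_fires(cfg, lc, stack)
        pd.testing.assert_frame_equal(_fire_summary(small_world["fires"]),
                                      _fire_summary(fires2))
        det2 = bf.gen_detections(fires2, small_world["flares"], lc, cfg)
        pd.testing.assert_frame_equal(small_world["det"].frame, det2.frame)
        pd.testing.assert_frame_equal(small_world["det"].truth, det2.truth)


class TestLandcover:
    def test_all_classes_present_as_patches(self, small_world):
        lc = small_world["lc"]
        for cls in LandCover:
            assert (lc.codes == cls).any(), cls

    def test_zero_cropland_rate(self, small_cfg):
        lc = bf.gen_landcover(small_cfg.with_(cropland_frac=0.0, seed=5))
        assert not (lc.codes == LandCover.CROPLAND).any()

    def test_burnable_mask_is_total_minus_water_barren(self, small_world):
        lc = small_world["lc"]
        special = ((lc.codes == LandCover.WATER)
                   | (lc.codes == LandCover.BARREN)).sum()
        assert lc.burnable_mask().sum() == lc.codes.size - special

    def test_cropland_concentrated_south(self, small_world):
        lc = small_world["lc"]
        ny = lc.shape[0]
        south = (lc.codes[: ny // 2] == LandCover.CROPLAND).sum()
        north = (lc.codes[ny // 2:] == LandCover.CROPLAND).sum()
        assert south > 3 * north

    def test_domain_too_small(self):
        with pytest.raises(ValueError, match="4 x cell_size"):
            bf.WorldConfig(domain_km=(300.0, 300.0))
        with pytest.raises(ValueError, match="smallest feasible|host all"):
            bf.gen_landcover(bf.WorldConfig(domain_km=(400.0, 400.0),
                                            lc_res_km=40.0))


class TestDrivers:
    def test_physical_invariants(self, small_world):
        st = small_world["stack"]
        assert (st.dewpoint < st.temperature).all()
        assert ((st.wilderness >= 0) & (st.wilderness <= 1)).all()
        assert ((st.crop_pasture >= 0) & (st.crop_pasture <= 1)).all()
        total = sum(st.tree_fractions.values())
        assert (total <= 1 + 1e-9).all()

    def test_wilderness_anticorrelated_with_cropland(self, small_world):
        st = small_world["stack"]
        r = np.corrcoef(st.wilderness.ravel(), st.crop_pasture.ravel())[0, 1]
        assert r < -0.2

    def test_zero_correlation_length_gives_white_noise(self):
        # variogram flat beyond one pixel when the smoothing scale vanishes
        rng = np.random.default_rng(0)
        white = smooth_field((200, 200), 0.0, rng)
        smooth = smooth_field((200, 200), 5.0, rng)

        def lag1_corr(f):
            return np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]

        assert abs(lag1_corr(white)) < 0.05
        assert lag1_corr(smooth) > 0.5

    def test_null_vpd_gradient_flat_across_latitude(self):
        # with the gradient knob at zero the latitude-band difference of
        # max-month VPD is Monte-Carlo noise; with the default it is planted
        diffs0, diffs1 = [], []
        for seed in range(4):
            cfg = bf.WorldConfig(domain_km=(1000.0, 1000.0), lc_res_km=20.0,
                                 n_years=2, seed=seed)
            lc = bf.gen_landcover(cfg)
            for g, acc in ((0.0, diffs0), (0.5, diffs1)):
                st = bf.gen_driver_stack(cfg.with_(vpd_gradient_kpa=g), lc)
                v, _ = climatological_max_vpd(st.monthly_vpd())
                ny = v.shape[0]
                acc.append(v[: ny // 3].mean() - v[-ny // 3:].mean())
        assert abs(np.mean(diffs0)) < 0.1
        assert np.mean(diffs1) > np.mean(diffs0) + 0.2


class TestTruthFires:
    def test_homogeneous_poisson_when_couplings_zero(self):
        # chi-square GOF of per-pixel ignition counts against Poisson
        cfg = bf.WorldConfig(
            domain_km=(500.0, 500.0), lc_res_km=10.0, n_years=4, seed=3,
            water_frac=0, barren_frac=0, cropland_frac=0, grassland_frac=0,
            urban_frac=0, peatland_frac=0,
            beta_vpd_ignition=0.0, beta_lightning_ignition=0.0,
            ignition_rate_per_1e4km2_yr=20.0,
        )
        lc = bf.gen_landcover(cfg)
        st = bf.gen_driver_stack(cfg, lc)
        fires = bf.gen_truth_fires(cfg, lc, st)
        counts = np.zeros(lc.shape, dtype=int)
        for f in fires:
            i, j = lc.index_of(f.x, f.y)
            counts[i, j] += 1
        lam = counts.mean()
        kmax = 3
        obs = np.array([(counts == k).sum() for k in range(kmax)]
                       + [(counts >= kmax).sum()])
        probs = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = stats.chisquare(obs, probs * counts.size, ddof=1)
        assert chi2.pvalue > 0.01

    def test_forced_suppression_truncates_to_one_step(self, small_cfg):
        cfg = small_cfg.with_(suppression_prob=1.0, suppression_max_steps=1,
                              seed=21)
        lc = bf.gen_landcover(cfg)
        st = bf.gen_driver_stack(cfg, lc)
        fires = bf.gen_truth_fires(cfg, lc, st)
        hit = 0
        for f in fires:
            i, j = lc.index_of(f.x, f.y)
            if st.wilderness[i, j] < cfg.wilderness_suppression_threshold:
                hit += 1
                assert f.n_steps == 1
        assert hit > 0, "no fires ignited in low-wilderness pixels"

    def test_footprints_nested(self, small_world):
        for f in small_world["fires"][:50]:
            assert np.all(np.diff(f.areas) >= 0)


class TestDetections:
    def test_exhaustive_emission_counts_lattice_points(self):
        cfg = bf.WorldConfig(domain_km=(500.0, 500.0), lc_res_km=10.0,
                             n_years=1, seed=0, p_detect=1.0,
                             pixel_spacing=1.0, flares_per_1e4km2=0.0,
                             ag_burns_per_cropcell_yr=0.0)
        fire = TruthFire(fid=0, x=250.0, y=250.0, step0=300, year=2012,
                         cause="lightning", axis_ratio=1.0, phi=0.0,
                         areas=np.array([80.0]), frp_level=np.array([5.0]))
        lc = bf.gen_landcover(cfg)
        det = bf.gen_detections([fire], pd.DataFrame(columns=["site_id", "x", "y"]),
                                lc, cfg)
        # independent count: lattice centres inside the circle of area 80
        r = np.sqrt(80.0 / np.pi)
        xs = np.arange(0.5, 500.0, 1.0)
        xx, yy = np.meshgrid(xs, xs)
        k = int((np.hypot(xx - 250.0, yy - 250.0) <= r).sum())
        assert len(det) == k

    def test_flare_emission_schedule(self):
        cfg = bf.WorldConfig(domain_km=(500.0, 500.0), lc_res_km=10.0,
                             n_years=1, seed=0, flare_daily_prob=1.0,
                             pixel_spacing=1.0, ag_burns_per_cropcell_yr=0.0)
        lc = bf.gen_landcover(cfg)
        flares = pd.DataFrame({"site_id": [0], "x": [100.0], "y": [100.0]})
        det = bf.gen_detections([], flares, lc, cfg)
        assert len(det) == 366            # daily over a leap start-year
        assert (np.abs(det.frame["x"] - 100.0) <= cfg.pixel_spacing).all()
        assert (np.abs(det.frame["y"] - 100.0) <= cfg.pixel_spacing).all()

    def test_empty_world_empty_table(self):
        cfg = bf.WorldConfig(domain_km=(500.0, 500.0), lc_res_km=10.0,
                             n_years=1, seed=0, flares_per_1e4km2=0.0,
                             ag_burns_per_cropcell_yr=0.0)
        lc = bf.gen_landcover(cfg)
        det = bf.gen_detections([], bf.gen_flares(cfg, lc), lc, cfg)
        assert len(det) == 0

    def test_truth_labels_sidecar_not_in_tracker_columns(self, small_world):
        det = small_world["det"]
        assert len(det.truth) == len(det.frame)
        assert "label" not in det.frame.columns
        assert set(det.frame.columns) == {"x", "y", "time", "frp", "daynight"}
        assert det.truth["label"].str.match(r"(fire|flare|ag):").all()
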