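"""Shared fixtures: small seeded worlds exercised by many modules."""

import numpy as np
import pandas as pd
import pytest

import borealfire as bf


@pytest.fixture(scope="session")
def small_cfg():
    """A 1000-km world with default nuisance rates, shared across modules."""
    return bf.WorldConfig(
        domain_km=(1000.0, 1000.0), pixel_spacing=0.75, lc_res_km=10.0,
        n_years=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    lc = bf.gen_landcover(small_cfg)
    stack = bf.gen_driver_stack(small_cfg, lc)
    fires = bf.gen_truth_fires(small_cfg, lc, stack)
    flares = bf.gen_flares(small_cfg, lc)
    det = bf.gen_detections(fires, flares, lc, small_cfg)
    return {"cfg": small_cfg, "lc": lc, "stack": stack, "fires": fires,
            "flares": flares, "det": det}


@pytest.fixture(scope="session")
def tracked_world(small_world):
    cfg = small_world["cfg"]
    tracker = bf.TrackerConfig.for_spacing(cfg.pixel_spacing)
    binned = bf.bin_timesteps(small_world["det"].frame)
    atlas = bf.track_events(binned, tracker, lc=small_world["lc"],
                            with_fireline=False, snapshot_perimeters=False)
    atlas.summarize(small_world["lc"])
    return {"atlas": atlas, "tracker": tracker, "binned": binned,
            **small_world}


def truth_event_labels(atlas, det):
    """Majority truth label per tracked event (for nuisance scoring)."""
    labels = det.truth["label"].to_numpy()
    out = {}
    for ev in atlas.events:
        lab, counts = np.unique(labels[ev.det_row_ids], return_counts=True)
        out[ev.event_id] = lab[np.argmax(counts)]
    return out


def make_event_row(event_id, geometry, size=None, duration_d=2,
                   start="2013-06-10", frp95=30.0, n_ignitions=1,
                   fire_type="EVERGREEN_FOREST"):
    return {
        "event_id": event_id, "geometry": geometry,
        "size_km2": geometry.area if size is None else size,
        "duration_d": duration_d, "start_date": pd.Timestamp(start),
        "frp95_wm2": frp95, "n_ignitions": n_ignitions, "fire_type": fire_type,
    }


def make_designed_filter_atlas():
    """Atlas with one event per filter rule plus survivors.

    Returns (events, flares, expected) where expected maps event id to
    the rule that should remove it (None = survives).
    """
    import shapely

    def sq(x, y, area):
        s = np.sqrt(area) / 2
        return shapely.box(x - s, y - s, x + s, y + s)

    rows, expected = [], {}
    rows.append(make_event_row(1, sq(5, 5, 4.0), fire_type="CROPLAND"))
    expected[1] = "R1"
    rows.append(make_event_row(2, sq(15, 5, 30.0), fire_type="Other"))
    expected[2] = "R1"
    rows.append(make_event_row(3, sq(25, 5, 4.0), start="2013-01-15"))
    expected[3] = "R2"
    rng = np.random.default_rng(0)
    for k in range(1, 16):      # flare calibration cloud, removed by R3
        size = 1.0 + 0.5 * k + rng.normal(0, 0.05)
        rows.append(make_event_row(100 + k, sq(100 + 10 * k, 50, size)))
        expected[100 + k] = "R3"
    rows.append(make_event_row(4, sq(110, 80, 19.0)))   # above cutoff
    expected[4] = None
    rows.append(make_event_row(5, sq(35, 5, 5.0), duration_d=120))
    expected[5] = "R4"
    for eid, yr in ((6, 2013), (7, 2015), (8, 2017)):
        rows.append(make_event_row(eid, sq(45, 5, 6.0), start=f"{yr}-06-10"))
        expected[eid] = "R5"
    for eid, yr in ((9, 2013), (10, 2015)):
        rows.append(make_event_row(eid, sq(55, 5, 6.0), start=f"{yr}-06-10"))
        expected[eid] = None
    rows.append(make_event_row(11, sq(65, 5, 0.8)))
    expected[11] = "R6"
    for eid in (12, 13):
        rows.append(make_event_row(eid, sq(70 + 10 * eid, 40, 25.0)))
        expected[eid] = None
    events = pd.DataFrame(rows)
    fx, fy = [], []
    for k in range(1, 16):
        for m in range(k):
            fx.append(100 + 10 * k + 0.05 * m)
            fy.append(50.0)
    fx.append(110.0)
    fy.append(80.0)
    flares = pd.DataFrame({"site_id": np.arange(len(fx)), "x": fx, "y": fy})
    return events, flares, expected
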