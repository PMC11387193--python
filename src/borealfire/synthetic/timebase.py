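"""Overpass time base for the synthetic detection simulator.

Detections are emitted at fixed daily overpass clock times (default
01:30 and 13:30 UTC, one per half-day, mimicking a polar-orbiting
sensor). A global overpass index ``g`` counts overpasses from 00:00 UTC
on 1 January of the start year: ``g = day * n_slots + slot``.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd


def day_number(year: int, month: int, day: int, start_year: int) -> int:
    """Days elapsed since 1 January of ``start_year``."""
    return (_dt.date(year, month, day) - _dt.date(start_year, 1, 1)).days


def overpass_timestamp(g, hours: tuple[float, ...], start_year: int):
    """Timestamp(s) of global overpass index/indices ``g`` (UTC, naive)."""
    g = np.asarray(g)
    n = len(hours)
    day, slot = np.divmod(g, n)
    hour = np.asarray(hours)[slot]
    base = pd.Timestamp(f"{start_year}-01-01")
    return base + pd.to_timedelta(day * 24.0 + hour, unit="h")


def season_overpass_range(year: int, months: tuple[int, int], start_year: int,
                          n_slots: int) -> tuple[int, int]:
    """Half-open global-overpass range [g0, g1) covering the fire season."""
    lo, hi = months
    d0 = day_number(year, lo, 1, start_year)
    if hi == 12:
        d1 = day_number(year + 1, 1, 1, start_year)
    else:
        d1 = day_number(year, hi + 1, 1, start_year)
    return d0 * n_slots, d1 * n_slots


def year_overpass_range(year: int, start_year: int, n_slots: int) -> tuple[int, int]:
    d0 = day_number(year, 1, 1, start_year)
    d1 = day_number(year + 1, 1, 1, start_year)
    return d0 * n_slots, d1 * n_slots
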