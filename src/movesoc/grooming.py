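"""Daily sunrise-to-sunset grooming totals.

Bout records (give/receive, start/end instants) are clipped to the local
solar window and summed per individual-day in minutes; nocturnal activity is
excluded to avoid misclassified night-time records.  Sunrise and sunset come
from the standard NOAA solar-position equations at the conventional zenith
of 90.833 degrees (refraction + solar radius).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date as date_t, datetime, timedelta

import numpy as np
import pandas as pd

#: Default study-site coordinates and civil time offset.
SITE_LAT = -34.15562
SITE_LON = 18.39858
SITE_TZ_HOURS = 2.0

ZENITH_DEG = 90.833


@dataclass(frozen=True)
class SolarWindow:
    date: date_t
    sunrise: datetime            # local civil time (naive)
    sunset: datetime
    daylength_h: float


def _solar_params(jd: float) -> tuple[float, float]:
    """NOAA solar position at a Julian date: (equation of time [min],
    declination [rad]).  Accurate to a few seconds for sunrise work."""
    t = (jd - 2451545.0) / 36525.0
    geom_mean_long = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    geom_mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    m = math.radians(geom_mean_anom)
    eq_centre = (
        math.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * m) * (0.019993 - 0.000101 * t)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_centre
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0 = math.radians(geom_mean_long)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y**2 * math.sin(4 * l0)
        - 1.25 * ecc**2 * math.sin(2 * m)
    )
    return eqtime, decl


def solar_window(
    date: date_t,
    lat: float = SITE_LAT,
    lon: float = SITE_LON,
    tz_offset_hours: float = SITE_TZ_HOURS,
) -> SolarWindow:
    """Sunrise, sunset (local civil time) and daylength for one date."""
    if abs(lat) >= 66.0:
        raise ValueError("polar latitudes not supported (no guaranteed sunrise/sunset)")
    phi = math.radians(lat)
    jd_midnight = date.toordinal() + 1721424.5

    def _utc_minutes(rising: bool, minutes_guess: float) -> float:
        eqtime, decl = _solar_params(jd_midnight + minutes_guess / 1440.0)
        cos_ha = (
            math.cos(math.radians(ZENITH_DEG)) / (math.cos(phi) * math.cos(decl))
            - math.tan(phi) * math.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise ValueError("sun does not cross the horizon on this date")
        ha = math.degrees(math.acos(cos_ha))
        if not rising:
            ha = -ha
        return 720.0 - 4.0 * (lon + ha) - eqtime

    # two refinement passes: evaluate solar position at the event time itself
    rise_min = _utc_minutes(True, 360.0)
    rise_min = _utc_minutes(True, rise_min)
    rise_min = _utc_minutes(True, rise_min)
    set_min = _utc_minutes(False, 1080.0)
    set_min = _utc_minutes(False, set_min)
    set_min = _utc_minutes(False, set_min)

    midnight = datetime(date.year, date.month, date.day)
    sunrise = midnight + timedelta(minutes=rise_min + tz_offset_hours * 60.0)
    sunset = midnight + timedelta(minutes=set_min + tz_offset_hours * 60.0)
    return SolarWindow(date, sunrise, sunset, (sunset - sunrise).total_seconds() / 3600.0)


def _merge_overlaps(bouts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union overlapping intervals (seconds); warns if any overlap was found."""
    if not bouts:
        return []
    bouts = sorted(bouts)
    merged = [list(bouts[0])]
    overlapped = False
    for s, e in bouts[1:]:
        if s < merged[-1][1]:
            overlapped = True
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if overlapped:
        warnings.warn("overlapping same-direction grooming bouts merged", stacklevel=3)
    return [tuple(iv) for iv in merged]


def _clipped_minutes(
    bouts: list[tuple[float, float]], win_start: float, win_end: float
) -> float:
    total = 0.0
    for s, e in _merge_overlaps(bouts):
        total += max(0.0, min(e, win_end) - max(s, win_start))
    return total / 60.0


def daily_totals(
    bouts: pd.DataFrame,
    lat: float = SITE_LAT,
    lon: float = SITE_LON,
    tz_offset_hours: float = SITE_TZ_HOURS,
    days: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sunrise-to-sunset grooming minutes per individual-day.

    ``bouts`` needs ``individual_id``, ``start``, ``end`` (ISO timestamps,
    local civil time) and ``direction`` in {give, receive}.  Overlapping
    same-direction bouts are merged before summation.  ``days`` (optional,
    columns ``individual_id,date``) forces explicit zero rows for bout-free
    individual-days.
    """
    b = bouts.copy()
    b["start"] = pd.to_datetime(b["start"])
    b["end"] = pd.to_datetime(b["end"])
    if (b["end"] <= b["start"]).any():
        raise ValueError("bout end must be after start")
    bad = set(b["direction"]) - {"give", "receive"}
    if bad:
        raise ValueError(f"unknown grooming direction(s): {sorted(bad)}")
    b["date"] = b["start"].dt.date

    keys = b[["individual_id", "date"]].drop_duplicates()
    if days is not None:
        keys = pd.concat([keys, days[["individual_id", "date"]]]).drop_duplicates()
    keys = keys.sort_values(["individual_id", "date"]).reset_index(drop=True)

    windows = {
        d: solar_window(d, lat, lon, tz_offset_hours) for d in keys["date"].unique()
    }

    def _win_seconds(d: date_t) -> tuple[float, float]:
        midnight = datetime(d.year, d.month, d.day)
        win = windows[d]
        return (
            (win.sunrise - midnight).total_seconds(),
            (win.sunset - midnight).total_seconds(),
        )

    win_s = {d: _win_seconds(d) for d in windows}
    midnights = pd.to_datetime(b["date"].astype(str))
    start_s = (b["start"] - midnights).dt.total_seconds().to_numpy()
    end_s = (b["end"] - midnights).dt.total_seconds().to_numpy()
    w0 = b["date"].map(lambda d: win_s[d][0]).to_numpy(dtype=float)
    w1 = b["date"].map(lambda d: win_s[d][1]).to_numpy(dtype=float)

    # same-direction overlap check; merged per-group only where needed
    b = b.assign(_s=start_s, _e=end_s, _w0=w0, _w1=w1)
    b = b.sort_values(["individual_id", "date", "direction", "_s"])
    same = (
        b[["individual_id", "date", "direction"]]
        .ne(b[["individual_id", "date", "direction"]].shift())
        .any(axis=1)
    )
    overlapping = (~same) & (b["_s"].to_numpy() < b["_e"].shift().to_numpy())
    clipped = np.clip(
        np.minimum(b["_e"], b["_w1"]) - np.maximum(b["_s"], b["_w0"]), 0.0, None
    )
    b["_clipped_min"] = clipped / 60.0
    bad_groups = set(
        map(tuple, b.loc[overlapping, ["individual_id", "date", "direction"]]
            .itertuples(index=False))
    )
    totals = (
        b.groupby(["individual_id", "date", "direction"], sort=False)["_clipped_min"]
        .sum()
    )
    for key in bad_groups:  # redo with interval union (emits the warning)
        g = b[
            (b["individual_id"] == key[0])
            & (b["date"] == key[1])
            & (b["direction"] == key[2])
        ]
        totals.loc[key] = _clipped_minutes(
            list(zip(g["_s"], g["_e"])), g["_w0"].iloc[0], g["_w1"].iloc[0]
        )
    wide = totals.unstack("direction")
    out = keys.copy()
    for direction, col in (("give", "give_min"), ("receive", "receive_min")):
        if direction in wide.columns:
            mapped = wide[direction].reindex(
                pd.MultiIndex.from_frame(keys[["individual_id", "date"]])
            )
            out[col] = mapped.to_numpy()
        else:
            out[col] = 0.0
    out[["give_min", "receive_min"]] = out[["give_min", "receive_min"]].fillna(0.0)
    out["daylength_h"] = out["date"].map(lambda d: windows[d].daylength_h)
    return out[["individual_id", "date", "give_min", "receive_min", "daylength_h"]]
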