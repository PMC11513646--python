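"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: residence time by 1-s
path discretisation, proximity events by interval union over listed contact
frames, haversine distances, and a Julian-date sunrise-equation ephemeris.
"""

from __future__ import annotations

import math

import numpy as np


def haversine_m(lon1, lat1, lon2, lat2, radius=6_371_008.8) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def residence_time_bruteforce(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, radius: float, cutoff: float,
    resolution: float = 1.0,
) -> np.ndarray:
    """Per-fix residence minutes by dense linear interpolation of the path.

    The path is sampled every ``resolution`` seconds; from each focal fix the
    scan runs forward and backward accumulating inside-disc time, ending a
    direction once the path has stayed outside for more than ``cutoff``.
    """
    tt = np.arange(t[0], t[-1] + resolution / 2, resolution)
    xx = np.interp(tt, t, x)
    yy = np.interp(tt, t, y)
    out = np.empty(len(t))
    for i in range(len(t)):
        inside = (xx - x[i]) ** 2 + (yy - y[i]) ** 2 <= radius**2
        fi = int(round((t[i] - t[0]) / resolution))
        total = resolution if inside[fi] else 0.0
        for direction in (1, -1):
            outside_run = 0.0
            j = fi + direction
            while 0 <= j < len(tt):
                if inside[j]:
                    total += resolution
                    outside_run = 0.0
                else:
                    outside_run += resolution
                    if outside_run > cutoff:
                        break
                j += direction
        out[i] = total / 60.0
    return out


def residence_focal_is_knife_edge(
    t, x, y, focal_idx: int, radius: float, cutoff: float, margin: float = 2.0
) -> bool:
    """True when some outside-disc excursion sits within ``margin`` seconds of
    the cutoff, where a 1-s discretised oracle and an exact-geometry
    implementation may legitimately disagree about including a whole visit."""
    tt = np.arange(t[0], t[-1] + 0.5)
    xx = np.interp(tt, t, x)
    yy = np.interp(tt, t, y)
    outside = (xx - x[focal_idx]) ** 2 + (yy - y[focal_idx]) ** 2 > radius**2
    run = 0
    for flag in outside:
        if flag:
            run += 1
        else:
            if run and abs(run - cutoff) <= margin:
                return True
            run = 0
    return bool(run and abs(run - cutoff) <= margin)


def events_bruteforce(
    frames: "pd.DataFrame", threshold: float, merge_gap: float
) -> set[tuple]:
    """All merged dyadic events as (id_a, id_b, start, end) tuples.

    Stage (a): list every frame where a dyad is <= threshold apart (both
    present).  Stage (b): each contact instant is a degenerate interval.
    Stage (c): union intervals whose separation is <= merge_gap.
    """
    import pandas as pd

    contacts: dict[tuple, list[float]] = {}
    for tval, grp in frames.groupby("t"):
        rows = list(grp.itertuples())
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a.individual_id == b.individual_id:
                    continue
                d = math.hypot(a.x - b.x, a.y - b.y)
                if d <= threshold:
                    key = tuple(sorted((a.individual_id, b.individual_id)))
                    contacts.setdefault(key, []).append(float(tval))
    out = set()
    for key, times in contacts.items():
        times.sort()
        start = end = times[0]
        for tv in times[1:]:
            if tv - end <= merge_gap:
                end = tv
            else:
                out.add((key[0], key[1], start, end))
                start = end = tv
        out.add((key[0], key[1], start, end))
    return out


def grooming_minutes_bruteforce(
    intervals: list[tuple[float, float]], w0: float, w1: float, step: float = 1.0
) -> float:
    """Union-and-clip by 1-s discretisation: minutes of covered seconds."""
    if not intervals:
        return 0.0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    grid = np.arange(lo, hi, step)
    covered = np.zeros(len(grid), dtype=bool)
    for s, e in intervals:
        covered |= (grid >= s) & (grid < e)
    covered &= (grid >= w0) & (grid < w1)
    return float(covered.sum() * step / 60.0)


def sunrise_sunset_utc_hours(date, lat: float, lon: float) -> tuple[float, float]:
    """Sunrise/sunset (fractional UTC hours) via the Julian-date sunrise
    equation (mean anomaly -> equation of centre -> ecliptic longitude ->
    declination -> hour angle), independent of the NOAA-style expansion."""
    jd = date.toordinal() + 1721425.0   # Julian date at noon UTC
    n = jd - 2451545.0 + 0.0008
    j_star = n - lon / 360.0
    m = math.radians((357.5291 + 0.98560028 * j_star) % 360.0)
    c = 1.9148 * math.sin(m) + 0.02 * math.sin(2 * m) + 0.0003 * math.sin(3 * m)
    lam = math.radians((math.degrees(m) + c + 180.0 + 102.9372) % 360.0)
    j_transit = 2451545.0 + j_star + 0.0053 * math.sin(m) - 0.0069 * math.sin(2 * lam)
    delta = math.asin(math.sin(lam) * math.sin(math.radians(23.4397)))
    phi = math.radians(lat)
    cos_h = (
        math.sin(math.radians(-0.833)) - math.sin(phi) * math.sin(delta)
    ) / (math.cos(phi) * math.cos(delta))
    h = math.degrees(math.acos(max(-1.0, min(1.0, cos_h))))
    j_rise = j_transit - h / 360.0
    j_set = j_transit + h / 360.0
    to_hours = lambda j: ((j + 0.5) % 1.0) * 24.0
    return to_hours(j_rise), to_hours(j_set)
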