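"""Dyadic social-opportunity events from simultaneous multi-individual GPS.

An opportunity event is an episode during which two collared individuals are
within a distance threshold (2 m by default, boundary inclusive) of each
other; re-contacts separated by no more than a short merge gap (2 s) count
as the same event.  Daily per-individual event frequencies are retained only
for days with enough simultaneously active collars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_M = 2.0
DEFAULT_MERGE_GAP_S = 2.0
DEFAULT_MIN_COLLARS = 10


@dataclass(frozen=True)
class ProximityEvent:
    id_a: str
    id_b: str
    start: float        # seconds (same clock as the input frames)
    end: float

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("dyad members must be distinct")
        if self.end < self.start:
            raise ValueError("event end before start")

    @property
    def dyad(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))

    @property
    def duration(self) -> float:
        return self.end - self.start


def pairwise_distances(frame: dict) -> dict:
    """Euclidean distances for every unordered pair in one position frame.

    ``frame`` maps individual_id -> (x, y) in metres; fewer than two
    individuals give an empty mapping.
    """
    ids = sorted(frame)
    out = {}
    for a, b in combinations(ids, 2):
        ax, ay = frame[a]
        bx, by = frame[b]
        out[(a, b)] = float(np.hypot(ax - bx, ay - by))
    return out


def _contact_times_to_events(times: np.ndarray, merge_gap: float) -> list[tuple[float, float]]:
    """Union contact instants into events: split where the gap exceeds merge_gap.

    With frames at native (<= merge_gap) sampling this single pass is exactly
    the two-stage rule 'form consecutive-frame runs, then merge runs whose
    separation is <= merge_gap'.
    """
    if len(times) == 0:
        return []
    times = np.sort(times)
    cut = np.flatnonzero(np.diff(times) > merge_gap + 1e-9)
    starts = np.concatenate(([0], cut + 1))
    ends = np.concatenate((cut, [len(times) - 1]))
    return [(float(times[i]), float(times[j])) for i, j in zip(starts, ends)]


def detect_events(
    frames: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD_M,
    merge_gap: float = DEFAULT_MERGE_GAP_S,
) -> list[ProximityEvent]:
    """Detect merged dyadic proximity events from a long-format frame table.

    ``frames`` needs columns ``t`` (seconds, shared clock), ``individual_id``,
    ``x``, ``y``.  A frame contributes to a dyad only when both members are
    present at that instant; a missing fix interrupts the dyad's run exactly
    like a supra-threshold distance and is then subject to the merge rule.
    """
    if len(frames) == 0:
        return []
    tcodes, tvals = pd.factorize(frames["t"], sort=True)
    icodes, ivals = pd.factorize(frames["individual_id"], sort=True)
    t = np.asarray(tvals, dtype=float)
    ids = list(ivals)
    X = np.full((len(tvals), len(ivals)), np.nan)
    Y = np.full_like(X, np.nan)
    X[tcodes, icodes] = frames["x"].to_numpy(dtype=float)
    Y[tcodes, icodes] = frames["y"].to_numpy(dtype=float)
    events: list[ProximityEvent] = []
    for i, j in combinations(range(len(ids)), 2):
        d = np.hypot(X[:, i] - X[:, j], Y[:, i] - Y[:, j])
        with np.errstate(invalid="ignore"):
            contact = d <= threshold          # NaN compares False
        for s, e in _contact_times_to_events(t[contact], merge_gap):
            events.append(ProximityEvent(ids[i], ids[j], s, e))
    events.sort(key=lambda ev: (ev.start, ev.id_a, ev.id_b))
    return events


def events_to_frame(events: list[ProximityEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"id_a": ev.id_a, "id_b": ev.id_b, "start": ev.start,
             "end": ev.end, "duration_s": ev.duration}
            for ev in events
        ],
        columns=["id_a", "id_b", "start", "end", "duration_s"],
    )


def daily_counts(
    events: list[ProximityEvent] | pd.DataFrame,
    active: pd.DataFrame,
) -> pd.DataFrame:
    """Per-individual daily event frequencies with explicit zeros.

    Each merged event increments the count of BOTH dyad members on the day
    the event starts.  ``active`` is a long table ``individual_id,date`` of
    collar-active individual-days; it defines the rows (so a zero-event day
    still appears) and ``n_active_collars`` per day.
    """
    if isinstance(events, list):
        events = events_to_frame(events)
    active = active[["individual_id", "date"]].drop_duplicates()
    n_active = (
        active.groupby("date")["individual_id"].nunique().rename("n_active_collars")
    )
    out = active.merge(n_active, on="date")
    out["n_events"] = 0
    if len(events):
        if "date" not in events.columns:
            raise ValueError("events need a 'date' column for daily counting")
        long = pd.concat(
            [
                events.rename(columns={"id_a": "individual_id"})[["individual_id", "date"]],
                events.rename(columns={"id_b": "individual_id"})[["individual_id", "date"]],
            ]
        )
        counts = long.groupby(["individual_id", "date"]).size().rename("k")
        out = out.merge(counts, on=["individual_id", "date"], how="left")
        out["n_events"] = out["k"].fillna(0).astype(int)
        out = out.drop(columns="k")
    return out.sort_values(["date", "individual_id"]).reset_index(drop=True)


def filter_active(
    counts: pd.DataFrame, min_collars: int = DEFAULT_MIN_COLLARS
) -> pd.DataFrame:
    """Drop individual-days with fewer than ``min_collars`` active collars."""
    return counts[counts["n_active_collars"] >= min_collars].reset_index(drop=True)


def active_from_gps(gps: pd.DataFrame) -> pd.DataFrame:
    """Collar-active individual-days inferred from fix presence."""
    return gps[["individual_id", "date"]].drop_duplicates().reset_index(drop=True)


def daily_opportunities(
    gps: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD_M,
    merge_gap: float = DEFAULT_MERGE_GAP_S,
    min_collars: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end: normalised GPS table -> (events, filtered daily counts).

    Detection runs within each local day at native fix resolution.
    """
    all_events = []
    for date, day in gps.groupby("date", sort=True):
        evs = detect_events(day, threshold=threshold, merge_gap=merge_gap)
        if not evs:
            continue
        ef = events_to_frame(evs)
        ef["date"] = date
        all_events.append(ef)
    events = (
        pd.concat(all_events, ignore_index=True)
        if all_events
        else events_to_frame([]).assign(date=pd.Series(dtype=object))
    )
    counts = daily_counts(events, active_from_gps(gps))
    if min_collars is not None:
        counts = filter_active(counts, min_collars)
    return events, counts
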