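"""Daily mobility features from segmented GPS day traces.

Thirteen features are computed per participant-day, grouped as activity
(distance traveled, radius of gyration, maximum diameter, maximum distance
from home, average flight length, average flight duration), inactivity (home
time, probability paused), routine (physical circadian routine, and its
weekend/weekday-stratified variant), location diversity (significant-location
entropy, significant locations visited) and missing-data accounting (minutes
missing pre-imputation).

Significant locations are duration-weighted K-means clusters of all pauses of
at least 10 minutes across the study, with no two cluster centers closer than
400 m (violating centers are merged, duration-weighted, and the solution
re-converged).  Home is the significant location accumulating the most pause
time in the nightly 21:00-06:00 window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .imputation import minute_positions
from .segmentation import DAY_S, MINUTES_PER_DAY, DayTrace

DEFAULT_MERGE_RADIUS_M = 400.0
DEFAULT_MIN_PAUSE_MIN = 10.0
DEFAULT_HOME_RADIUS_M = 200.0
DEFAULT_ROUTINE_BIN_MIN = 30
NIGHT_START_S = 21 * 3600.0  # 21:00 local
NIGHT_END_S = 6 * 3600.0     # 06:00 next morning

FEATURE_COLUMNS = [
    "distance_traveled",
    "radius_of_gyration",
    "max_diameter",
    "max_distance_home",
    "avg_flight_length",
    "avg_flight_duration",
    "home_time",
    "probability_paused",
    "circadian_routine",
    "weekend_circadian_routine",
    "sig_location_entropy",
    "sig_locations_visited",
    "minutes_missing",
]


@dataclass
class SignificantLocation:
    label: int
    x: float
    y: float
    total_pause_minutes: float

    @property
    def center(self):
        return np.array([self.x, self.y])


@dataclass
class HomeLocation:
    participant_id: str
    x: float
    y: float
    radius: float = DEFAULT_HOME_RADIUS_M
    label: int = 0

    @property
    def center(self):
        return np.array([self.x, self.y])


def _collect_pauses(day_traces, include_imputed=True, include_excluded=False):
    """(x, y, start, end) arrays over all pauses of the given traces."""
    xs, ys, t0, t1 = [], [], [], []
    for tr in day_traces:
        if tr.excluded and not include_excluded:
            continue
        for s in tr.segments:
            if s.kind != "pause":
                continue
            if s.imputed and not include_imputed:
                continue
            xs.append(s.x0)
            ys.append(s.y0)
            t0.append(s.start)
            t1.append(s.end)
    return (np.asarray(xs), np.asarray(ys), np.asarray(t0), np.asarray(t1))


def find_significant_locations(day_traces, k_max=10,
                               merge_radius=DEFAULT_MERGE_RADIUS_M,
                               min_pause_minutes=DEFAULT_MIN_PAUSE_MIN,
                               seed=0, include_imputed=True):
    """Duration-weighted K-means clustering of qualifying pause positions.

    Starts from ``k_max`` clusters (capped at the number of distinct pause
    positions), then repeatedly merges the closest pair of centers nearer
    than ``merge_radius`` (weighted by accumulated pause time) and
    re-converges, so the result keeps the maximal number of well-separated
    locations.  Deterministic given ``seed``.
    """
    x, y, t0, t1 = _collect_pauses(day_traces, include_imputed=include_imputed)
    if len(x) == 0:
        warnings.warn("no qualifying pauses; no significant locations found")
        return []
    dur_min = (t1 - t0) / 60.0
    qual = dur_min >= min_pause_minutes
    if not np.any(qual):
        warnings.warn("no qualifying pauses; no significant locations found")
        return []
    pts = np.column_stack([x[qual], y[qual]])
    w = dur_min[qual]
    uniq = np.unique(np.round(pts, 3), axis=0)
    k = int(min(k_max, len(uniq)))
    if k == 1:
        centers = np.average(pts, axis=0, weights=w)[None, :]
    else:
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        km.fit(pts, sample_weight=w)
        centers = km.cluster_centers_
    while len(centers) > 1:
        d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        if d2[i, j] >= merge_radius ** 2:
            break
        assign = np.argmin(
            np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1), axis=1)
        wi = w[assign == i].sum() or 1.0
        wj = w[assign == j].sum() or 1.0
        merged = (centers[i] * wi + centers[j] * wj) / (wi + wj)
        centers = np.delete(centers, [i, j], axis=0)
        centers = np.vstack([centers, merged])
        if len(centers) > 1:
            km = KMeans(n_clusters=len(centers), init=centers, n_init=1,
                        max_iter=300)
            km.fit(pts, sample_weight=w)
            centers = km.cluster_centers_
    assign = np.argmin(
        np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1), axis=1)
    totals = np.array([w[assign == c].sum() for c in range(len(centers))])
    order = np.argsort(-totals)
    return [SignificantLocation(label=r, x=float(centers[c, 0]),
                                y=float(centers[c, 1]),
                                total_pause_minutes=float(totals[c]))
            for r, c in enumerate(order)]


def _night_overlap(start, end):
    """Seconds of [start, end] (absolute study seconds) falling inside nightly
    21:00-06:00 windows."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    total = np.zeros_like(start)
    d_lo = np.floor(start / DAY_S).astype(int) - 1
    d_hi = np.floor(end / DAY_S).astype(int)
    for i in range(len(total)):
        acc = 0.0
        for d in range(d_lo[i], d_hi[i] + 1):
            a = d * DAY_S + NIGHT_START_S
            b = (d + 1) * DAY_S + NIGHT_END_S
            acc += max(0.0, min(end[i], b) - max(start[i], a))
        total[i] = acc
    return total


def infer_home(significant_locations, day_traces, participant_id=None,
               radius=DEFAULT_HOME_RADIUS_M):
    """The significant location with the largest total pause time in the
    nightly 21:00-06:00 window over all non-excluded days.

    Ties break by larger total pause time overall, then by lowest label.
    """
    if not significant_locations:
        raise ValueError("no significant locations to infer home from")
    x, y, t0, t1 = _collect_pauses(day_traces)
    pid = participant_id or day_traces[0].participant_id
    centers = np.array([[s.x, s.y] for s in significant_locations])
    if len(x) == 0:
        best = significant_locations[0]
        return HomeLocation(pid, best.x, best.y, radius, best.label)
    assign = np.argmin(
        (x[:, None] - centers[None, :, 0]) ** 2
        + (y[:, None] - centers[None, :, 1]) ** 2, axis=1)
    night = _night_overlap(t0, t1)
    total = t1 - t0
    night_per = np.zeros(len(centers))
    total_per = np.zeros(len(centers))
    np.add.at(night_per, assign, night)
    np.add.at(total_per, assign, total)
    labels = np.array([s.label for s in significant_locations])
    order = np.lexsort((labels, -total_per, -night_per))
    best = significant_locations[int(order[0])]
    return HomeLocation(pid, best.x, best.y, radius, best.label)


def location_entropy(day_trace, significant_locations,
                     radius=DEFAULT_HOME_RADIUS_M):
    """Shannon entropy (nats) of the day's pause-time shares across
    significant locations, and the number of locations visited.

    A pause counts toward the nearest significant location within ``radius``
    meters of its position; p_i are shares of total pause minutes spent at
    any significant location that day.
    """
    if not significant_locations:
        return 0.0, 0
    centers = np.array([[s.x, s.y] for s in significant_locations])
    minutes = np.zeros(len(centers))
    for s in day_trace.segments:
        if s.kind != "pause":
            continue
        d2 = (centers[:, 0] - s.x0) ** 2 + (centers[:, 1] - s.y0) ** 2
        c = int(np.argmin(d2))
        if d2[c] <= radius ** 2:
            minutes[c] += s.duration / 60.0
    tot = minutes.sum()
    if tot <= 0:
        return 0.0, 0
    p = minutes[minutes > 0] / tot
    return float(-(p * np.log(p)).sum()), int((minutes > 0).sum())


def circadian_routine_series(day_traces, stratified=False,
                             bin_minutes=DEFAULT_ROUTINE_BIN_MIN,
                             radius=DEFAULT_HOME_RADIUS_M,
                             include_imputed=True, grid=None):
    """Physical circadian routine for every day of one participant.

    The day is discretized into ``bin_minutes`` bins; for each bin with a
    known position on the target day, the fraction of other comparable days
    whose same-bin position lies within ``radius`` m is computed, and the
    routine is the mean over bins.  ``stratified=True`` compares weekend days
    only with weekend days and weekdays only with weekdays.  Days with no
    comparable day yield NaN.  Ranges from 0 (never in the same place at the
    same time) to 1 (identical routine).
    """
    traces = sorted(day_traces, key=lambda tr: tr.day_index)
    if grid is None:
        grid = minute_positions(traces, include_imputed=include_imputed)
    pos, known = grid
    n_days = pos.shape[0]
    mids = np.arange(0, MINUTES_PER_DAY, bin_minutes) + bin_minutes // 2
    bp = pos[:, mids, :]          # (n_days, n_bins, 2)
    bk = known[:, mids]           # (n_days, n_bins)
    weekend = np.zeros(n_days, dtype=bool)
    excluded = np.ones(n_days, dtype=bool)
    for tr in traces:
        weekend[tr.day_index] = tr.date.weekday() >= 5
        excluded[tr.day_index] = tr.excluded
    out = {}
    for tr in traces:
        d = tr.day_index
        if tr.excluded:
            out[d] = np.nan
            continue
        comp = ~excluded
        comp[d] = False
        if stratified:
            comp &= weekend == weekend[d]
        if not comp.any():
            out[d] = np.nan
            continue
        diff = bp[comp] - bp[d][None, :, :]           # (n_comp, n_bins, 2)
        near = (diff[..., 0] ** 2 + diff[..., 1] ** 2) <= radius ** 2
        valid = bk[comp] & bk[d][None, :]
        n_valid = valid.sum(axis=0)                   # per bin
        use = bk[d] & (n_valid > 0)
        if not use.any():
            out[d] = np.nan
            continue
        frac = (near & valid).sum(axis=0)[use] / n_valid[use]
        out[d] = float(frac.mean())
    return out


def compute_daily_features(day_trace, home, significant_locations,
                           home_radius=DEFAULT_HOME_RADIUS_M):
    """The per-day feature dict, excluding the two routine features (which
    need the full study period and are filled in by
    :func:`daily_feature_table`)."""
    segs = day_trace.segments
    feat = dict.fromkeys(FEATURE_COLUMNS, np.nan)
    feat["minutes_missing"] = day_trace.minutes_missing_preimputation
    if not segs:
        return feat
    flights = [s for s in segs if s.kind == "flight"]
    pauses = [s for s in segs if s.kind == "pause"]
    flight_s = sum(s.duration for s in flights)
    pause_s = sum(s.duration for s in pauses)
    if flight_s + pause_s <= 0:
        return feat

    feat["distance_traveled"] = float(sum(s.length for s in flights))
    feat["avg_flight_length"] = (float(np.mean([s.length for s in flights]))
                                 if flights else 0.0)
    feat["avg_flight_duration"] = (float(np.mean([s.duration for s in flights]))
                                   if flights else 0.0)
    feat["probability_paused"] = pause_s / (pause_s + flight_s)

    # time-weighted radius of gyration: pauses at their centroid, flights at
    # their midpoint, weighted by duration
    px = np.array([(s.x0 + s.x1) / 2.0 for s in segs])
    py = np.array([(s.y0 + s.y1) / 2.0 for s in segs])
    wt = np.array([s.duration for s in segs])
    cx = np.average(px, weights=wt)
    cy = np.average(py, weights=wt)
    feat["radius_of_gyration"] = float(
        np.average(np.hypot(px - cx, py - cy), weights=wt))

    if pauses:
        qx = np.array([s.x0 for s in pauses])
        qy = np.array([s.y0 for s in pauses])
        if len(pauses) > 1:
            d2 = ((qx[:, None] - qx[None, :]) ** 2
                  + (qy[:, None] - qy[None, :]) ** 2)
            feat["max_diameter"] = float(np.sqrt(d2.max()))
        else:
            feat["max_diameter"] = 0.0
        dh = np.hypot(qx - home.x, qy - home.y)
        feat["max_distance_home"] = float(dh.max()) if np.any(dh > home_radius) else 0.0
        near = dh <= home_radius
        feat["home_time"] = float(
            sum(s.duration for s, n in zip(pauses, near) if n) / 60.0)
    else:
        feat["max_diameter"] = 0.0
        feat["max_distance_home"] = 0.0
        feat["home_time"] = 0.0

    ent, nvis = location_entropy(day_trace, significant_locations,
                                 radius=home_radius)
    feat["sig_location_entropy"] = ent
    feat["sig_locations_visited"] = nvis
    return feat


def daily_feature_table(day_traces, k_max=10,
                        merge_radius=DEFAULT_MERGE_RADIUS_M,
                        min_pause_minutes=DEFAULT_MIN_PAUSE_MIN,
                        home_radius=DEFAULT_HOME_RADIUS_M,
                        bin_minutes=DEFAULT_ROUTINE_BIN_MIN,
                        seed=0):
    """All 13 daily features for one participant as a DataFrame.

    One row per day (excluded days flagged, features NaN), columns
    ``participant_id, date, excluded`` plus :data:`FEATURE_COLUMNS`.
    """
    traces = sorted(day_traces, key=lambda tr: tr.day_index)
    sig = find_significant_locations(traces, k_max=k_max,
                                     merge_radius=merge_radius,
                                     min_pause_minutes=min_pause_minutes,
                                     seed=seed)
    rows = []
    if sig:
        home = infer_home(sig, traces, radius=home_radius)
        grid = minute_positions(traces, include_imputed=True)
        routine = circadian_routine_series(traces, stratified=False,
                                           bin_minutes=bin_minutes,
                                           radius=home_radius, grid=grid)
        routine_w = circadian_routine_series(traces, stratified=True,
                                             bin_minutes=bin_minutes,
                                             radius=home_radius, grid=grid)
    for tr in traces:
        if not sig or tr.excluded:
            feat = dict.fromkeys(FEATURE_COLUMNS, np.nan)
            feat["minutes_missing"] = tr.minutes_missing_preimputation
        else:
            feat = compute_daily_features(tr, home, sig, home_radius=home_radius)
            feat["circadian_routine"] = routine[tr.day_index]
            feat["weekend_circadian_routine"] = routine_w[tr.day_index]
        rows.append({"participant_id": tr.participant_id,
                     "date": tr.date, "excluded": tr.excluded, **feat})
    return pd.DataFrame(rows)
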