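"""Flight/pause segmentation of raw GPS streams.

A *pause* is a maximal interval during which every fix stays within
``pause_radius`` of the interval's running centroid and that lasts at least
``min_pause_duration`` seconds; the pause is represented by its centroid.
Motion between pauses is approximated by a chain of *flights* (straight
segments between fixes), merged while consecutive steps remain collinear
within a tolerance.  Fixes separated by more than ``max_fix_gap`` never form
a segment: they open a missing interval, which downstream imputation may
fill.

Times are handled as float seconds since local midnight of the first study
day, so day ``d`` occupies ``[d*86400, (d+1)*86400)``.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import project_local

DAY_S = 86_400.0
MINUTES_PER_DAY = 1440

DEFAULT_PAUSE_RADIUS_M = 10.0
DEFAULT_MIN_PAUSE_S = 300.0
DEFAULT_MAX_FIX_GAP_S = 300.0
DEFAULT_COLLINEAR_TOL_M = 10.0
DEFAULT_MAX_ACCURACY_M = 100.0

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass
class MobilitySegment:
    """One flight or pause.  Positions are local planar meters."""

    kind: str  # "pause" | "flight"
    start: float  # seconds since study-start midnight
    end: float
    x0: float
    y0: float
    x1: float
    y1: float
    imputed: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def length(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))

    def position_at(self, t: float) -> tuple[float, float]:
        """Linear position along the segment at absolute time ``t``."""
        if self.kind == "pause" or self.end <= self.start:
            return self.x0, self.y0
        f = (t - self.start) / (self.end - self.start)
        f = min(max(f, 0.0), 1.0)
        return (self.x0 + f * (self.x1 - self.x0),
                self.y0 + f * (self.y1 - self.y0))


@dataclass
class DayTrace:
    """Segments and missing-data accounting for one participant-day."""

    participant_id: str
    date: dt.date
    day_index: int
    segments: list[MobilitySegment] = field(default_factory=list)
    minutes_missing_preimputation: int = MINUTES_PER_DAY
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def day_start(self) -> float:
        return self.day_index * DAY_S

    def observed_segments(self) -> list[MobilitySegment]:
        return [s for s in self.segments if not s.imputed]


@njit(cache=True)
def _find_pauses(x, y, t, pause_radius, min_pause):
    """Greedy running-centroid pause detection on one gap-free run.

    Returns parallel arrays (start index, end index, centroid x, centroid y).
    """
    n = x.shape[0]
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    cxs = np.empty(n, dtype=np.float64)
    cys = np.empty(n, dtype=np.float64)
    m = 0
    r2 = pause_radius * pause_radius
    i = 0
    while i < n:
        j = i
        sx = x[i]
        sy = y[i]
        cnt = 1.0
        cx = sx
        cy = sy
        while j + 1 < n:
            dx = x[j + 1] - cx
            dy = y[j + 1] - cy
            if dx * dx + dy * dy <= r2:
                j += 1
                sx += x[j]
                sy += y[j]
                cnt += 1.0
                cx = sx / cnt
                cy = sy / cnt
            else:
                break
        if j > i and t[j] - t[i] >= min_pause:
            starts[m] = i
            ends[m] = j
            cxs[m] = cx
            cys[m] = cy
            m += 1
            i = j + 1
        else:
            i += 1
    return starts[:m], ends[:m], cxs[:m], cys[:m]


@njit(cache=True)
def _merge_collinear(px, py, tol):
    """Merge a fix path into flights while points stay within ``tol`` of the
    chord; returns breakpoint indices (consecutive pairs are flights)."""
    n = px.shape[0]
    bounds = np.empty(n, dtype=np.int64)
    bounds[0] = 0
    m = 1
    a = 0
    while a < n - 1:
        b = a + 1
        while b + 1 < n:
            # max perpendicular deviation of points a+1..b from chord a->b+1
            bx = px[b + 1] - px[a]
            by = py[b + 1] - py[a]
            norm = np.sqrt(bx * bx + by * by)
            ok = True
            if norm < 1e-9:
                # chord degenerate: require all points near the endpoint
                for k in range(a + 1, b + 1):
                    dx = px[k] - px[a]
                    dy = py[k] - py[a]
                    if np.sqrt(dx * dx + dy * dy) > tol:
                        ok = False
                        break
            else:
                for k in range(a + 1, b + 1):
                    dev = abs((px[k] - px[a]) * by - (py[k] - py[a]) * bx) / norm
                    if dev > tol:
                        ok = False
                        break
            if ok:
                b += 1
            else:
                break
        bounds[m] = b
        m += 1
        a = b
    return bounds[:m]


def _segment_run(x, y, t, pause_radius, min_pause, collinear_tol, imputed=False):
    """Segment one gap-free run of fixes into pauses and flights."""
    segs: list[MobilitySegment] = []
    if len(x) < 2:
        return segs
    ps, pe, cx, cy = _find_pauses(
        np.ascontiguousarray(x, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(t, dtype=np.float64),
        float(pause_radius), float(min_pause))

    # boundaries of the movement paths between pauses (inclusive fix indices)
    n = len(x)
    anchors = []  # (path_lo, path_hi, start_pos, end_pos) with pause-centroid endpoints
    prev_end = 0
    prev_pos = None  # centroid of previous pause
    for k in range(len(ps)):
        i, j = int(ps[k]), int(pe[k])
        if i > prev_end or (prev_pos is None and i > 0):
            anchors.append((prev_end, i, prev_pos, (cx[k], cy[k])))
        elif prev_pos is not None and i == prev_end:
            anchors.append((prev_end, i, prev_pos, (cx[k], cy[k])))
        segs.append(MobilitySegment("pause", float(t[i]), float(t[j]),
                                    float(cx[k]), float(cy[k]),
                                    float(cx[k]), float(cy[k]), imputed))
        prev_end = j
        prev_pos = (cx[k], cy[k])
    if prev_end < n - 1:
        anchors.append((prev_end, n - 1, prev_pos, None))

    for lo, hi, p0, p1 in anchors:
        if hi <= lo:
            continue
        idx = np.arange(lo, hi + 1)
        px = np.ascontiguousarray(x[idx], dtype=np.float64)
        py = np.ascontiguousarray(y[idx], dtype=np.float64)
        pt = t[idx].astype(float)
        if p0 is not None:
            px[0], py[0] = p0
        if p1 is not None:
            px[-1], py[-1] = p1
        bounds = _merge_collinear(px, py, float(collinear_tol))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if pt[b] > pt[a]:
                segs.append(MobilitySegment("flight", float(pt[a]), float(pt[b]),
                                            float(px[a]), float(py[a]),
                                            float(px[b]), float(py[b]), imputed))
    segs.sort(key=lambda s: s.start)
    return segs


def segment_flights_pauses(x, y, t,
                           pause_radius=DEFAULT_PAUSE_RADIUS_M,
                           min_pause_duration=DEFAULT_MIN_PAUSE_S,
                           max_fix_gap=DEFAULT_MAX_FIX_GAP_S,
                           collinear_tol=DEFAULT_COLLINEAR_TOL_M):
    """Segment a time-sorted, projected fix stream into flights and pauses.

    Fixes separated by more than ``max_fix_gap`` seconds split the stream into
    independent runs; the interval between runs is missing, never a flight.
    Empty input or a single isolated fix yields no segments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("fixes must be time-sorted")
    gap_idx = np.flatnonzero(np.diff(t) > max_fix_gap)
    bounds = np.concatenate(([0], gap_idx + 1, [len(t)]))
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.extend(_segment_run(x[a:b], y[a:b], t[a:b],
                                 pause_radius, min_pause_duration, collinear_tol))
    return segs


def coverage_mask(t, max_fix_gap, n_days):
    """Boolean minute grid (n_days*1440) of observed coverage.

    A minute is covered when a fix falls in it or when it overlaps the span
    between two fixes no more than ``max_fix_gap`` apart (an ongoing observed
    pause or flight bridges it).
    """
    n_min = n_days * MINUTES_PER_DAY
    covered = np.zeros(n_min + 1, dtype=np.int64)
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        return np.zeros(n_min, dtype=bool)
    fix_min = np.clip((t // 60).astype(np.int64), 0, n_min - 1)
    lo = fix_min.copy()
    hi = fix_min + 1
    if len(t) > 1:
        ok = np.diff(t) <= max_fix_gap
        lo2 = fix_min[:-1][ok]
        hi2 = fix_min[1:][ok] + 1
        lo = np.concatenate([lo, lo2])
        hi = np.concatenate([hi, hi2])
    diff = np.zeros(n_min + 1, dtype=np.int64)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi, -1)
    return np.cumsum(diff)[:-1] > 0


def minutes_missing(t_seconds_of_day, max_fix_gap=DEFAULT_MAX_FIX_GAP_S):
    """Whole minutes of a 1440-minute day with no fix and no bridging
    observed interval.  ``t_seconds_of_day`` are fix times in [0, 86400)."""
    t = np.asarray(t_seconds_of_day, dtype=float)
    mask = coverage_mask(t, max_fix_gap, 1)
    return int(MINUTES_PER_DAY - mask.sum())


def _split_segment_at_midnights(seg):
    """Yield copies of ``seg`` clipped to single days."""
    d0 = int(seg.start // DAY_S)
    d1 = int(np.ceil(seg.end / DAY_S)) - 1 if seg.end % DAY_S == 0 and seg.end > seg.start else int(seg.end // DAY_S)
    if d1 <= d0:
        yield d0, seg
        return
    for d in range(d0, d1 + 1):
        a = max(seg.start, d * DAY_S)
        b = min(seg.end, (d + 1) * DAY_S)
        if b <= a:
            continue
        xa, ya = seg.position_at(a)
        xb, yb = seg.position_at(b)
        yield d, MobilitySegment(seg.kind, a, b, xa, ya, xb, yb, seg.imputed)


def segment_stream(df, anchor=None, tz="UTC", study_days=None,
                   pause_radius=DEFAULT_PAUSE_RADIUS_M,
                   min_pause_duration=DEFAULT_MIN_PAUSE_S,
                   max_fix_gap=DEFAULT_MAX_FIX_GAP_S,
                   collinear_tol=DEFAULT_COLLINEAR_TOL_M,
                   max_accuracy=DEFAULT_MAX_ACCURACY_M):
    """Segment one participant's raw record stream into per-day traces.

    Parameters
    ----------
    df : DataFrame
        Columns ``participant_id, timestamp, latitude, longitude`` and
        optionally ``accuracy`` (fixes with accuracy > ``max_accuracy`` m are
        discarded before segmentation).
    anchor : (lat, lon), optional
        Projection anchor; defaults to the median fix position.
    tz : str
        Study timezone; day boundaries fall at local midnight.
    study_days : int, optional
        Number of days in the study window (defaults to the observed span).

    Returns
    -------
    traces : list of DayTrace
    epoch : pandas.Timestamp
        Local midnight of the first study day.
    """
    if len(df) == 0:
        raise ValueError("empty record stream")
    pid = str(df["participant_id"].iloc[0])
    ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(tz)
    tsv = ts.to_numpy(dtype="datetime64[ns]")  # wall-clock instants (UTC)
    order = np.argsort(tsv, kind="stable")
    df = df.iloc[order]
    tsv = tsv[order]
    if "accuracy" in df.columns:
        keep = df["accuracy"].to_numpy(dtype=float) <= max_accuracy
        df = df.loc[keep]
        tsv = tsv[keep]
        if len(df) == 0:
            raise ValueError("no records pass the accuracy filter")
    epoch = pd.Timestamp(tsv[0], tz="UTC").tz_convert(tz).normalize()
    epoch_ns = epoch.tz_convert("UTC").tz_localize(None).to_datetime64()
    t = (tsv - epoch_ns).astype("timedelta64[ns]").astype(np.int64) / 1e9
    lat = df["latitude"].to_numpy(dtype=float)
    lon = df["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    if anchor is None:
        anchor = (float(np.median(lat)), float(np.median(lon)))
    x, y = project_local(lat, lon, anchor[0], anchor[1])

    if study_days is None:
        study_days = int(t[-1] // DAY_S) + 1
    segs = segment_flights_pauses(x, y, t, pause_radius, min_pause_duration,
                                  max_fix_gap, collinear_tol)
    cov = coverage_mask(t, max_fix_gap, study_days)

    per_day: dict[int, list[MobilitySegment]] = {d: [] for d in range(study_days)}
    for seg in segs:
        for d, piece in _split_segment_at_midnights(seg):
            if 0 <= d < study_days:
                per_day[d].append(piece)
    traces = []
    for d in range(study_days):
        day_cov = cov[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY]
        traces.append(DayTrace(
            participant_id=pid,
            date=(epoch + pd.Timedelta(days=d)).date(),
            day_index=d,
            segments=sorted(per_day[d], key=lambda s: s.start),
            minutes_missing_preimputation=int(MINUTES_PER_DAY - day_cov.sum()),
        ))
    return traces, epoch


def exclude_days(day_traces, exclusion_list):
    """Flag listed (participant, date, reason) days as excluded.

    Raises ``ValueError`` naming the first row whose participant/date does
    not occur in ``day_traces``.  Returns the same list (mutated in place).
    """
    index = {(tr.participant_id, tr.date): tr for tr in day_traces}
    for row in exclusion_list:
        pid, date, reason = row[0], row[1], (row[2] if len(row) > 2 else "listed")
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        key = (str(pid), date)
        if key not in index:
            raise ValueError(f"exclusion row refers to unknown participant-day: {key}")
        index[key].excluded = True
        index[key].exclusion_reason = reason
    by_pid: dict[str, list[DayTrace]] = {}
    for tr in day_traces:
        by_pid.setdefault(tr.participant_id, []).append(tr)
    for pid, trs in by_pid.items():
        if all(tr.excluded for tr in trs):
            warnings.warn(f"all days excluded for participant {pid}; "
                          "participant will be dropped downstream")
    return day_traces


def segments_frame(day_traces):
    """Flatten day traces into the segments CSV surface."""
    rows = []
    for tr in day_traces:
        for s in tr.segments:
            rows.append({
                "participant_id": tr.participant_id,
                "date": tr.date.isoformat(),
                "kind": s.kind,
                "start_s": s.start,
                "end_s": s.end,
                "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
                "length_m": s.length if s.kind == "flight" else 0.0,
                "duration_s": s.duration,
                "imputed": s.imputed,
            })
    return pd.DataFrame(rows)
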