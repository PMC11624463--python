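"""Hot-deck gap imputation for segmented GPS day traces.

Smartphone GPS streams lose large stretches of each day (screen off, app
permissions, battery saving).  Before daily features are computed, each
missing interval is filled by resampling the participant's *own* observed
trajectory: a donor window at the same clock time on another day (allowing
small clock shifts, weighted by a Gaussian kernel on the shift) is copied
into the gap, translated so it starts at the last observed position and
linearly corrected so it ends at the next observed position.  When no donor
window exists, the gap is filled stationary at the last known location.

Imputed intervals are re-segmented into flights and pauses and flagged
``imputed``; observed segments and the pre-imputation missing-minute count
are never altered.  This is a deliberately simple single-imputation scheme
(optionally repeated and averaged at the feature level) rather than a full
multiple-imputation posterior.
"""

from __future__ import annotations

import warnings

import numpy as np

from .segmentation import (DAY_S, MINUTES_PER_DAY, DayTrace, MobilitySegment,
                           segment_flights_pauses)

#: candidate clock shifts (minutes) for donor windows
DEFAULT_SHIFTS_MIN = (0, -30, 30, -60, 60, -120, 120)
#: SD (hours) of the Gaussian kernel weighting donor clock shifts
DEFAULT_TIME_KERNEL_H = 2.0


def minute_positions(day_traces, include_imputed=False):
    """Minute-midpoint position grid for one participant.

    Returns ``(pos, known)`` with ``pos`` of shape (n_days, 1440, 2) and a
    matching boolean mask; minute m of day d is known when a segment covers
    the instant ``d*86400 + m*60 + 30``.
    """
    n_days = max(tr.day_index for tr in day_traces) + 1
    pos = np.full((n_days, MINUTES_PER_DAY, 2), np.nan, dtype=np.float64)
    known = np.zeros((n_days, MINUTES_PER_DAY), dtype=bool)
    for tr in day_traces:
        d = tr.day_index
        off = d * DAY_S
        for s in tr.segments:
            if s.imputed and not include_imputed:
                continue
            a = s.start - off
            b = s.end - off
            m_lo = int(np.ceil((a - 30.0) / 60.0))
            m_hi = int(np.floor((b - 30.0) / 60.0))
            m_lo = max(m_lo, 0)
            m_hi = min(m_hi, MINUTES_PER_DAY - 1)
            if m_hi < m_lo:
                continue
            ms = np.arange(m_lo, m_hi + 1)
            tm = ms * 60.0 + 30.0
            if s.kind == "pause" or s.end <= s.start:
                pos[d, ms, 0] = s.x0
                pos[d, ms, 1] = s.y0
            else:
                f = np.clip((tm - a) / (b - a), 0.0, 1.0)
                pos[d, ms, 0] = s.x0 + f * (s.x1 - s.x0)
                pos[d, ms, 1] = s.y0 + f * (s.y1 - s.y0)
            known[d, ms] = True
    return pos, known


def _unknown_runs(mask_row):
    """Maximal runs of False as (start, stop) minute pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], ~mask_row, [False])).astype(np.int8)))
    return list(zip(idx[::2], idx[1::2]))


def _path_to_segments(path, m0, m1, day_offset, pause_radius, collinear_tol):
    """Convert a minute-midpoint path into imputed segments tiling the gap."""
    t = day_offset + np.arange(m0, m1) * 60.0 + 30.0
    gap_start = day_offset + m0 * 60.0
    gap_end = day_offset + m1 * 60.0
    if len(path) == 1:
        return [MobilitySegment("pause", gap_start, gap_end,
                                path[0, 0], path[0, 1], path[0, 0], path[0, 1],
                                imputed=True)]
    segs = segment_flights_pauses(path[:, 0], path[:, 1], t,
                                  pause_radius=pause_radius,
                                  min_pause_duration=120.0,
                                  max_fix_gap=1e18,
                                  collinear_tol=collinear_tol)
    if not segs:
        c = path.mean(axis=0)
        return [MobilitySegment("pause", gap_start, gap_end,
                                c[0], c[1], c[0], c[1], imputed=True)]
    for s in segs:
        s.imputed = True
    # stretch the boundary segments to tile the full gap
    segs[0].start = gap_start
    segs[-1].end = gap_end
    return segs


def impute_gaps(day_traces, seed=0, pause_radius=10.0, collinear_tol=10.0,
                shifts_min=DEFAULT_SHIFTS_MIN,
                time_kernel_h=DEFAULT_TIME_KERNEL_H):
    """Fill missing intervals of one participant's day traces.

    Operates in place on non-excluded days and returns ``day_traces``.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    traces = sorted(day_traces, key=lambda tr: tr.day_index)
    pos, known = minute_positions(traces, include_imputed=False)
    n_days = pos.shape[0]
    usable = np.zeros(n_days, dtype=bool)
    by_index = {tr.day_index: tr for tr in traces}
    for tr in traces:
        usable[tr.day_index] = not tr.excluded
    # prefix sums for O(1) "window fully observed" queries
    kcum = np.concatenate([np.zeros((n_days, 1), dtype=np.int64),
                           np.cumsum(known, axis=1)], axis=1)
    shifts = np.asarray(shifts_min, dtype=np.int64)
    kernel_w = np.exp(-0.5 * (shifts / (60.0 * time_kernel_h)) ** 2)

    any_gap = False
    all_fallback = True
    for tr in traces:
        if tr.excluded:
            continue
        d = tr.day_index
        for m0, m1 in _unknown_runs(known[d]):
            any_gap = True
            # anchors: last known position before / first after the gap
            p0 = p1 = None
            if m0 > 0 and known[d, m0 - 1]:
                p0 = pos[d, m0 - 1]
            elif d > 0 and known[d - 1, MINUTES_PER_DAY - 1]:
                p0 = pos[d - 1, MINUTES_PER_DAY - 1]
            if m1 < MINUTES_PER_DAY and known[d, m1]:
                p1 = pos[d, m1]
            elif m1 == MINUTES_PER_DAY and d + 1 < n_days and known[d + 1, 0]:
                p1 = pos[d + 1, 0]

            a_s = np.clip(m0 + shifts, 0, MINUTES_PER_DAY)
            b_s = np.clip(m1 + shifts, 0, MINUTES_PER_DAY)
            in_range = (m0 + shifts >= 0) & (m1 + shifts <= MINUTES_PER_DAY)
            # (n_days, n_shifts): donor window fully observed
            full = (kcum[:, b_s] - kcum[:, a_s]) == (m1 - m0)
            full &= in_range[None, :] & usable[:, None]
            full[d, :] = False
            cand_d, cand_s = np.nonzero(full)
            if len(cand_d):
                all_fallback = False
                w = kernel_w[cand_s]
                pick = np.searchsorted(np.cumsum(w), rng.random() * w.sum())
                pick = min(pick, len(cand_d) - 1)
                e = int(cand_d[pick])
                s = int(shifts[cand_s[pick]])
                path = pos[e, m0 + s:m1 + s].copy()
                if p0 is not None:
                    path += p0 - path[0]
                elif p1 is not None:
                    path += p1 - path[-1]
                if p0 is not None and p1 is not None and len(path) > 1:
                    corr = (p1 - path[-1])
                    path += np.linspace(0.0, 1.0, len(path))[:, None] * corr
            else:
                # stationary fallback at the last known location
                if p0 is None and p1 is None:
                    continue  # nothing observed nearby: leave unfilled
                anchor = p0 if p0 is not None else p1
                if (p0 is not None and p1 is not None
                        and np.hypot(*(p1 - p0)) > pause_radius):
                    f = np.linspace(0.0, 1.0, max(m1 - m0, 2))[:m1 - m0, None]
                    path = p0 + f * (p1 - p0)
                else:
                    path = np.tile(anchor, (m1 - m0, 1))
            tr.segments.extend(_path_to_segments(path, m0, m1, d * DAY_S,
                                                 pause_radius, collinear_tol))
        tr.segments.sort(key=lambda sgm: sgm.start)
    if any_gap and all_fallback:
        warnings.warn(
            f"participant {traces[0].participant_id}: no donor windows found "
            "for any gap; all gaps filled stationary at last known location")
    return day_traces
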