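"""Missing-data monitoring: flag runs of fully missing sensor days.

During live data collection, a phone powered off, a logged-out app, or reset
location permissions silently stop the GPS stream.  The detector replicates
the automated alerting rule used during collection: an alert fires when a
participant accumulates more than ``threshold_days`` consecutive fully
missing days (strictly greater — a 3-day run with the default threshold of 3
produces no alert; a 4-day run alerts on its fourth day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import MINUTES_PER_DAY

DEFAULT_THRESHOLD_DAYS = 3


@dataclass
class AlertRecord:
    participant_id: str
    run_start: object  # date
    run_length: int
    triggered_at: object  # date


def _runs(flags):
    """(start, length) of maximal True runs."""
    f = np.asarray(flags, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], f.view(np.int8), [0]))))
    return [(int(a), int(b - a)) for a, b in zip(edges[::2], edges[1::2])]


def detect_missing_alerts(daily_log, threshold_days=DEFAULT_THRESHOLD_DAYS,
                          day_missing_minutes=MINUTES_PER_DAY,
                          cumulative=False):
    """Alerts for missing-day runs in a per-participant daily log.

    Parameters
    ----------
    daily_log : DataFrame
        Columns ``participant_id, date`` and either ``minutes_missing`` (a
        day is missing when minutes_missing >= ``day_missing_minutes``) or a
        boolean ``missing`` column.  Dates must be contiguous per
        participant; a gap in the date index raises.
    threshold_days : int
        Alert on runs strictly longer than this.
    cumulative : bool
        If True, count cumulative (not consecutive) missing days per
        participant and alert once when the total first exceeds the
        threshold.

    Returns
    -------
    list of AlertRecord — one per maximal offending run, triggered on the
    first day the run length exceeds the threshold.
    """
    log = daily_log.copy()
    log["date"] = pd.to_datetime(log["date"]).dt.date
    if "missing" in log.columns:
        log["_miss"] = log["missing"].astype(bool)
    elif "minutes_missing" in log.columns:
        log["_miss"] = log["minutes_missing"] >= day_missing_minutes
    else:
        raise ValueError("daily_log needs a 'missing' or 'minutes_missing' column")

    alerts = []
    for pid, g in log.groupby("participant_id", sort=True):
        g = g.sort_values("date")
        dates = g["date"].to_numpy()
        deltas = np.array([(b - a).days for a, b in zip(dates[:-1], dates[1:])])
        if np.any(deltas != 1):
            raise ValueError(f"gap in the date index for participant {pid}")
        miss = g["_miss"].to_numpy()
        if cumulative:
            cum = np.cumsum(miss)
            over = np.flatnonzero(cum > threshold_days)
            if len(over):
                first_missing = int(np.flatnonzero(miss)[0])
                alerts.append(AlertRecord(str(pid), dates[first_missing],
                                          int(cum[-1]), dates[int(over[0])]))
            continue
        for start, length in _runs(miss):
            if length > threshold_days:
                alerts.append(AlertRecord(
                    str(pid), dates[start], length,
                    dates[start + threshold_days]))
    return alerts


def alerts_frame(alerts):
    """Alerts as the CSV surface."""
    return pd.DataFrame([a.__dict__ for a in alerts],
                        columns=["participant_id", "run_start", "run_length",
                                 "triggered_at"])
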