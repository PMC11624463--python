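"""Monthly summaries of daily mobility features.

Each participant's daily feature series is collapsed to a monthly mean
(mobility level) and a day-to-day individual standard deviation, the iSD
(intraindividual variability, IIV), over non-excluded, non-missing days.
Cohort-level distributions with strong skew can be log(x+c) transformed
before correlation analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_COLUMNS

DEFAULT_SKEW_THRESHOLD = 2.0
DEFAULT_LOG_C = 1.0


def summarize_participant(daily_df):
    """Monthly mean and iSD (sample SD, n-1 denominator) for one participant.

    ``daily_df`` holds that participant's daily feature rows; excluded days
    are dropped, and each feature uses its own non-missing day count.  iSD is
    NaN when fewer than 2 usable days exist.  Returns a dict, or None (with a
    warning) when no usable day remains.
    """
    use = daily_df.loc[~daily_df["excluded"].astype(bool)] \
        if "excluded" in daily_df.columns else daily_df
    if len(use) == 0 or use[FEATURE_COLUMNS].notna().sum().max() == 0:
        warnings.warn("participant has no usable days; omitted from summary")
        return None
    out = {"participant_id": use["participant_id"].iloc[0],
           "n_days_used": int(use[FEATURE_COLUMNS].notna().sum().max())}
    for col in FEATURE_COLUMNS:
        v = use[col].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        out[f"{col}_mean"] = float(v.mean()) if len(v) else np.nan
        out[f"{col}_isd"] = float(v.std(ddof=1)) if len(v) >= 2 else np.nan
    return out


def summarize_cohort(daily_df):
    """Per-participant monthly mean/iSD table for the whole cohort."""
    rows = []
    for _, g in daily_df.groupby("participant_id", sort=True):
        s = summarize_participant(g)
        if s is not None:
            rows.append(s)
    return pd.DataFrame(rows)


def log_transform(values, skew_threshold=DEFAULT_SKEW_THRESHOLD,
                  c=DEFAULT_LOG_C, name="variable"):
    """log(x+c) transform applied iff |sample skewness| exceeds the threshold.

    Returns ``(values, applied, c)``.  Raises when x+c is nonpositive for a
    to-be-transformed variable.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if len(obs) < 3 or np.std(obs) == 0:
        return v, False, c
    sk = float(sps.skew(obs, bias=False))
    if abs(sk) <= skew_threshold:
        return v, False, c
    if np.any(obs + c <= 0):
        raise ValueError(f"log transform undefined for {name!r}: x + {c} <= 0")
    out = np.where(np.isnan(v), np.nan, np.log(np.maximum(v + c, 1e-300)))
    return out, True, c


def transform_summary_table(summary_df, skew_threshold=DEFAULT_SKEW_THRESHOLD,
                            c=DEFAULT_LOG_C):
    """Apply :func:`log_transform` per numeric column across the cohort.

    Returns the transformed copy and a metadata dict
    ``column -> {"applied": bool, "c": float}`` recorded for reproducibility.
    """
    out = summary_df.copy()
    meta = {}
    for col in out.columns:
        if col in ("participant_id", "n_days_used"):
            continue
        vals, applied, used_c = log_transform(out[col].to_numpy(dtype=float),
                                              skew_threshold, c, name=col)
        out[col] = vals
        meta[col] = {"applied": bool(applied), "c": used_c}
    return out, meta


def mobility_plot_data(day_traces, cluster_radius=100.0):
    """Plot specification for a participant's month of mobility.

    Stationary periods collapse into markers whose area is proportional to
    total minutes spent at that point cluster and whose color value is the
    circular mean hour of day of the stays; flights become polyline specs.
    """
    markers = []  # greedy point clusters: [x, y, minutes, sum_sin, sum_cos]
    lines = []
    for tr in day_traces:
        if tr.excluded:
            continue
        for s in tr.segments:
            if s.kind == "pause":
                mid_h = (((s.start + s.end) / 2.0) % 86400.0) / 3600.0
                ang = 2 * np.pi * mid_h / 24.0
                minutes = s.duration / 60.0
                for m in markers:
                    if np.hypot(m[0] - s.x0, m[1] - s.y0) <= cluster_radius:
                        w = m[2] + minutes
                        m[0] = (m[0] * m[2] + s.x0 * minutes) / w
                        m[1] = (m[1] * m[2] + s.y0 * minutes) / w
                        m[2] = w
                        m[3] += minutes * np.sin(ang)
                        m[4] += minutes * np.cos(ang)
                        break
                else:
                    markers.append([s.x0, s.y0, minutes,
                                    minutes * np.sin(ang), minutes * np.cos(ang)])
            else:
                lines.append({"x": [s.x0, s.x1], "y": [s.y0, s.y1]})
    marker_specs = []
    for x, y, minutes, ss, cc in markers:
        hour = (np.rad2deg(np.arctan2(ss, cc)) % 360.0) / 15.0
        marker_specs.append({"x": x, "y": y, "minutes": minutes,
                             "area": minutes, "hour_of_day": hour})
    return {"markers": marker_specs, "lines": lines,
            "color_key": "hour_of_day (0-24 h, circular mean of stay times)"}


def render_mobility_plot(plot_data, path=None, ax=None):
    """Render a mobility plot (lines for flights, time-of-day colored
    circles for stays) with matplotlib."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for ln in plot_data["lines"]:
        ax.plot(ln["x"], ln["y"], color="0.4", lw=0.6, zorder=1)
    if plot_data["markers"]:
        xs = [m["x"] for m in plot_data["markers"]]
        ys = [m["y"] for m in plot_data["markers"]]
        area = np.array([m["area"] for m in plot_data["markers"]])
        hue = [m["hour_of_day"] for m in plot_data["markers"]]
        size = 20.0 + 400.0 * area / max(area.max(), 1.0)
        sc = ax.scatter(xs, ys, s=size, c=hue, cmap="twilight", vmin=0,
                        vmax=24, alpha=0.8, zorder=2)
        plt.colorbar(sc, ax=ax, label="hour of day")
    ax.set_aspect("equal")
    ax.set_xlabel("east (m)")
    ax.set_ylabel("north (m)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
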