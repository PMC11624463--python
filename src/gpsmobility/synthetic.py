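"""Synthetic GPS cohort generator with known ground truth.

Emulates the data-generating process the analysis assumes: each participant
lives at a home location and owns a small set of recurrent significant
locations; days consist of a home-anchored schedule (home overnight,
21:00-06:00) interrupted by outings to those locations, with outing counts
drawn from a gamma-Poisson process whose mean (mobility level) and
dispersion (day-to-day variability) differ between participants.  Streams
are sampled at a fixed period, perturbed by isotropic Gaussian GPS noise,
and thinned by realistic missingness — a mixture of short dropouts and long
"phone off" blocks — calibrated to a target missing fraction (the study
condition is ~29% of the day).

A matched validator table (cognitive, mood, function and life-space scores)
is generated as linear functions of each participant's planted mobility
level and variability plus Gaussian noise, so that the sign and approximate
size of feature-validator correlations are known and recoverable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import unproject_local
from .segmentation import DAY_S, MINUTES_PER_DAY

STUDY_EPOCH = pd.Timestamp("2023-05-01", tz="UTC")  # a Monday


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants for the synthetic cohort.

    Defaults mirror the 4-week smartphone monitoring design: 28 study days,
    ~29% of each day missing, minute-level sampling (the sensor ceiling is
    1 Hz but a 60 s duty cycle is the realistic effective rate), and a few
    kilometers of urban travel per outing.
    """

    n_participants: int = 1
    study_days: int = 28
    locations_min: int = 3
    locations_max: int = 6
    home_anchor: tuple = (39.9810, -75.1550)  # Philadelphia
    daily_outing_rate: float = 1.5
    outing_variability: float = 0.5
    gps_noise_sd: float = 3.0
    missing_fraction_target: float = 0.29
    sampling_period: float = 60.0
    speed_mps: float = 8.0  # walking/driving mix
    timezone: str = "UTC"
    seed: int = 0

    def __post_init__(self):
        if self.study_days < 2:
            raise ValueError("study_days must be >= 2")
        if not 0.0 <= self.missing_fraction_target < 1.0:
            raise ValueError("missing_fraction_target must be in [0, 1)")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.locations_min < 1 or self.locations_max < self.locations_min:
            raise ValueError("invalid locations range")
        # mean outing block = mean stay + two travel legs; must fit the
        # 08:00-20:00 active window
        mean_block = 5400.0 + 2 * 8000.0 / self.speed_mps
        if self.daily_outing_rate * mean_block > 12 * 3600.0:
            raise ValueError("outing durations cannot fit in a day at this rate")


@dataclass
class ScheduleEntry:
    """A stay at one location; travel fills the time between entries."""
    location: int  # 0 = home
    x: float
    y: float
    start: float  # seconds since study-start midnight
    end: float


@dataclass
class GroundTruth:
    """Planted quantities recoverable from the noise-free schedules."""
    home_latlon: dict = field(default_factory=dict)
    locations_xy: dict = field(default_factory=dict)  # pid -> (n_loc, 2) incl home row 0
    daily: pd.DataFrame | None = None  # per participant-day planted values
    level: dict = field(default_factory=dict)  # planted mean daily distance (m)
    iiv: dict = field(default_factory=dict)    # planted day-to-day SD of distance (m)
    validator_effects: dict = field(default_factory=dict)


#: validator -> (slope on mobility level z, slope on mobility IIV z, noise SD,
#: intercept).  Signs plant the hypothesized direction: more activity and more
#: location diversity go with better cognition/function/life space and less
#: depression.
DEFAULT_VALIDATOR_EFFECTS = {
    "language_t": (4.0, 2.5, 7.5, 50.0),
    "mmse_t": (2.5, 1.5, 7.5, 52.0),
    "gds_t": (-4.0, -2.0, 9.0, 52.0),
    "faq": (-0.8, -0.4, 1.6, 1.5),
    "lsa": (9.0, 4.0, 15.0, 78.0),
    "acpq": (0.7, 0.3, 1.5, 3.8),
    "tug_s": (-0.5, 0.0, 3.5, 11.0),
}


def null_effects(noise_scale=1.0):
    """Validator effects with all planted slopes zero (null cohort)."""
    return {k: (0.0, 0.0, v[2] * noise_scale, v[3])
            for k, v in DEFAULT_VALIDATOR_EFFECTS.items()}


def _rng(config, participant_index, role):
    return np.random.default_rng([config.seed & 0x7FFFFFFF,
                                  participant_index, role])


def _grid(v, period):
    return float(np.round(v / period) * period)


def _participant_places(config, pidx):
    """Home offset and significant-location coordinates (local m, anchor=0)."""
    rng = _rng(config, pidx, 0)
    home = rng.normal(0.0, 800.0, size=2)
    n_loc = int(rng.integers(config.locations_min, config.locations_max + 1))
    locs = [home]
    while len(locs) < n_loc + 1:
        r = rng.uniform(800.0, 8000.0)
        th = rng.uniform(0.0, 2 * np.pi)
        cand = home + r * np.array([np.cos(th), np.sin(th)])
        if all(np.hypot(*(cand - p)) >= 500.0 for p in locs):
            locs.append(cand)
    weights = rng.dirichlet(np.ones(n_loc) * 2.0)
    # mean-one lognormal multiplier: between-participant mobility level
    rate = (config.daily_outing_rate
            * float(rng.lognormal(-0.08, 0.4)) if config.daily_outing_rate > 0 else 0.0)
    disp = config.outing_variability * float(rng.uniform(0.6, 1.4))
    return np.array(locs), weights, rate, disp


def build_schedule(config: CohortConfig, participant_index: int):
    """Per-day location schedules for one participant.

    Returns ``(schedules, info)``: one ordered ScheduleEntry list per study
    day (entries clipped at local midnight; travel between consecutive
    entries runs at ``speed_mps``), and a dict of planted per-day values
    (home minutes, outing count, travel distance).  The participant is home
    for the whole 21:00-06:00 window every day.
    """
    if participant_index >= config.n_participants:
        raise ValueError("participant_index out of range")
    locs, weights, rate, disp = _participant_places(config, participant_index)
    rng = _rng(config, participant_index, 1)
    period = config.sampling_period
    home = locs[0]

    entries: list[ScheduleEntry] = []  # whole-study, home entries merged
    day_truth = []
    t_cursor = 0.0  # start of the current home stay
    for d in range(config.study_days):
        day0 = d * DAY_S
        if rate > 0:
            lam = rng.gamma(1.0 / disp ** 2, rate * disp ** 2) if disp > 0 else rate
            n_out = int(rng.poisson(lam))
        else:
            n_out = 0
        # draw the outing blocks, then place them in non-overlapping slots of
        # the 08:00-20:30 active window (random Dirichlet spacings) so the
        # realized outing count matches the planted rate
        window_start = day0 + 8 * 3600.0
        window_end = day0 + 20.5 * 3600.0
        outs = []
        for _ in range(n_out):
            dest = int(rng.choice(len(weights), p=weights)) + 1
            dxy = locs[dest]
            dist = float(np.hypot(*(dxy - home)))
            tau = _grid(max(dist / config.speed_mps, period), period)
            dur = _grid(rng.uniform(1800.0, 9000.0), period)
            outs.append((dest, dxy, dist, dur, tau))
        while outs and (sum(d + 2 * tu for *_, d, tu in outs)
                        + (len(outs) + 1) * period) > window_end - window_start:
            outs.pop()
        dist_m = 0.0
        accepted = 0
        if outs:
            free = (window_end - window_start
                    - sum(d + 2 * tu for *_, d, tu in outs))
            gaps = rng.dirichlet(np.ones(len(outs) + 1)) * free
            cursor = window_start
            for (dest, dxy, dist, dur, tau), g in zip(outs, gaps):
                depart_home = _grid(cursor + g, period)
                arrive = depart_home + tau
                leave = arrive + dur
                back_home = leave + tau
                if depart_home <= t_cursor + period or back_home > window_end:
                    cursor = max(cursor, t_cursor)
                    continue  # grid rounding squeezed this outing out (rare)
                entries.append(ScheduleEntry(0, home[0], home[1],
                                             t_cursor, depart_home))
                entries.append(ScheduleEntry(dest, dxy[0], dxy[1], arrive, leave))
                t_cursor = back_home
                cursor = back_home
                dist_m += 2.0 * dist
                accepted += 1
        day_truth.append({"participant_index": participant_index,
                          "day_index": d,
                          "n_outings": accepted,
                          "distance_m": dist_m})
    entries.append(ScheduleEntry(0, home[0], home[1], t_cursor,
                                 config.study_days * DAY_S))

    # split entries at midnights into per-day schedules + planted home minutes
    schedules = [[] for _ in range(config.study_days)]
    home_min = np.zeros(config.study_days)
    for e in entries:
        d0 = int(e.start // DAY_S)
        d1 = min(int(np.ceil(e.end / DAY_S)), config.study_days)
        for d in range(d0, d1):
            a = max(e.start, d * DAY_S)
            b = min(e.end, (d + 1) * DAY_S)
            if b <= a:
                continue
            schedules[d].append(replace(e, start=a, end=b))
            if e.location == 0:
                home_min[d] += (b - a) / 60.0
    for d, row in enumerate(day_truth):
        row["home_minutes"] = float(home_min[d])
    info = {"locations_xy": locs, "rate": rate, "dispersion": disp,
            "daily": day_truth}
    return schedules, info


def _positions_at(entries, t):
    """Vectorized piecewise position for sorted entries; travel between
    consecutive entries is linear."""
    starts = np.array([e.start for e in entries])
    ends = np.array([e.end for e in entries])
    ex = np.array([e.x for e in entries])
    ey = np.array([e.y for e in entries])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(entries) - 1)
    x = ex[idx].copy()
    y = ey[idx].copy()
    trav = (t > ends[idx]) & (idx < len(entries) - 1)
    if np.any(trav):
        i = idx[trav]
        f = (t[trav] - ends[i]) / np.maximum(starts[i + 1] - ends[i], 1e-9)
        f = np.clip(f, 0.0, 1.0)
        x[trav] = ex[i] + f * (ex[i + 1] - ex[i])
        y[trav] = ey[i] + f * (ey[i + 1] - ey[i])
    return x, y


def _missing_minute_mask(config, rng):
    """Per-minute dropout mask for the whole study: one long 'phone off'
    block plus short dropouts per day, hitting the target fraction."""
    mask = np.zeros(config.study_days * MINUTES_PER_DAY, dtype=bool)
    target = config.missing_fraction_target
    if target <= 0:
        return mask
    for d in range(config.study_days):
        f = float(np.clip(rng.normal(target, 0.02), 0.0, 0.9))
        m_target = int(round(f * MINUTES_PER_DAY))
        day = np.zeros(MINUTES_PER_DAY, dtype=bool)
        placed = 0
        if m_target >= 90:
            L = int(m_target * rng.uniform(0.4, 0.7))
            s = int(rng.integers(0, MINUTES_PER_DAY - L + 1))
            day[s:s + L] = True
            placed = L
        tries = 0
        while placed < m_target - 5 and tries < 400:
            tries += 1
            L = int(rng.integers(6, 16))
            s = int(rng.integers(0, MINUTES_PER_DAY - L + 1))
            if not day[max(0, s - 1):s + L + 1].any():
                day[s:s + L] = True
                placed += L
        mask[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY] = day
    return mask


def simulate_stream(schedules, config: CohortConfig, participant_index=0,
                    participant_id=None):
    """Raw GPS record stream for one participant's schedules.

    Records at the configured sampling period with isotropic Gaussian
    position noise and minute-level gaps removing roughly the target missing
    fraction; strictly time-ordered.
    """
    pid = participant_id or f"P{participant_index:03d}"
    entries = [e for day in schedules for e in day]
    entries.sort(key=lambda e: e.start)
    # merge back entries split at midnight so travel interpolation is clean
    merged = []
    for e in entries:
        if merged and merged[-1].location == e.location \
                and abs(merged[-1].end - e.start) < 1e-6 \
                and merged[-1].x == e.x and merged[-1].y == e.y:
            merged[-1] = replace(merged[-1], end=e.end)
        else:
            merged.append(replace(e))
    rng = _rng(config, participant_index, 2)
    n_days = int(np.ceil(merged[-1].end / DAY_S))
    t = np.arange(0.0, n_days * DAY_S, config.sampling_period)
    x, y = _positions_at(merged, t)
    if config.gps_noise_sd > 0:
        x = x + rng.normal(0.0, config.gps_noise_sd, len(t))
        y = y + rng.normal(0.0, config.gps_noise_sd, len(t))
    mask = _missing_minute_mask(config, rng)
    minute = np.minimum((t // 60).astype(int), len(mask) - 1)
    keep = ~mask[minute]
    t, x, y = t[keep], x[keep], y[keep]
    lat, lon = unproject_local(x, y, *config.home_anchor)
    ts = STUDY_EPOCH + pd.to_timedelta(t, unit="s")
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": ts,
        "latitude": lat,
        "longitude": lon,
        "altitude": 30.0 + rng.normal(0.0, 2.0, len(t)),
        "accuracy": np.abs(rng.normal(10.0, 5.0, len(t))) + 1.0,
    })


def simulate_cohort(config: CohortConfig, validator_effects=None):
    """Simulate the full cohort.

    Returns ``(streams, validators, truth)``: a concatenated record stream
    DataFrame, a per-participant validator table, and the ground truth.
    Deterministic given ``config.seed``.
    """
    if validator_effects is None:
        validator_effects = DEFAULT_VALIDATOR_EFFECTS
    truth = GroundTruth(validator_effects=dict(validator_effects))
    streams = []
    daily_rows = []
    pids = []
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        pids.append(pid)
        schedules, info = build_schedule(config, p)
        streams.append(simulate_stream(schedules, config, p, pid))
        locs = info["locations_xy"]
        lat, lon = unproject_local(locs[0, 0], locs[0, 1], *config.home_anchor)
        truth.home_latlon[pid] = (float(lat), float(lon))
        truth.locations_xy[pid] = locs
        dist = np.array([r["distance_m"] for r in info["daily"]])
        truth.level[pid] = float(dist.mean())
        truth.iiv[pid] = float(dist.std(ddof=1)) if len(dist) > 1 else 0.0
        for r in info["daily"]:
            daily_rows.append({"participant_id": pid, **r})
    truth.daily = pd.DataFrame(daily_rows)

    lv = np.array([truth.level[p] for p in pids])
    iv = np.array([truth.iiv[p] for p in pids])

    def z(v):
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    zl, zi = z(lv), z(iv)
    vrng = np.random.default_rng([config.seed & 0x7FFFFFFF, 999_983])
    table = {"participant_id": pids}
    for name, (a, b, sd, base) in validator_effects.items():
        table[name] = base + a * zl + b * zi + vrng.normal(0.0, sd, len(pids))
    table["age"] = vrng.integers(63, 86, len(pids))
    table["sex"] = vrng.choice(["F", "M"], len(pids), p=[0.68, 0.32])
    table["phone_type"] = vrng.choice(["iPhone", "Android"], len(pids),
                                      p=[0.76, 0.24])
    table["season"] = vrng.choice(["winter", "spring", "summer", "fall"],
                                  len(pids))
    validators = pd.DataFrame(table)
    return pd.concat(streams, ignore_index=True), validators, truth


def write_cohort(outdir, streams, validators, truth, config):
    """Write the stream/validator/ground-truth CSV surfaces and the config."""
    import json
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    streams.to_csv(out / "streams.csv", index=False)
    validators.to_csv(out / "validators.csv", index=False)
    truth.daily.to_csv(out / "ground_truth_daily.csv", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in config.__dict__.items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
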