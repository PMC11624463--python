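"""Shared fixtures: hand-built traces and a small simulated cohort."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from gpsmobility.geo import unproject_local
from gpsmobility.segmentation import DayTrace, MobilitySegment
from gpsmobility.synthetic import STUDY_EPOCH, CohortConfig, simulate_cohort

ANCHOR = (39.9810, -75.1550)


def make_stream(points, participant_id="T00", anchor=ANCHOR):
    """Raw record DataFrame from (t_seconds, x_m, y_m) triples."""
    t = np.array([p[0] for p in points], dtype=float)
    x = np.array([p[1] for p in points], dtype=float)
    y = np.array([p[2] for p in points], dtype=float)
    lat, lon = unproject_local(x, y, *anchor)
    return pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": STUDY_EPOCH + pd.to_timedelta(t, unit="s"),
        "latitude": lat,
        "longitude": lon,
        "altitude": 30.0,
        "accuracy": 5.0,
    })


def pause(start, end, x, y, imputed=False):
    return MobilitySegment("pause", start, end, x, y, x, y, imputed)


def flight(start, end, x0, y0, x1, y1, imputed=False):
    return MobilitySegment("flight", start, end, x0, y0, x1, y1, imputed)


def day_trace(day_index, segments, pid="T00", missing=0, excluded=False):
    return DayTrace(pid, dt.date(2023, 5, 1) + dt.timedelta(days=day_index),
                    day_index, list(segments), missing, excluded)


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, ten days, default noise/missingness conditions."""
    cfg = CohortConfig(n_participants=6, study_days=10, seed=11)
    streams, validators, truth = simulate_cohort(cfg)
    return cfg, streams, validators, truth


@pytest.fixture(scope="session")
def clean_participant():
    """One participant with zero noise and zero missingness (recovery tests)."""
    cfg = CohortConfig(n_participants=1, study_days=8, seed=5,
                       gps_noise_sd=0.0, missing_fraction_target=0.0)
    streams, validators, truth = simulate_cohort(cfg)
    return cfg, streams, truth
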