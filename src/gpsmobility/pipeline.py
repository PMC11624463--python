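"""End-to-end orchestration: raw streams -> daily features -> summaries ->
composite -> validation statistics -> monitoring alerts.

The pipeline is a thin sequencing layer over the library modules; every
intermediate surface is a DataFrame and can be written out as CSV.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import composite, features, imputation, segmentation, stats, summarize
from .monitoring import alerts_frame, detect_missing_alerts

DEFAULT_VALIDATOR_COLUMNS = ["language_t", "mmse_t", "gds_t", "faq", "lsa",
                             "acpq", "tug_s"]


@dataclass
class PipelineParams:
    tz: str = "UTC"
    anchor: tuple | None = None
    study_days: int | None = None
    pause_radius: float = segmentation.DEFAULT_PAUSE_RADIUS_M
    min_pause_duration: float = segmentation.DEFAULT_MIN_PAUSE_S
    max_fix_gap: float = segmentation.DEFAULT_MAX_FIX_GAP_S
    max_accuracy: float = segmentation.DEFAULT_MAX_ACCURACY_M
    k_max: int = 10
    merge_radius: float = features.DEFAULT_MERGE_RADIUS_M
    min_pause_minutes: float = features.DEFAULT_MIN_PAUSE_MIN
    home_radius: float = features.DEFAULT_HOME_RADIUS_M
    bin_minutes: int = features.DEFAULT_ROUTINE_BIN_MIN
    gmm_k: int = composite.DEFAULT_K
    imputations: int = 1
    seed: int = 0
    exclusions: list = field(default_factory=list)  # (pid, date, reason)


@dataclass
class PipelineResult:
    daily: pd.DataFrame
    summary: pd.DataFrame
    summary_transformed: pd.DataFrame
    transform_meta: dict
    segments: pd.DataFrame
    mds1: pd.DataFrame | None
    distance_matrix: pd.DataFrame | None
    correlations: pd.DataFrame | None
    alerts: pd.DataFrame
    day_traces: dict  # pid -> list of DayTrace


def _clone_traces(traces):
    import copy
    return [segmentation.DayTrace(tr.participant_id, tr.date, tr.day_index,
                                  [copy.copy(s) for s in tr.segments],
                                  tr.minutes_missing_preimputation,
                                  tr.excluded, tr.exclusion_reason)
            for tr in traces]


def extract_daily_features(streams, params: PipelineParams):
    """Segment, impute and featurize every participant in ``streams``.

    With ``params.imputations > 1`` the gap imputation is repeated with
    distinct seeds and the daily features averaged over repetitions.
    Returns ``(daily_df, day_traces_by_pid)`` (traces from the first
    imputation).
    """
    daily_frames = []
    traces_by_pid = {}
    for i, (pid, g) in enumerate(streams.groupby("participant_id", sort=True)):
        traces, _ = segmentation.segment_stream(
            g, anchor=params.anchor, tz=params.tz, study_days=params.study_days,
            pause_radius=params.pause_radius,
            min_pause_duration=params.min_pause_duration,
            max_fix_gap=params.max_fix_gap, max_accuracy=params.max_accuracy)
        if params.exclusions:
            rel = [r for r in params.exclusions if str(r[0]) == str(pid)]
            if rel:
                segmentation.exclude_days(traces, rel)
        reps = []
        for m in range(max(params.imputations, 1)):
            t_m = traces if m == params.imputations - 1 else _clone_traces(traces)
            imputation.impute_gaps(t_m, seed=params.seed + 7919 * i + m,
                                   pause_radius=params.pause_radius)
            reps.append(features.daily_feature_table(
                t_m, k_max=params.k_max, merge_radius=params.merge_radius,
                min_pause_minutes=params.min_pause_minutes,
                home_radius=params.home_radius, bin_minutes=params.bin_minutes,
                seed=params.seed))
        if len(reps) == 1:
            df = reps[0]
        else:
            df = reps[0].copy()
            cols = features.FEATURE_COLUMNS
            df[cols] = np.nanmean(
                np.stack([r[cols].to_numpy(dtype=float) for r in reps]), axis=0)
        traces_by_pid[str(pid)] = traces
        daily_frames.append(df)
    return pd.concat(daily_frames, ignore_index=True), traces_by_pid


def run_pipeline(streams, validators=None, params: PipelineParams | None = None,
                 validator_columns=None, correlation_method="pearson"):
    """Run the full analysis on raw record streams.

    ``validators`` (optional) is a per-participant table of baseline
    measures; when given, monthly mean and iSD of every feature are
    correlated against each validator column with Bonferroni flags at
    .05/13.
    """
    params = params or PipelineParams()
    daily, traces_by_pid = extract_daily_features(streams, params)

    summary = summarize.summarize_cohort(daily)
    summary_t, meta = summarize.transform_summary_table(summary)

    all_traces = [tr for trs in traces_by_pid.values() for tr in trs]
    seg_df = segmentation.segments_frame(all_traces)

    mds1 = dist = None
    enough_days = daily.groupby("participant_id")["distance_traveled"] \
        .count().ge(composite.MIN_DAYS_PER_COMPONENT).sum()
    if enough_days >= 2:
        mds1, _, dist = composite.cohort_mds1(daily, k=params.gmm_k,
                                              seed=params.seed)

    correlations = None
    if validators is not None:
        if validator_columns is None:
            validator_columns = [c for c in DEFAULT_VALIDATOR_COLUMNS
                                 if c in validators.columns]
        feature_cols = ([f"{c}_mean" for c in features.FEATURE_COLUMNS]
                        + [f"{c}_isd" for c in features.FEATURE_COLUMNS])
        correlations = stats.correlation_table(
            summary_t, validators, feature_cols, validator_columns,
            method=correlation_method, m_tests=stats.N_GPS_FEATURES)

    alerts = alerts_frame(detect_missing_alerts(
        daily[["participant_id", "date", "minutes_missing"]]))

    return PipelineResult(daily=daily, summary=summary,
                          summary_transformed=summary_t, transform_meta=meta,
                          segments=seg_df, mds1=mds1, distance_matrix=dist,
                          correlations=correlations, alerts=alerts,
                          day_traces=traces_by_pid)


def write_outputs(result: PipelineResult, outdir):
    """Write every CSV surface of a pipeline run."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.daily.to_csv(out / "daily_features.csv", index=False)
    result.summary.to_csv(out / "participant_summary.csv", index=False)
    result.summary_transformed.to_csv(out / "participant_summary_transformed.csv",
                                      index=False)
    result.segments.to_csv(out / "segments.csv", index=False)
    result.alerts.to_csv(out / "alerts.csv", index=False)
    if result.mds1 is not None:
        result.mds1.to_csv(out / "mds1_scores.csv", index=False)
        result.distance_matrix.to_csv(out / "distance_matrix.csv")
    if result.correlations is not None:
        result.correlations.to_csv(out / "correlations.csv", index=False)
    import json
    (out / "transforms.json").write_text(json.dumps(result.transform_meta,
                                                    indent=2))
    return out
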