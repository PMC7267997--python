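"""Synthetic dyad cohorts with known ground truth.

This module generates everything the downstream pipeline consumes, so every
stage can be tested against simulation truth without any external data:

* a covariate table for ``n_dyads`` parent-child pairs;
* per-child epoch-level accelerometer streams.  Waking minutes (7:00-22:00
  by default) follow a first-order Markov chain over sedentary / light /
  MVPA states; off-body episodes are superimposed as contiguous blocks;
  each minute emits an integer counts-per-minute value inside the emitting
  state's cutpoint band, split across four 15-s epochs;
* signal-contingent EMA schedules — four prompts per day, uniformly random
  inside the 7-10 am, 12-2 pm, 3-6 pm and 7-10 pm windows, completed with a
  per-prompt Bernoulli draw within the 60-minute expiry;
* parent yes/no reports generated as a noisy channel on the pre-period
  ground truth, with sensitivity/specificity optionally shifted on the
  log-odds scale by weekend, sex and season;
* semi-synthetic regression outcomes ``y = X @ beta + cluster effect +
  noise`` for calibration studies of the estimator itself.

Reproducibility: a single master seed; each participant and purpose gets a
deterministic substream via ``np.random.default_rng([seed, participant, tag])``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    WORN_STATES,
    ActivityTruthParams,
    CohortConfig,
    EmaScheduleParams,
    PipelineConfig,
    ReportingParams,
    season_of,
)

__all__ = [
    "EpochStream",
    "StudyData",
    "simulate_cohort",
    "simulate_activity_stream",
    "simulate_ema_schedule",
    "simulate_parent_reports",
    "simulate_study",
    "simulate_clustered_outcomes",
]

# rng substream tags
_TAG_COHORT, _TAG_ACTIVITY, _TAG_SCHEDULE, _TAG_REPORT = 0, 1, 2, 3


@dataclasses.dataclass
class EpochStream:
    """One child's accelerometer record plus simulation ground truth.

    ``epochs`` holds ``timestamp`` / ``counts`` rows on a uniform 15-s grid
    inside the waking span of each study day; ``truth`` holds the per-minute
    generating state.
    """

    participant_id: str
    epochs: pd.DataFrame
    truth: pd.DataFrame


@dataclasses.dataclass
class StudyData:
    """Complete simulated study: covariates, streams, and survey records."""

    cohort: pd.DataFrame
    streams: dict[str, EpochStream]
    surveys: pd.DataFrame


def _rng(seed: int, participant_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, participant_index, tag])


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw the participant covariate table.

    Start dates are drawn uniformly within the configured calendar year but
    consistent with each dyad's drawn season (summer starts fall in
    June-August), so weekday/weekend labels come from real dates.
    """
    rng = _rng(config.seed, 0, _TAG_COHORT)
    n = config.n_dyads
    sex = _draw_categorical(rng, config.sex_probs, n)
    race = _draw_categorical(rng, config.race_ethnicity_probs, n)
    weight = _draw_categorical(rng, config.weight_status_probs, n)
    income = _draw_categorical(rng, config.income_probs, n)
    season = _draw_categorical(rng, config.season_probs, n)
    age = rng.normal(config.age_mean, config.age_sd, size=n).round(1)
    year = config.calendar_year
    summer_lo, summer_hi = dt.date(year, 6, 1), dt.date(year, 8, 24) - dt.timedelta(days=config.study_days)
    start_dates = []
    for s in season:
        while True:
            day = dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 357)))
            mid = day + dt.timedelta(days=config.study_days // 2)
            if season_of(mid) == s:
                start_dates.append(day)
                break
    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "participant_id": [f"D{i + 1:0{width}d}" for i in range(n)],
            "sex": sex,
            "race_ethnicity": race,
            "weight_status": weight,
            "income": income,
            "season": season,
            "age_years": age,
            "start_date": start_dates,
        }
    )


def _simulate_day_states(
    rng: np.random.Generator, params: ActivityTruthParams, n_days: int, span_minutes: int
) -> np.ndarray:
    """Markov-chain worn states for all days of one participant.

    Returns an integer array (n_days, span_minutes) indexing WORN_STATES.
    """
    trans = params.transition_array()
    cum = np.cumsum(trans, axis=1)
    p0 = np.array([params.initial_probs.get(s, 0.0) for s in WORN_STATES])
    states = np.empty((n_days, span_minutes), dtype=np.int8)
    u = rng.random((n_days, span_minutes))
    states[:, 0] = np.searchsorted(np.cumsum(p0), u[:, 0], side="right")
    for t in range(1, span_minutes):
        # vectorised across days: next state via inverse-CDF on each row
        states[:, t] = (u[:, t : t + 1] > cum[states[:, t - 1]]).sum(axis=1)
    return states


def _overlay_nonwear(
    rng: np.random.Generator, params: ActivityTruthParams, n_days: int, span_minutes: int
) -> np.ndarray:
    """Boolean mask (n_days, span) of superimposed off-body minutes."""
    mask = np.zeros((n_days, span_minutes), dtype=bool)
    lo, hi = params.nonwear_duration_minutes
    for d in range(n_days):
        for _ in range(rng.poisson(params.nonwear_episodes_per_day)):
            dur = int(rng.integers(lo, hi + 1))
            dur = min(dur, span_minutes)
            start = int(rng.integers(0, span_minutes - dur + 1))
            mask[d, start : start + dur] = True
    return mask


def _emit_cpm(
    rng: np.random.Generator, params: ActivityTruthParams, state_names: np.ndarray
) -> np.ndarray:
    """Counts-per-minute for each minute given its truth state."""
    cpm = np.zeros(state_names.size, dtype=np.int64)
    emit_state = state_names.copy()
    if params.emission_noise > 0:
        worn = np.isin(state_names, WORN_STATES)
        flip = worn & (rng.random(state_names.size) < params.emission_noise)
        for i in np.flatnonzero(flip):
            others = [s for s in WORN_STATES if s != state_names[i]]
            emit_state[i] = others[int(rng.integers(0, len(others)))]
    for s in WORN_STATES:
        sel = emit_state == s
        if sel.any():
            lo, hi = params.emission_bands[s]
            cpm[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    return cpm


def simulate_activity_stream(
    participant_id: str,
    start_date: dt.date,
    study_days: int,
    params: ActivityTruthParams | None = None,
    seed: int = 0,
    participant_index: int = 0,
) -> EpochStream:
    """Simulate one child's epoch stream over the study window.

    Each study day covers the waking span (``day_start_hour`` to
    ``day_end_hour``); the per-minute truth state drives an emitted
    counts-per-minute value which is split multinomially across the
    minute's four 15-s epochs, so re-aggregation recovers it exactly.
    """
    params = params or ActivityTruthParams()
    rng = _rng(seed, participant_index, _TAG_ACTIVITY)
    span = (params.day_end_hour - params.day_start_hour) * 60
    worn_idx = _simulate_day_states(rng, params, study_days, span)
    state_names = np.array(WORN_STATES, dtype=object)[worn_idx]
    state_names[_overlay_nonwear(rng, params, study_days, span)] = "off_body"

    minutes = []
    for d in range(study_days):
        day0 = pd.Timestamp(start_date) + pd.Timedelta(days=d, hours=params.day_start_hour)
        minutes.append(day0 + pd.to_timedelta(np.arange(span), unit="min"))
    minute_index = pd.DatetimeIndex(np.concatenate([m.values for m in minutes]))
    flat_states = state_names.reshape(-1)
    cpm = _emit_cpm(rng, params, flat_states)

    epoch_counts = rng.multinomial(cpm, [0.25, 0.25, 0.25, 0.25])  # (n_min, 4)
    ts = np.repeat(minute_index.values, 4) + np.tile(
        np.arange(4) * np.timedelta64(15, "s"), minute_index.size
    )
    epochs = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": ts,
            "counts": epoch_counts.reshape(-1),
        }
    )
    truth = pd.DataFrame(
        {"participant_id": participant_id, "minute": minute_index, "state": flat_states}
    )
    return EpochStream(participant_id=participant_id, epochs=epochs, truth=truth)


def simulate_ema_schedule(
    participant_id: str,
    date: dt.date,
    params: EmaScheduleParams | None = None,
    seed: int = 0,
    participant_index: int = 0,
    day_index: int = 0,
) -> pd.DataFrame:
    """One day's four signal-contingent prompts for one parent.

    Each prompt time is uniform within its window; completion is a
    Bernoulli draw at the compliance rate, with the response delay uniform
    on [0, expiry) minutes so completion never exceeds the expiry.
    """
    params = params or EmaScheduleParams()
    rng = _rng(seed, participant_index, _TAG_SCHEDULE)
    # advance the substream deterministically to this day
    raw = rng.random((day_index + 1, len(params.windows), 3))[day_index]
    rows = []
    for w, (lo, hi) in enumerate(params.windows, start=1):
        prompt = pd.Timestamp(date) + pd.Timedelta(hours=lo) + pd.Timedelta(
            seconds=float(raw[w - 1, 0]) * (hi - lo) * 3600
        )
        completed = raw[w - 1, 1] < params.compliance
        max_delay = params.expiry_minutes
        if params.max_delay_minutes is not None:
            max_delay = min(params.max_delay_minutes, max_delay)
        completion = (
            prompt + pd.Timedelta(seconds=float(raw[w - 1, 2]) * max_delay * 60)
            if completed
            else pd.NaT
        )
        rows.append(
            {
                "participant_id": participant_id,
                "date": date,
                "window_index": w,
                "prompt_time": prompt.floor("s"),
                "completed": bool(completed),
                "completion_time": completion.floor("s") if completed else pd.NaT,
            }
        )
    return pd.DataFrame(rows)


def _shifted_prob(p: float, shift: float) -> float:
    """Apply an additive log-odds shift to a probability, handling 0/1."""
    if shift == 0 or p in (0.0, 1.0):
        if math.isinf(shift):
            return 1.0 if shift > 0 else 0.0
        return p
    logit = math.log(p / (1 - p)) + shift
    if math.isinf(logit):
        return 1.0 if logit > 0 else 0.0
    return 1.0 / (1.0 + math.exp(-logit))


def simulate_parent_reports(
    truth_pa_minutes: float,
    truth_sb_minutes: float,
    params: ReportingParams | None = None,
    modifiers: Mapping[str, bool] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[bool, bool]:
    """Draw the parent's yes/no PA and SB responses for one pre-period.

    The true binary state is 1 when the pre-period accumulated at least the
    configured threshold minutes of the behaviour.  The response equals the
    truth with probability sensitivity (truth=1) or specificity (truth=0),
    each shifted on the log-odds scale by the active modifiers.
    """
    params = params or ReportingParams()
    modifiers = modifiers or {}
    rng = rng if rng is not None else np.random.default_rng()
    shift = sum(params.modifier_effects.get(k, 0.0) for k, on in modifiers.items() if on)

    def _one(truth: bool, sens: float, spec: float) -> bool:
        acc = _shifted_prob(sens if truth else spec, shift)
        correct = rng.random() < acc
        return truth if correct else (not truth)

    pa_truth = truth_pa_minutes >= params.pa_threshold_minutes
    sb_truth = truth_sb_minutes >= params.sb_threshold_minutes
    return (
        _one(pa_truth, params.pa_sensitivity, params.pa_specificity),
        _one(sb_truth, params.sb_sensitivity, params.sb_specificity),
    )


def _truth_window_minutes(
    truth_day: pd.DataFrame, start_hour: int, end_hour: int
) -> tuple[float, float]:
    """(PA minutes, SB minutes) of ground truth inside [start, end) hours."""
    hours = truth_day["minute"].dt.hour
    sel = truth_day[(hours >= start_hour) & (hours < end_hour)]
    pa = float(sel["state"].isin(["light", "mvpa"]).sum())
    sb = float((sel["state"] == "sedentary").sum())
    return pa, sb


def simulate_study(config: PipelineConfig | None = None) -> StudyData:
    """Generate the full study: cohort, streams, and answered surveys.

    Parent responses are tied to ground truth through the same hour-window
    convention the analysis uses: each completed survey's report reflects
    the truth minutes between the previous completed survey's hour (or the
    day's first truly-worn hour) and the survey's completion hour.
    """
    config = config or PipelineConfig()
    cc = config.cohort
    cohort = simulate_cohort(cc)
    streams: dict[str, EpochStream] = {}
    all_surveys: list[pd.DataFrame] = []

    for pidx, row in cohort.iterrows():
        pid = row["participant_id"]
        stream = simulate_activity_stream(
            pid, row["start_date"], cc.study_days, config.activity, cc.seed, int(pidx)
        )
        streams[pid] = stream
        report_rng = _rng(cc.seed, int(pidx), _TAG_REPORT)
        truth = stream.truth
        truth_dates = truth["minute"].dt.date
        for d in range(cc.study_days):
            date = row["start_date"] + dt.timedelta(days=d)
            day = simulate_ema_schedule(pid, date, config.ema, cc.seed, int(pidx), d)
            truth_day = truth[truth_dates == date]
            worn = truth_day[truth_day["state"].isin(WORN_STATES)]
            first_worn_hour = int(worn["minute"].dt.hour.iloc[0]) if len(worn) else None
            modifiers = {
                "weekend": pd.Timestamp(date).dayofweek >= 5,
                "boy": row["sex"] == "boy",
                "summer": row["season"] == "summer",
            }
            prev_hour: int | None = None
            pa_col, sb_col = [], []
            for _, srow in day.iterrows():
                if not srow["completed"]:
                    pa_col.append(pd.NA)
                    sb_col.append(pd.NA)
                    continue
                end_hour = int(srow["completion_time"].hour)
                start_hour = first_worn_hour if prev_hour is None else prev_hour + 1
                if start_hour is None or start_hour >= end_hour:
                    pa_min, sb_min = 0.0, 0.0
                else:
                    pa_min, sb_min = _truth_window_minutes(truth_day, start_hour, end_hour)
                pa, sb = simulate_parent_reports(
                    pa_min, sb_min, config.reporting, modifiers, report_rng
                )
                pa_col.append(bool(pa))
                sb_col.append(bool(sb))
                prev_hour = end_hour
            day["pa_response"] = pd.array(pa_col, dtype="boolean")
            day["sb_response"] = pd.array(sb_col, dtype="boolean")
            all_surveys.append(day)

    surveys = pd.concat(all_surveys, ignore_index=True)
    return StudyData(cohort=cohort, streams=streams, surveys=surveys)


def simulate_clustered_outcomes(
    X: np.ndarray,
    beta: Sequence[float],
    clusters: Sequence,
    cluster_sd: float = 3.0,
    resid_sd: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Semi-synthetic outcomes ``y = X @ beta + b_cluster + noise``.

    Used for calibration studies of the marginal estimator: the design
    (typically produced by the structural simulation) is held fixed while
    outcomes are redrawn with known coefficients, a shared normal cluster
    effect (SD ``cluster_sd``) and independent normal noise (``resid_sd``).
    """
    rng = rng if rng is not None else np.random.default_rng()
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    codes, uniques = pd.factorize(np.asarray(clusters))
    b = rng.normal(0.0, cluster_sd, size=len(uniques))
    return X @ beta + b[codes] + rng.normal(0.0, resid_sd, size=X.shape[0])
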