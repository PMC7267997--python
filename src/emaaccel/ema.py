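"""Survey validation, pre-period window construction, accelerometer
matching, and assembly of the standardized analysis table.

Each completed survey is paired with the accelerometer record preceding it
on the same day, truncated to whole clock hours: a survey completed at any
time during the 10 am hour is matched to data through 9:59 am.  The first
completed survey of a day reaches back to the day's first worn hour; each
later survey starts one hour after the hour of the previous completed
survey, so windows within a day never share a minute.  Class minutes in
the window are standardized to minutes per worn hour, placing unequal
windows on a common 0-60 scale.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

__all__ = [
    "validate_response_days",
    "build_pre_period_window",
    "match_accelerometer",
    "standardize_outcomes",
    "assemble_analysis_table",
]

MAX_SURVEYS_PER_DAY = 4
MIN_COMPLETED_PER_VALID_DAY = 2


def validate_response_days(surveys: pd.DataFrame) -> pd.DataFrame:
    """Flag valid response days (>= 2 of the 4 daily surveys completed).

    Returns one row per participant-day with ``n_completed`` and
    ``valid_day``.  More than 4 surveys on a day raises ``ValueError``.
    """
    grouped = surveys.groupby(["participant_id", "date"], sort=True)
    n_delivered = grouped.size()
    if (n_delivered > MAX_SURVEYS_PER_DAY).any():
        bad = n_delivered[n_delivered > MAX_SURVEYS_PER_DAY].index[0]
        raise ValueError(f"more than {MAX_SURVEYS_PER_DAY} surveys on {bad}")
    n_completed = grouped["completed"].sum()
    out = pd.DataFrame(
        {
            "n_delivered": n_delivered,
            "n_completed": n_completed,
            "valid_day": n_completed >= MIN_COMPLETED_PER_VALID_DAY,
        }
    ).reset_index()
    return out


def build_pre_period_window(
    completion_time: pd.Timestamp,
    previous_completion_time: pd.Timestamp | None = None,
    first_worn_hour: int | None = None,
) -> tuple[int, int] | None:
    """Hour-resolution pre-period ``[start_hour, end_hour)`` for one survey.

    ``end_hour`` is the floor-to-hour of the completion time (data through
    hh:59 of the previous hour).  For the day's first completed survey the
    window starts at the day's first worn hour; otherwise one hour after
    the previous completed survey's hour, keeping consecutive windows
    disjoint.  Returns ``None`` when the window is empty.
    """
    end_hour = int(pd.Timestamp(completion_time).hour)
    if previous_completion_time is not None:
        start_hour = int(pd.Timestamp(previous_completion_time).hour) + 1
    elif first_worn_hour is not None:
        start_hour = int(first_worn_hour)
    else:
        return None
    if start_hour >= end_hour:
        return None
    return start_hour, end_hour


def match_accelerometer(
    minutes_day: pd.DataFrame, start_hour: int, end_hour: int
) -> dict[str, float] | None:
    """Worn and class minutes inside ``[start_hour, end_hour)`` of one day.

    Sums run over worn minutes only.  Returns ``None`` (observation
    dropped) when the window contains no worn minute.
    """
    hours = pd.to_datetime(minutes_day["minute"]).dt.hour
    sel = minutes_day[(hours >= start_hour) & (hours < end_hour)]
    worn = sel[sel["wear"]]
    if worn.empty:
        return None
    return {
        "wear_minutes": float(len(worn)),
        "st_minutes": float((worn["intensity"] == "ST").sum()),
        "lpa_minutes": float((worn["intensity"] == "LPA").sum()),
        "mvpa_minutes": float((worn["intensity"] == "MVPA").sum()),
    }


def standardize_outcomes(
    st_minutes: float, lpa_minutes: float, mvpa_minutes: float, wear_minutes: float
) -> tuple[float, float, float]:
    """Convert window class minutes to minutes per worn hour (0-60 scale)."""
    if wear_minutes <= 0:
        raise ValueError("standardization requires positive wear minutes")
    scale = 60.0 / wear_minutes
    return st_minutes * scale, lpa_minutes * scale, mvpa_minutes * scale


def _first_worn_hour(minutes_day: pd.DataFrame) -> int | None:
    worn = minutes_day[minutes_day["wear"]]
    if worn.empty:
        return None
    return int(pd.to_datetime(worn["minute"]).dt.hour.iloc[0])


def assemble_analysis_table(
    surveys: pd.DataFrame,
    minutes: pd.DataFrame,
    cohort: pd.DataFrame,
    eligible: Iterable | None = None,
) -> pd.DataFrame:
    """Build the analysis table: one row per completed survey on a valid
    response day of an eligible participant, with a nonempty worn window.

    Exposure flags come from the same survey's responses; weekend, season
    and participant covariates are joined on.  A participant present in the
    surveys but absent from the covariate table raises ``ValueError``.
    """
    if surveys.empty:
        return pd.DataFrame()
    eligible_set = set(eligible) if eligible is not None else set(surveys["participant_id"])
    missing = set(surveys["participant_id"]) - set(cohort["participant_id"])
    if missing & eligible_set:
        raise ValueError(f"covariates missing for participants: {sorted(missing & eligible_set)}")
    day_flags = validate_response_days(surveys)
    valid_days = set(
        map(tuple, day_flags.loc[day_flags["valid_day"], ["participant_id", "date"]].to_numpy())
    )
    covars = cohort.set_index("participant_id")
    minutes = minutes.copy()
    minutes["_date"] = pd.to_datetime(minutes["minute"]).dt.date
    minute_groups = dict(iter(minutes.groupby(["participant_id", "_date"], sort=False)))

    rows = []
    surveys = surveys.sort_values(["participant_id", "date", "window_index"])
    for (pid, date), day in surveys.groupby(["participant_id", "date"], sort=True):
        if pid not in eligible_set or (pid, date) not in valid_days:
            continue
        minutes_day = minute_groups.get((pid, date))
        if minutes_day is None:
            continue
        first_worn = _first_worn_hour(minutes_day)
        prev_completion = None
        for _, srow in day.iterrows():
            if not srow["completed"]:
                continue
            window = build_pre_period_window(
                srow["completion_time"], prev_completion, first_worn
            )
            # the previous *completed* survey defines the next start,
            # whether or not this one yields an observation
            this_completion = srow["completion_time"]
            if window is not None:
                matched = match_accelerometer(minutes_day, *window)
                if matched is not None:
                    st, lpa, mvpa = standardize_outcomes(
                        matched["st_minutes"],
                        matched["lpa_minutes"],
                        matched["mvpa_minutes"],
                        matched["wear_minutes"],
                    )
                    cov = covars.loc[pid]
                    rows.append(
                        {
                            "participant_id": pid,
                            "date": date,
                            "window_index": int(srow["window_index"]),
                            "completion_time": srow["completion_time"],
                            "window_start_hour": window[0],
                            "window_end_hour": window[1],
                            "weekend": pd.Timestamp(date).dayofweek >= 5,
                            "pa_reported": bool(srow["pa_response"]),
                            "sb_reported": bool(srow["sb_response"]),
                            "wear_minutes": matched["wear_minutes"],
                            "st_min_per_hr": st,
                            "lpa_min_per_hr": lpa,
                            "mvpa_min_per_hr": mvpa,
                            "sex": cov["sex"],
                            "race_ethnicity": cov["race_ethnicity"],
                            "weight_status": cov["weight_status"],
                            "income": cov["income"],
                            "season": cov["season"],
                            "age_years": float(cov["age_years"]),
                        }
                    )
            prev_completion = this_completion
    return pd.DataFrame(rows)
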