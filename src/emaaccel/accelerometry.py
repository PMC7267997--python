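"""Epoch-to-minute processing, cutpoint classification, nonwear detection,
day summaries, and wear-time validity filtering.

The processing chain mirrors standard ActiGraph practice for child studies:
15-s epoch counts are reintegrated to clock minutes, minutes are classified
with the Evenson child cutpoints (ST <= 100 cpm, LPA 101-2295 cpm,
MVPA >= 2296 cpm), runs of more than 60 consecutive zero-count minutes are
flagged nonwear and removed, and participants are retained only if they
supply at least 4 valid days (3 weekdays + 1 weekend day) with at least
4 worn hours each.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import CutpointSet, ValidityCriteria

__all__ = [
    "EPOCH_SECONDS",
    "aggregate_epochs_to_minutes",
    "classify_intensity",
    "detect_nonwear",
    "summarize_days",
    "filter_valid_participants",
    "process_stream",
    "read_actigraph_csv",
    "write_actigraph_csv",
]

EPOCH_SECONDS = 15
CLASS_NAMES = ("ST", "LPA", "MVPA")


def aggregate_epochs_to_minutes(stream: pd.DataFrame) -> pd.DataFrame:
    """Reintegrate 15-s epoch counts to clock-minute counts.

    Parameters
    ----------
    stream
        Columns ``timestamp`` (datetime64, strictly increasing on a uniform
        15-s grid) and ``counts`` (nonnegative int).  A ``participant_id``
        column, if present, is carried through.

    Returns
    -------
    DataFrame with columns ``minute`` (datetime64 floored to the minute) and
    ``counts`` (sum of the minute's four epochs).  Minutes with fewer than
    four epochs at the stream edges are dropped; a missing or duplicated
    epoch in the interior raises ``ValueError``.
    """
    if stream.empty:
        return pd.DataFrame({"minute": pd.Series(dtype="datetime64[ns]"), "counts": pd.Series(dtype=int)})
    ts = pd.to_datetime(stream["timestamp"])
    counts = np.asarray(stream["counts"])
    if (counts < 0).any():
        raise ValueError("negative epoch counts")
    diffs = ts.diff().dropna().dt.total_seconds()
    if (diffs <= 0).any():
        raise ValueError("timestamps are not strictly increasing")
    if not ts.dt.second.isin(range(0, 60, EPOCH_SECONDS)).all():
        raise ValueError("timestamps are not aligned to the 15-s grid")
    minute = ts.dt.floor("min")
    grouped = pd.DataFrame({"minute": minute, "counts": counts}).groupby("minute", sort=True)
    n_epochs = grouped["counts"].size()
    full = n_epochs == 60 // EPOCH_SECONDS
    # a partial minute is legal only at the edges of its calendar day; one in
    # the interior means epochs were lost or duplicated upstream
    day = n_epochs.index.normalize()
    for _, sub in full.groupby(day):
        if (~sub.iloc[1:-1]).any():
            raise ValueError("duplicated or missing epochs in an interior minute")
    sums = grouped["counts"].sum()[full]
    out = sums.rename("counts").reset_index()
    for col in ("participant_id",):
        if col in stream.columns:
            out.insert(0, col, stream[col].iloc[0])
    return out


def classify_intensity(cpm: int | np.ndarray | pd.Series, cutpoints: CutpointSet | None = None) -> np.ndarray | str:
    """Assign ST / LPA / MVPA to counts-per-minute values.

    Boundaries are inclusive as published: ST iff cpm <= ``st_max`` (100),
    LPA iff cpm <= ``lpa_max`` (2295), MVPA above.  Negative input raises.
    """
    cp = cutpoints or CutpointSet()
    arr = np.asarray(cpm)
    if (arr < 0).any():
        raise ValueError("counts per minute must be nonnegative")
    cls = np.where(arr <= cp.st_max, "ST", np.where(arr <= cp.lpa_max, "LPA", "MVPA"))
    if np.isscalar(cpm) or arr.ndim == 0:
        return str(cls)
    return cls


def _flag_runs(zero: np.ndarray, max_run: int) -> np.ndarray:
    """True where a maximal run of zeros is strictly longer than ``max_run``."""
    n = zero.size
    nonwear = np.zeros(n, dtype=bool)
    if n == 0:
        return nonwear
    change = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        if zero[s] and e - s > max_run:
            nonwear[s:e] = True
    return nonwear


def detect_nonwear(minutes: pd.DataFrame, criteria: ValidityCriteria | None = None) -> pd.DataFrame:
    """Add a ``wear`` flag: False inside any run of zero-count minutes
    strictly longer than ``criteria.nonwear_run_minutes`` (default 60).

    Runs are evaluated within each participant-day; a run spanning midnight
    is split at the day boundary before the length test, because days are
    the analysis unit.  A gap in the minute grid also terminates a run.
    """
    crit = criteria or ValidityCriteria()
    out = minutes.copy()
    out["wear"] = True
    if out.empty:
        return out
    keys = ["participant_id"] if "participant_id" in out.columns else []
    day = pd.to_datetime(out["minute"]).dt.normalize()
    for _, idx in out.groupby([*keys, day]).groups.items():
        sub = out.loc[idx]
        mins = pd.to_datetime(sub["minute"])
        zero = (sub["counts"].to_numpy() == 0)
        # a discontinuity in the grid breaks the run
        breaks = np.flatnonzero(mins.diff().dt.total_seconds().to_numpy()[1:] != 60) + 1
        flags = np.zeros(zero.size, dtype=bool)
        start = 0
        for stop in [*breaks, zero.size]:
            flags[start:stop] = _flag_runs(zero[start:stop], crit.nonwear_run_minutes)
            start = stop
        out.loc[idx, "wear"] = ~flags
    return out


def _classify_column(minutes: pd.DataFrame, cutpoints: CutpointSet | None) -> pd.DataFrame:
    out = minutes.copy()
    cls = classify_intensity(out["counts"].to_numpy(), cutpoints)
    out["intensity"] = np.where(out["wear"], cls, None)
    return out


def process_stream(
    stream: pd.DataFrame,
    cutpoints: CutpointSet | None = None,
    criteria: ValidityCriteria | None = None,
) -> pd.DataFrame:
    """Epoch stream -> classified minute series (counts, wear, intensity)."""
    minutes = aggregate_epochs_to_minutes(stream)
    minutes = detect_nonwear(minutes, criteria)
    return _classify_column(minutes, cutpoints)


def summarize_days(minutes: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day wear hours and ST/LPA/MVPA minutes.

    Class minutes partition worn minutes exactly; nonwear minutes contribute
    nothing.
    """
    if minutes.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", "wear_hours", "st_min", "lpa_min", "mvpa_min", "weekend"]
        )
    df = minutes.copy()
    df["date"] = pd.to_datetime(df["minute"]).dt.date
    rows = []
    for (pid, date), sub in df.groupby(["participant_id", "date"], sort=True):
        worn = sub[sub["wear"]]
        rows.append(
            {
                "participant_id": pid,
                "date": date,
                "wear_hours": len(worn) / 60.0,
                "st_min": int((worn["intensity"] == "ST").sum()),
                "lpa_min": int((worn["intensity"] == "LPA").sum()),
                "mvpa_min": int((worn["intensity"] == "MVPA").sum()),
                "weekend": pd.Timestamp(date).dayofweek >= 5,
            }
        )
    return pd.DataFrame(rows)


def filter_valid_participants(
    day_summaries: pd.DataFrame, criteria: ValidityCriteria | None = None
) -> tuple[set, pd.DataFrame]:
    """Apply the wear-time validity rules.

    A day is valid iff ``wear_hours >= min_hours_per_day``; a participant is
    eligible iff their valid days number at least ``min_days`` and include
    at least ``min_weekdays`` weekdays and ``min_weekend_days`` weekend
    days (Saturday/Sunday by calendar date).

    Returns the eligible participant set and the day table with a
    ``valid_day`` column added.
    """
    crit = criteria or ValidityCriteria()
    days = day_summaries.copy()
    days["valid_day"] = days["wear_hours"] >= crit.min_hours_per_day
    eligible: set = set()
    for pid, sub in days.groupby("participant_id"):
        valid = sub[sub["valid_day"]]
        n_weekend = int(valid["weekend"].sum())
        n_weekday = len(valid) - n_weekend
        if (
            len(valid) >= crit.min_days
            and n_weekday >= crit.min_weekdays
            and n_weekend >= crit.min_weekend_days
        ):
            eligible.add(pid)
    return eligible, days


# ---------------------------------------------------------------------------
# ActiGraph-style CSV dialect

_HEADER_SENTINEL = "------------"


def write_actigraph_csv(stream: pd.DataFrame, path: str | Path, participant_id: str | None = None) -> None:
    """Write an epoch stream in an ActiGraph-export-like CSV layout:
    a short banner header, then ``timestamp,counts`` rows at 15-s resolution.
    """
    pid = participant_id or (stream["participant_id"].iloc[0] if "participant_id" in stream.columns else "")
    ts = pd.to_datetime(stream["timestamp"])
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_SENTINEL} Data File Created By emaaccel {_HEADER_SENTINEL}\n")
        fh.write(f"Serial Number: {pid}\n")
        fh.write(f"Epoch Period (hh:mm:ss) 00:00:{EPOCH_SECONDS:02d}\n")
        fh.write(f"Start Time {ts.iloc[0]:%H:%M:%S}\n")
        fh.write(f"Start Date {ts.iloc[0]:%Y-%m-%d}\n")
        fh.write(f"{_HEADER_SENTINEL}\n")
        fh.write("timestamp,counts\n")
        for t, c in zip(ts, stream["counts"]):
            fh.write(f"{t:%Y-%m-%d %H:%M:%S},{int(c)}\n")


def read_actigraph_csv(path: str | Path) -> pd.DataFrame:
    """Read the dialect written by :func:`write_actigraph_csv`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    pid = ""
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("Serial Number:"):
            pid = line.split(":", 1)[1].strip()
        if line.startswith("timestamp,"):
            data_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[data_start:])), parse_dates=["timestamp"])
    df["counts"] = df["counts"].astype(int)
    if pid:
        df.insert(0, "participant_id", pid)
    return df
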