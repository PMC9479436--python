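"""Epoch-stream processing: from wrist-accelerometer epoch summaries to
daily 4-part compositions.

The rules implemented here are the standard GGIR-style wrist pipeline:

* non-wear — 15-min blocks are flagged when, over the 60-min window
  centred on the block, the per-axis SD is below 13 mg for at least two
  of three axes, or the per-axis value range is below 50 mg for at
  least two of three axes;
* sleep — within the diary-reported bed-to-wake window, maximal spans of
  at least 5 min during which the arm angle stays within a 5-degree
  band; sleep is never detected outside the logged window;
* intensity — waking worn epochs are sedentary below 30 mg ENMO, light
  from 30 up to (not including) 100.6 mg, and MVPA at 100.6 mg or more;
* day definition — each measurement day runs from one diary bedtime to
  the next; a day is valid with at least 600 min (10 h) of waking wear,
  and participants keep both waves only with at least four valid days
  in each.

Epoch records carry their 60-min window statistics (axis SD/range)
directly; recomputation from raw 80 Hz signal is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DailyLog

__all__ = [
    "DayComposition",
    "detect_nonwear",
    "detect_sleep",
    "sleep_mask_from_intervals",
    "classify_intensity",
    "segment_days",
    "compute_day_composition",
    "process_stream",
    "filter_participants",
]

SED_CUT_MG = 30.0
MVPA_CUT_MG = 100.6
NONWEAR_SD_MG = 13.0
NONWEAR_RANGE_MG = 50.0
NONWEAR_BLOCK_MIN = 15
SLEEP_ANGLE_TOL_DEG = 5.0
SLEEP_MIN_SPAN_MIN = 5
VALID_WAKING_WEAR_MIN = 600.0
MIN_VALID_DAYS = 4


@dataclass(frozen=True)
class DayComposition:
    """Minutes per behavior for one measurement day."""

    participant_id: str
    wave: str
    day_index: int
    sleep_min: float
    sed_min: float
    lpa_min: float
    mvpa_min: float
    waking_wear_min: float
    day_length_min: float
    valid: bool


def _epoch_seconds(epochs: pd.DataFrame) -> float:
    ts = epochs["timestamp"]
    if len(ts) < 2:
        raise ValueError("need at least two epochs")
    deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
    step = deltas[0]
    bad = np.flatnonzero(deltas != step)
    if len(bad):
        at = ts.iloc[bad[0] + 1]
        raise ValueError(f"epoch timeline has a gap or irregular spacing at {at}")
    return float(step)


def detect_nonwear(
    epochs: pd.DataFrame,
    block_min: int = NONWEAR_BLOCK_MIN,
    sd_threshold: float = NONWEAR_SD_MG,
    range_threshold: float = NONWEAR_RANGE_MG,
) -> np.ndarray:
    """Per-epoch wear mask (True = worn), resolved at 15-min blocks.

    Each block is judged from the 60-min window statistics carried on
    the epoch nearest its centre: non-wear when >= 2 of 3 axis SDs are
    below ``sd_threshold`` or >= 2 of 3 axis ranges are below
    ``range_threshold``.
    """
    step = _epoch_seconds(epochs)
    n = len(epochs)
    per_block = int(round(block_min * 60.0 / step))
    sd = epochs[["sd_x_mg", "sd_y_mg", "sd_z_mg"]].to_numpy()
    rg = epochs[["range_x_mg", "range_y_mg", "range_z_mg"]].to_numpy()
    wear = np.ones(n, dtype=bool)
    for start in range(0, n, per_block):
        stop = min(start + per_block, n)
        mid = (start + stop) // 2
        low_sd = (sd[mid] < sd_threshold).sum() >= 2
        low_rg = (rg[mid] < range_threshold).sum() >= 2
        if low_sd or low_rg:
            wear[start:stop] = False
    return wear


def detect_sleep(
    epochs: pd.DataFrame,
    log: DailyLog | None,
    angle_tol_deg: float = SLEEP_ANGLE_TOL_DEG,
    min_span_min: float = SLEEP_MIN_SPAN_MIN,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Sleep intervals within the logged bed-to-wake window.

    Scans the window greedily for maximal spans over which the arm
    angle stays within a band of ``angle_tol_deg``; spans of at least
    ``min_span_min`` minutes count as sleep.  A posture change starts a
    new span, so an uninterrupted night made of several calm postures
    is returned as adjoining intervals.  With no log for the night, no
    sleep is detected and a warning reports it.
    """
    if log is None:
        warnings.warn("no daily log for this night: contributing zero sleep", stacklevel=2)
        return []
    step = _epoch_seconds(epochs)
    ts = epochs["timestamp"]
    in_window = (ts >= log.bedtime) & (ts < log.waketime)
    idx = np.flatnonzero(in_window.to_numpy())
    if len(idx) == 0:
        return []
    angle = epochs["arm_angle_deg"].to_numpy()[idx]
    min_epochs = int(round(min_span_min * 60.0 / step))
    intervals: list[tuple[int, int]] = []

    run_start = 0
    lo = hi = angle[0]
    for i in range(1, len(angle) + 1):
        if i < len(angle):
            new_lo, new_hi = min(lo, angle[i]), max(hi, angle[i])
        if i == len(angle) or new_hi - new_lo > angle_tol_deg:
            if i - run_start >= min_epochs:
                intervals.append((run_start, i))
            if i < len(angle):
                run_start = i
                lo = hi = angle[i]
        else:
            lo, hi = new_lo, new_hi

    out: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    tss = ts.to_numpy()
    for a, b in intervals:
        start = tss[idx[a]]
        end = tss[idx[b - 1]] + pd.Timedelta(seconds=step)
        if out and out[-1][1] == start:  # adjoining calm postures merge
            out[-1] = (out[-1][0], end)
        else:
            out.append((pd.Timestamp(start), pd.Timestamp(end)))
    return out


def sleep_mask_from_intervals(
    epochs: pd.DataFrame, intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
) -> np.ndarray:
    """Boolean per-epoch mask from a list of (start, end) sleep intervals."""
    ts = epochs["timestamp"].to_numpy()
    mask = np.zeros(len(ts), dtype=bool)
    for start, end in intervals:
        mask |= (ts >= np.datetime64(start)) & (ts < np.datetime64(end))
    return mask


def classify_intensity(enmo_mg) -> np.ndarray:
    """Intensity class per epoch from ENMO: 'sed' | 'lpa' | 'mvpa'.

    Sedentary below 30 mg; light from 30 mg up to but excluding
    100.6 mg; MVPA at 100.6 mg and above.
    """
    enmo = np.asarray(enmo_mg, dtype=float)
    if np.any(enmo < 0):
        raise ValueError("ENMO cannot be negative")
    return np.select([enmo < SED_CUT_MG, enmo < MVPA_CUT_MG], ["sed", "lpa"], "mvpa")


def segment_days(logs: list[DailyLog]) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Measurement-day windows: one per consecutive pair of bedtimes."""
    if len(logs) < 2:
        raise ValueError("need at least two logged bedtimes to define a day")
    bedtimes = [log.bedtime for log in logs]
    for a, b in zip(bedtimes, bedtimes[1:]):
        if b <= a:
            raise ValueError(f"bedtimes out of order: {b} follows {a}")
    return list(zip(bedtimes, bedtimes[1:]))


def compute_day_composition(
    epochs: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    wear: np.ndarray,
    sleep_intervals: list[tuple[pd.Timestamp, pd.Timestamp]],
    participant_id: str = "",
    wave: str = "",
    day_index: int = 0,
) -> DayComposition:
    """Tally one day window into sleep/SED/LPA/MVPA minutes.

    Non-wear epochs are excluded from all four behaviors; worn epochs
    inside a sleep interval count as sleep; remaining worn epochs are
    classified by ENMO.  Waking wear determines validity (>= 600 min).
    """
    step = _epoch_seconds(epochs)
    ts = epochs["timestamp"].to_numpy()
    start, end = window
    in_day = (ts >= np.datetime64(start)) & (ts < np.datetime64(end))
    if not in_day.any():
        raise ValueError(f"day window {start} .. {end} contains no epochs")
    sleep = sleep_mask_from_intervals(epochs, sleep_intervals)
    labels = classify_intensity(epochs["enmo_mg"])
    per_min = step / 60.0

    worn = in_day & wear
    asleep = worn & sleep
    awake = worn & ~sleep
    minutes = {
        "sleep": asleep.sum() * per_min,
        "sed": ((awake) & (labels == "sed")).sum() * per_min,
        "lpa": ((awake) & (labels == "lpa")).sum() * per_min,
        "mvpa": ((awake) & (labels == "mvpa")).sum() * per_min,
    }
    waking_wear = awake.sum() * per_min
    day_length = in_day.sum() * per_min
    return DayComposition(
        participant_id=participant_id,
        wave=wave,
        day_index=day_index,
        sleep_min=minutes["sleep"],
        sed_min=minutes["sed"],
        lpa_min=minutes["lpa"],
        mvpa_min=minutes["mvpa"],
        waking_wear_min=waking_wear,
        day_length_min=day_length,
        valid=waking_wear >= VALID_WAKING_WEAR_MIN,
    )


def process_stream(
    epochs: pd.DataFrame,
    logs: list[DailyLog],
    participant_id: str = "",
    wave: str = "",
) -> pd.DataFrame:
    """Run the full detector chain over a multi-day stream.

    Returns one row per measurement day with the DayComposition fields.
    """
    wear = detect_nonwear(epochs)
    windows = segment_days(logs)
    rows = []
    for day_index, (window, log) in enumerate(zip(windows, logs)):
        sleep_intervals = detect_sleep(epochs, log)
        day = compute_day_composition(
            epochs, window, wear, sleep_intervals, participant_id, wave, day_index
        )
        rows.append(day.__dict__)
    return pd.DataFrame(rows)


def filter_participants(
    day_df: pd.DataFrame, min_valid_days: int = MIN_VALID_DAYS
) -> tuple[list[str], pd.DataFrame]:
    """Apply the >=4-valid-days-per-wave inclusion rule.

    ``day_df`` needs columns ``participant, wave, valid``.  Returns the
    retained participant ids and a DataFrame of exclusions with reasons
    (``missing_wave`` or ``too_few_valid_days``).
    """
    included: list[str] = []
    reasons: list[dict] = []
    for pid, grp in day_df.groupby("participant", sort=True):
        waves = set(grp["wave"])
        if not {"pre", "post"} <= waves:
            reasons.append({"participant": pid, "reason": "missing_wave"})
            continue
        ok = all(
            int(grp.loc[grp["wave"] == w, "valid"].sum()) >= min_valid_days
            for w in ("pre", "post")
        )
        if ok:
            included.append(str(pid))
        else:
            reasons.append({"participant": pid, "reason": "too_few_valid_days"})
    return included, pd.DataFrame(reasons, columns=["participant", "reason"])
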