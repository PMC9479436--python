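"""Plain-text serialisation of the pipeline's tabular artifacts.

Schemas (CSV, one header row):

* epoch stream — ``timestamp, enmo_mg, arm_angle_deg, sd_x_mg, sd_y_mg,
  sd_z_mg, range_x_mg, range_y_mg, range_z_mg`` (optionally
  ``true_label`` when simulated);
* daily logs — ``participant, wave, date, bedtime, waketime``;
* day compositions — ``participant, gender, occupation, wave, day,
  sleep_min, sed_min, lpa_min, mvpa_min, waking_wear_min,
  day_length_min, valid``.

Ternary regions are exported as JSON; pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .simulate import DailyLog
from .ternary import TernaryRegion

__all__ = [
    "write_day_compositions",
    "read_day_compositions",
    "write_epoch_stream",
    "read_epoch_stream",
    "write_daily_logs",
    "read_daily_logs",
    "write_regions",
    "read_yaml",
    "write_yaml",
]


def write_day_compositions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_day_compositions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool)
    return df


def write_epoch_stream(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_epoch_stream(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_daily_logs(logs: dict[tuple[str, str], list[DailyLog]], path) -> None:
    rows = [
        {
            "participant": pid,
            "wave": wave,
            "date": log.date.date().isoformat(),
            "bedtime": log.bedtime.isoformat(),
            "waketime": log.waketime.isoformat(),
        }
        for (pid, wave), entries in logs.items()
        for log in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_daily_logs(path) -> dict[tuple[str, str], list[DailyLog]]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str], list[DailyLog]] = {}
    for _, row in df.iterrows():
        log = DailyLog(
            date=pd.Timestamp(row["date"]),
            bedtime=pd.Timestamp(row["bedtime"]),
            waketime=pd.Timestamp(row["waketime"]),
        )
        out.setdefault((str(row["participant"]), str(row["wave"])), []).append(log)
    return out


def write_regions(regions: dict[str, TernaryRegion], path) -> None:
    payload = {name: region.to_dict() for name, region in regions.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
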