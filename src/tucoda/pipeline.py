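"""End-to-end orchestration: simulate, process, screen, describe, model.

``run_pipeline`` wires the stages together with a single seed, writes
every artifact as plain text (CSV/JSON) and keeps an exclusion ledger:
every simulated participant is either included or counted under exactly
one exclusion rule (invalid days via the <4-valid-days rule, missing
wave, outlier screen).

``describe_cohort`` produces the descriptive group summary: per
gender-by-occupation group (plus the marginal groups) and wave, the
compositional mean rescaled to 1440 min, and a change block of
after-minus-before differences rounded to whole minutes.  Changes are
computed from the unrounded means and then rounded (so a printed change
cell can differ by one minute from subtracting the two rounded means;
the rounded-then-subtract convention is available too).
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .composition import MINUTES_PER_DAY, compositional_mean, replace_zeros, subcompositions
from .model import build_model_frame, run_all_models
from .processing import filter_participants, process_stream
from .screening import flag_outliers
from .simulate import CohortSimConfig, make_daily_log, simulate_cohort, simulate_epoch_stream
from .ternary import confidence_region

__all__ = ["PipelineConfig", "describe_cohort", "run_pipeline"]

logger = logging.getLogger("tucoda")

_COMP_COLS = ["sleep_min", "sed_min", "lpa_min", "mvpa_min"]
_PART_LABELS = ("Sleep", "SED", "LPA", "MVPA")

#: descriptive groups in the conventional column order
GROUPS: tuple[tuple[str, str | None, str | None], ...] = (
    ("All", None, None),
    ("Women", "woman", None),
    ("Women non-manual", "woman", "non-manual"),
    ("Women manual", "woman", "manual"),
    ("Men", "man", None),
    ("Men non-manual", "man", "non-manual"),
    ("Men manual", "man", "manual"),
)


def describe_cohort(
    day_df: pd.DataFrame,
    change_convention: str = "unrounded",
) -> pd.DataFrame:
    """Group-by-wave compositional means (min/1440) with a change block.

    Rows are indexed by (block, part) with blocks ``before``, ``after``
    and ``change``; columns follow the conventional group order.  Empty
    groups are omitted with a warning in the log.
    """
    if change_convention not in ("unrounded", "rounded"):
        raise ValueError("change_convention must be 'unrounded' or 'rounded'")
    cols = {}
    for label, gender, occupation in GROUPS:
        sub = day_df
        if gender is not None:
            sub = sub[sub["gender"] == gender]
        if occupation is not None:
            sub = sub[sub["occupation"] == occupation]
        if len(sub) == 0:
            logger.warning("describe: empty group %r omitted", label)
            continue
        means = {}
        for wave in ("pre", "post"):
            w = sub[sub["wave"] == wave]
            if len(w) == 0:
                logger.warning("describe: group %r has no %s wave; omitted", label, wave)
                break
            means[wave] = compositional_mean(w[_COMP_COLS].to_numpy(), kappa=MINUTES_PER_DAY)
        if len(means) < 2:
            continue
        if change_convention == "unrounded":
            change = np.round(means["post"] - means["pre"]).astype(int)
        else:
            change = np.round(means["post"]) - np.round(means["pre"])
        col = {}
        for i, part in enumerate(_PART_LABELS):
            col[("before", part)] = means["pre"][i]
            col[("after", part)] = means["post"][i]
            col[("change", part)] = change[i]
        cols[label] = col
    out = pd.DataFrame(cols)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["block", "part"])
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for a full run; everything stochastic flows from ``seed``."""

    seed: int = 0
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    detection_limit_min: float = 1.0
    outlier_screen: bool = True
    outlier_threshold: float = 3.5
    describe: bool = True
    change_convention: str = "unrounded"
    regions: bool = True
    n_boot: int = 500
    model: bool = True
    model_levels: tuple[int, ...] = (1, 2, 3)
    aggregation: str = "day_level"
    epoch_demo: bool = False
    epoch_demo_days: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = tio.read_yaml(path)
        cohort_raw = raw.pop("cohort", {})
        cohort = CohortSimConfig(**cohort_raw) if cohort_raw else CohortSimConfig()
        cfg = cls(cohort=cohort, **raw)
        # the cohort inherits the pipeline seed unless it sets its own
        if "seed" not in cohort_raw:
            cfg = replace(cfg, cohort=replace(cfg.cohort, seed=cfg.seed))
        return cfg


def _screen_outliers(day_df: pd.DataFrame, included: list[str], threshold: float):
    """Per-participant change screen on wave-level compositional means."""
    if not included:
        return pd.DataFrame(columns=["participant", "max_abs_z", "worst_score", "flagged"])
    pre, post, pids = [], [], []
    for pid in included:
        grp = day_df[(day_df["participant"] == pid) & day_df["valid"]]
        pre.append(compositional_mean(grp.loc[grp["wave"] == "pre", _COMP_COLS].to_numpy()))
        post.append(compositional_mean(grp.loc[grp["wave"] == "post", _COMP_COLS].to_numpy()))
        pids.append(pid)
    flags = flag_outliers(np.asarray(pre), np.asarray(post), threshold=threshold)
    flags.insert(0, "participant", pids)
    return flags


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate, process, screen, describe and model; write artifacts.

    Returns the run log as a dict (also written to ``run_log.json``):
    stage timings, participant accounting and artifact paths.  A stage
    failure raises with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**16]))

    def stage(name):
        logger.info("stage %s", name)
        return _Stage(name, log)

    with stage("simulate"):
        cohort_cfg = replace(config.cohort, seed=config.cohort.seed or config.seed)
        day_df = simulate_cohort(cohort_cfg)
        n_simulated = day_df["participant"].nunique()
        tio.write_day_compositions(day_df, outdir / "day_compositions.csv")
        log["artifacts"]["day_compositions"] = "day_compositions.csv"

    if config.epoch_demo:
        with stage("process_epochs"):
            demo = _epoch_demo(day_df, config, rng)
            demo.to_csv(outdir / "epoch_demo_day_compositions.csv", index=False)
            log["artifacts"]["epoch_demo"] = "epoch_demo_day_compositions.csv"

    with stage("filter"):
        included, exclusions = filter_participants(day_df)
        log["n_simulated"] = int(n_simulated)
        log["n_excluded_too_few_valid_days"] = int(
            (exclusions["reason"] == "too_few_valid_days").sum()
        )
        log["n_excluded_missing_wave"] = int((exclusions["reason"] == "missing_wave").sum())

    with stage("replace_zeros"):
        valid = day_df[day_df["valid"] & day_df["participant"].isin(included)].copy()
        comps = replace_zeros(
            valid[_COMP_COLS].to_numpy(), detection_limit=config.detection_limit_min
        )
        valid[_COMP_COLS] = comps
        log["n_zero_mvpa_imputed"] = int((day_df.loc[valid.index, "mvpa_min"] == 0).sum())

    n_outliers = 0
    if config.outlier_screen:
        with stage("outlier_screen"):
            flags = _screen_outliers(valid, included, config.outlier_threshold)
            flags.to_csv(outdir / "outlier_flags.csv", index=False)
            log["artifacts"]["outlier_flags"] = "outlier_flags.csv"
            flagged = set(flags.loc[flags["flagged"], "participant"])
            n_outliers = len(flagged)
            valid = valid[~valid["participant"].isin(flagged)]
            included = [p for p in included if p not in flagged]
    log["n_excluded_outliers"] = int(n_outliers)
    log["n_included"] = len(included)

    if not included:
        logger.warning("no participants pass the inclusion rules; downstream stages skipped")
        log["artifacts"]["note"] = "empty analytical sample"
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
        return log

    if config.describe:
        with stage("describe"):
            table = describe_cohort(valid, change_convention=config.change_convention)
            table.to_csv(outdir / "descriptive_means.csv")
            log["artifacts"]["descriptive_means"] = "descriptive_means.csv"

    if config.regions:
        with stage("regions"):
            regions = {}
            region_seed = int(rng.integers(2**31))
            for wave in ("pre", "post"):
                w = valid[valid["wave"] == wave]
                means = np.asarray(
                    [
                        compositional_mean(g[_COMP_COLS].to_numpy(), kappa=1.0)
                        for _, g in w.groupby("participant")
                    ]
                )
                for names, triples in subcompositions(means).items():
                    key = f"{wave}:{'-'.join(names)}"
                    regions[key] = confidence_region(
                        triples, n_boot=config.n_boot, seed=region_seed
                    )
            tio.write_regions(regions, outdir / "ternary_regions.json")
            log["artifacts"]["ternary_regions"] = "ternary_regions.json"

    if config.model:
        with stage("model"):
            frame = build_model_frame(valid, aggregation=config.aggregation)
            report = run_all_models(frame, levels=config.model_levels)
            report.to_csv(outdir / "fixed_effects.csv")
            (outdir / "fixed_effects.txt").write_text(report.summary() + "\n")
            log["artifacts"]["fixed_effects"] = "fixed_effects.csv"

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return log


def _epoch_demo(day_df: pd.DataFrame, config: PipelineConfig, rng) -> pd.DataFrame:
    """Round-trip a few simulated days through the epoch-level path."""
    from .simulate import DailyLog

    rows = []
    pool = day_df[day_df["valid"]].head(config.epoch_demo_days)
    for _, row in pool.iterrows():
        target = row[_COMP_COLS].to_numpy(dtype=float)
        target = target / target.sum() * MINUTES_PER_DAY
        log0 = make_daily_log("2020-01-06", "23:00", sleep_minutes=target[0])
        stream = simulate_epoch_stream(target, log0, seed=int(rng.integers(2**31)))
        next_bed = log0.bedtime + pd.Timedelta(minutes=MINUTES_PER_DAY)
        log1 = DailyLog(
            date=log0.date + pd.Timedelta(days=1),
            bedtime=next_bed,
            waketime=next_bed + pd.Timedelta(minutes=1),
        )
        days = process_stream(
            stream, [log0, log1], participant_id=str(row["participant"]), wave=str(row["wave"])
        )
        days = days.iloc[:1].copy()
        for col, tgt in zip(_COMP_COLS, target):
            days[f"target_{col}"] = tgt
        rows.append(days)
    return pd.concat(rows, ignore_index=True)


class _Stage:
    def __init__(self, name: str, log: dict):
        self.name = name
        self.log = log

    def __enter__(self):
        self.t0 = _time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = _time.perf_counter() - self.t0
        self.log["stages"][self.name] = {"seconds": round(elapsed, 3), "ok": exc is None}
        if exc is not None:
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        return False
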