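"""Synthetic cohorts and wrist-accelerometer epoch streams.

Two generators make the whole pipeline testable without any real data:

``simulate_cohort``
    Day-level 4-part compositions for a two-wave (pre/post retirement)
    cohort stratified by gender and pre-retirement occupation.  Noise is
    logistic-normal: participant effects, participant-specific change
    and day-to-day variation are independent normals in the 3-D balance
    coordinate space and are mapped back to the simplex through the
    inverse ilr transform, so the group compositional means are exactly
    the configured ones.

``simulate_epoch_stream``
    A stream of 5-s epoch summaries (ENMO, arm angle, per-axis 60-min
    window SD and range) realising a target day composition together
    with a daily log (bedtime/waking time), so the detector rules of the
    processing module can be round-trip tested.  Optional constant-
    signal blocks emulate the device being taken off.

Default cohort conditions mirror the study design they emulate: four
gender-by-occupation strata totalling 551 participants, seven
measurement days per wave, group pre-wave compositional means and
post-wave change perturbations taken from the published group means,
and six person-days with zero MVPA to exercise zero replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_SBP,
    MINUTES_PER_DAY,
    close,
    ilr_inverse,
    ilr_transform,
    perturb_diff,
)

__all__ = [
    "STRATA",
    "GROUP_MEANS_PRE",
    "GROUP_MEANS_POST",
    "default_change_perturbations",
    "CohortSimConfig",
    "ParticipantWave",
    "DailyLog",
    "simulate_cohort",
    "iter_participant_waves",
    "simulate_epoch_stream",
    "make_daily_log",
]

#: (gender, occupation) cells, in the fixed order used for ids and seeds
STRATA: tuple[tuple[str, str], ...] = (
    ("woman", "non-manual"),
    ("woman", "manual"),
    ("man", "non-manual"),
    ("man", "manual"),
)

#: published group mean minutes (sleep, SED, LPA, MVPA) before retirement
GROUP_MEANS_PRE: dict[tuple[str, str], tuple[float, ...]] = {
    ("woman", "non-manual"): (482.0, 684.0, 228.0, 46.0),
    ("woman", "manual"): (475.0, 622.0, 284.0, 58.0),
    ("man", "non-manual"): (455.0, 749.0, 188.0, 49.0),
    ("man", "manual"): (482.0, 677.0, 228.0, 53.0),
}

#: published group mean minutes after retirement
GROUP_MEANS_POST: dict[tuple[str, str], tuple[float, ...]] = {
    ("woman", "non-manual"): (517.0, 660.0, 221.0, 42.0),
    ("woman", "manual"): (520.0, 658.0, 221.0, 41.0),
    ("man", "non-manual"): (487.0, 721.0, 189.0, 43.0),
    ("man", "manual"): (504.0, 690.0, 206.0, 40.0),
}

#: stratum sizes of the cohort being emulated (total 551)
DEFAULT_N: dict[tuple[str, str], int] = {
    ("woman", "non-manual"): 308,
    ("woman", "manual"): 164,
    ("man", "non-manual"): 54,
    ("man", "manual"): 25,
}


def default_change_perturbations() -> dict[tuple[str, str], np.ndarray]:
    """Post/pre ratio compositions implied by the published group means."""
    return {
        s: perturb_diff(GROUP_MEANS_POST[s], GROUP_MEANS_PRE[s], kappa=1.0)
        for s in STRATA
    }


def _identity_perturbations() -> dict[tuple[str, str], np.ndarray]:
    return {s: np.full(4, 0.25) for s in STRATA}


@dataclass(frozen=True)
class CohortSimConfig:
    """Conditions for a two-wave cohort simulation.

    Parameters
    ----------
    n_per_stratum
        Either one count for every gender-by-occupation cell or a
        mapping from ``(gender, occupation)`` to a count.  The default
        mapping reproduces the emulated cohort's cell sizes (551 total).
    group_means
        Pre-wave mean composition per stratum, minutes summing to 1440
        (small rounding slack is re-closed).
    change_perturbations
        4-part perturbation applied at the post wave, per stratum.
    between_sd, within_sd, slope_sd
        SDs of the participant random effect, the day-level noise and
        the participant-specific change, per balance coordinate.  The
        day-to-day and between-person magnitudes are not published for
        the emulated study; the defaults are plausible for wrist-worn
        data and documented as this package's own choice.
    days_per_wave
        Measurement days per participant and wave.
    n_zero_mvpa_days
        Person-days whose MVPA is forced to exactly zero, emulating the
        handful of zero MVPA values the device can produce.
    p_invalid_day
        Probability that a day fails the 600-min waking-wear rule
        (emulating the ~1.5% of days lost in practice).
    day_length_jitter_sd
        SD (minutes) of day-length jitter; 0 keeps every simulated day
        at exactly 24 h.
    """

    n_per_stratum: int | Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N)
    )
    group_means: Mapping[tuple[str, str], Sequence[float]] = field(
        default_factory=lambda: dict(GROUP_MEANS_PRE)
    )
    change_perturbations: Mapping[tuple[str, str], Sequence[float]] = field(
        default_factory=default_change_perturbations
    )
    between_sd: tuple[float, float, float] = (0.30, 0.35, 0.18)
    within_sd: tuple[float, float, float] = (0.25, 0.40, 0.20)
    slope_sd: tuple[float, float, float] = (0.15, 0.20, 0.10)
    days_per_wave: int = 7
    n_zero_mvpa_days: int = 6
    p_invalid_day: float = 0.015
    day_length_jitter_sd: float = 0.0
    seed: int = 0

    def counts(self) -> dict[tuple[str, str], int]:
        if isinstance(self.n_per_stratum, Mapping):
            return {s: int(self.n_per_stratum[s]) for s in STRATA}
        return {s: int(self.n_per_stratum) for s in STRATA}

    def validate(self) -> None:
        for s, n in self.counts().items():
            if n < 1:
                raise ValueError(f"n_per_stratum for {s} must be >= 1")
        for s in STRATA:
            mean = np.asarray(self.group_means[s], dtype=float)
            if np.any(mean <= 0):
                raise ValueError(f"group mean for {s} must be strictly positive")
            if abs(mean.sum() - MINUTES_PER_DAY) > 2.0:
                raise ValueError(
                    f"group mean for {s} sums to {mean.sum():.1f}, not ~1440 min"
                )
            pert = np.asarray(self.change_perturbations[s], dtype=float)
            if np.any(pert <= 0):
                raise ValueError(f"change perturbation for {s} must be positive")
        for name in ("between_sd", "within_sd", "slope_sd"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.days_per_wave < 1:
            raise ValueError("days_per_wave must be >= 1")
        if not 0.0 <= self.p_invalid_day < 1.0:
            raise ValueError("p_invalid_day must be in [0, 1)")

    def with_identity_change(self) -> "CohortSimConfig":
        return replace(self, change_perturbations=_identity_perturbations())


@dataclass(frozen=True)
class ParticipantWave:
    """One participant's day compositions and covariates at one wave."""

    participant_id: str
    gender: str
    occupation: str
    wave: str  # "pre" | "post"
    day_compositions: np.ndarray  # (n_days, 4) minutes


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw a two-wave cohort of day-level compositions.

    Returns a tidy DataFrame with one row per (participant, wave, day):
    columns ``participant, gender, occupation, wave, day, sleep_min,
    sed_min, lpa_min, mvpa_min, waking_wear_min, day_length_min, valid``.
    Identical seeds give identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    stratum_seeds = root.spawn(len(STRATA) + 1)
    tail_rng = np.random.default_rng(stratum_seeds[-1])

    counts = config.counts()
    frames = []
    for s_idx, stratum in enumerate(STRATA):
        gender, occupation = stratum
        n = counts[stratum]
        days = config.days_per_wave
        rng = np.random.default_rng(stratum_seeds[s_idx])

        z_mean = ilr_transform(close(np.asarray(config.group_means[stratum], float), 1.0))
        z_pert = ilr_transform(close(np.asarray(config.change_perturbations[stratum], float), 1.0))

        b = rng.normal(0.0, config.between_sd, size=(n, 3))
        slope = rng.normal(0.0, config.slope_sd, size=(n, 3))
        e = rng.normal(0.0, config.within_sd, size=(n, 2, days, 3))

        z = np.empty((n, 2, days, 3))
        z[:, 0] = z_mean + b[:, None, :] + e[:, 0]
        z[:, 1] = z_mean + z_pert + (b + slope)[:, None, :] + e[:, 1]

        if config.day_length_jitter_sd > 0:
            day_len = rng.normal(MINUTES_PER_DAY, config.day_length_jitter_sd, size=(n, 2, days))
        else:
            day_len = np.full((n, 2, days), MINUTES_PER_DAY)
        comps = ilr_inverse(z, kappa=1.0) * day_len[..., None]

        pid = np.array([f"{gender[0]}{'m' if occupation == 'manual' else 'n'}{i:04d}" for i in range(n)])
        frame = pd.DataFrame(
            {
                "participant": np.repeat(pid, 2 * days),
                "gender": gender,
                "occupation": occupation,
                "wave": np.tile(np.repeat(["pre", "post"], days), n),
                "day": np.tile(np.arange(days), 2 * n),
                "sleep_min": comps[..., 0].ravel(),
                "sed_min": comps[..., 1].ravel(),
                "lpa_min": comps[..., 2].ravel(),
                "mvpa_min": comps[..., 3].ravel(),
                "day_length_min": day_len.ravel(),
            }
        )
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)

    # force a handful of zero-MVPA days (re-closing the rest of the day)
    n_zero = min(config.n_zero_mvpa_days, len(df))
    if n_zero > 0:
        rows = tail_rng.choice(len(df), size=n_zero, replace=False)
        cols = ["sleep_min", "sed_min", "lpa_min"]
        vals = df.loc[rows, cols].to_numpy()
        day_len = df.loc[rows, "day_length_min"].to_numpy()
        df.loc[rows, cols] = vals / vals.sum(axis=1, keepdims=True) * day_len[:, None]
        df.loc[rows, "mvpa_min"] = 0.0

    invalid = tail_rng.random(len(df)) < config.p_invalid_day
    waking_wear = df["day_length_min"].to_numpy() - df["sleep_min"].to_numpy()
    waking_wear = np.where(invalid, tail_rng.uniform(120.0, 599.0, len(df)), waking_wear)
    df["waking_wear_min"] = waking_wear
    df["valid"] = waking_wear >= 600.0
    return df


def iter_participant_waves(cohort: pd.DataFrame) -> Iterator[ParticipantWave]:
    """View a tidy cohort frame as ParticipantWave records."""
    cols = ["sleep_min", "sed_min", "lpa_min", "mvpa_min"]
    for (pid, wave), grp in cohort.groupby(["participant", "wave"], sort=True):
        yield ParticipantWave(
            participant_id=str(pid),
            gender=str(grp["gender"].iloc[0]),
            occupation=str(grp["occupation"].iloc[0]),
            wave=str(wave),
            day_compositions=grp.sort_values("day")[cols].to_numpy(),
        )


# ---------------------------------------------------------------------------
# epoch-level signal simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyLog:
    """Self-reported bed and waking times for one measurement day."""

    date: pd.Timestamp
    bedtime: pd.Timestamp
    waketime: pd.Timestamp

    def __post_init__(self):
        if self.waketime <= self.bedtime:
            raise ValueError("waketime must follow bedtime on the timeline")


def make_daily_log(date: str, bedtime_clock: str, sleep_minutes: float, in_bed_wake_minutes: float = 0.0) -> DailyLog:
    """Convenience constructor: bedtime on ``date`` plus a sleep window."""
    bedtime = pd.Timestamp(f"{date} {bedtime_clock}")
    wake = bedtime + pd.Timedelta(minutes=float(sleep_minutes + in_bed_wake_minutes))
    return DailyLog(date=pd.Timestamp(date), bedtime=bedtime, waketime=wake)


# wear-time signal levels: window SDs well above the 13 mg non-wear bound,
# ranges above 50 mg; injected non-wear sits clearly below both
_WEAR_SD = (15.0, 45.0)
_WEAR_RANGE = (60.0, 300.0)
_NONWEAR_SD = (0.0, 5.0)
_NONWEAR_RANGE = (0.0, 20.0)
# ENMO bands, kept a hair inside the cut-points so float noise cannot
# flip a label across a boundary
_ENMO = {
    "sleep": (0.0, 15.0),
    "sed": (0.0, 29.8),
    "lpa": (30.0, 100.4),
    "mvpa": (100.6, 400.0),
}


def _largest_remainder_counts(minutes: np.ndarray, epochs_per_min: int, total: int) -> np.ndarray:
    raw = minutes * epochs_per_min
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(raw - base)
        for i in order:
            take = min(base[i], -short)
            base[i] -= take
            short += take
            if short == 0:
                break
    return base


def simulate_epoch_stream(
    target,
    log: DailyLog,
    epoch_s: int = 5,
    seed=None,
    nonwear_blocks: Sequence[tuple[float, float]] = (),
    day_length_min: float = MINUTES_PER_DAY,
) -> pd.DataFrame:
    """Realise a day composition as a stream of epoch summaries.

    The stream covers one measurement day, ``[bedtime, bedtime +
    day_length_min)``.  Sleep epochs sit inside the logged window with
    arm-angle changes within 5 degrees over spans far exceeding 5 min;
    waking epochs oscillate in angle and carry ENMO drawn inside the
    correct intensity band; time in bed beyond the sleep target is spent
    still (drawn from the SED budget).  ``nonwear_blocks`` is a list of
    ``(start_min, duration_min)`` offsets from the day start, aligned to
    the 15-min detector grid; those epochs get constant-signal window
    statistics and displace whatever behavior was scheduled there.

    Returns a DataFrame with columns ``timestamp, enmo_mg,
    arm_angle_deg, sd_{x,y,z}_mg, range_{x,y,z}_mg`` plus a
    ``true_label`` ground-truth column (for validation only; the
    processing module never reads it).
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (4,):
        raise ValueError("target must be a 4-part composition in minutes")
    if np.any(target < 0):
        raise ValueError("target minutes must be nonnegative")
    epoch_min = epoch_s / 60.0
    if 60 % epoch_s != 0:
        raise ValueError("epoch_s must divide 60 s")
    if abs(target.sum() - day_length_min) > epoch_min:
        raise ValueError(
            f"target sums to {target.sum():.2f} min but the day is {day_length_min:.2f} min"
        )
    epochs_per_min = int(round(1.0 / epoch_min))
    n_total = int(round(day_length_min * epochs_per_min))

    window_min = (log.waketime - log.bedtime).total_seconds() / 60.0
    n_window = int(round(window_min * epochs_per_min))
    if n_window > n_total:
        raise ValueError("logged in-bed window exceeds the day length")
    # sleep is pinned first (capped at the logged window), the waking
    # parts split the remaining epochs by largest remainder: every part
    # lands within one epoch of its target
    n_sleep = min(int(round(target[0] * epochs_per_min)), n_window, n_total)
    if target[0] * epochs_per_min - n_window > 1.0:
        raise ValueError("sleep target exceeds the logged bed-to-wake window")
    waking = _largest_remainder_counts(target[1:], epochs_per_min, n_total - n_sleep)
    n_sed, n_lpa, n_mvpa = (int(c) for c in waking)
    n_in_bed_wake = n_window - n_sleep
    if n_in_bed_wake > n_sed:
        raise ValueError("SED budget too small to cover wakeful time in bed")

    rng = np.random.default_rng(seed)

    # label schedule: sleep block at bedtime, wakeful-in-bed stillness to
    # waketime, then shuffled 5-min bouts of the remaining behaviors
    labels = ["sleep"] * n_sleep + ["sed"] * n_in_bed_wake
    bout = 5 * epochs_per_min
    pool: list[np.ndarray] = []
    for lab, count in (("sed", n_sed - n_in_bed_wake), ("lpa", n_lpa), ("mvpa", n_mvpa)):
        k = count
        while k > 0:
            take = min(bout, k)
            pool.append(np.repeat(lab, take))
            k -= take
    rng.shuffle(pool)
    if pool:
        labels = np.concatenate([np.asarray(labels, dtype=object)] + pool)
    else:
        labels = np.asarray(labels, dtype=object)
    assert len(labels) == n_total

    # injected non-wear overwrites the schedule
    nonwear_mask = np.zeros(n_total, dtype=bool)
    for start_min, dur_min in nonwear_blocks:
        i0 = int(round(start_min * epochs_per_min))
        i1 = int(round((start_min + dur_min) * epochs_per_min))
        if i0 < 0 or i1 > n_total:
            raise ValueError("non-wear block falls outside the day")
        nonwear_mask[i0:i1] = True
    labels = np.where(nonwear_mask, "nonwear", labels)

    enmo = np.empty(n_total)
    angle = np.empty(n_total)
    for lab, (lo, hi) in _ENMO.items():
        m = labels == lab
        enmo[m] = rng.uniform(lo, hi, m.sum())
    enmo[nonwear_mask] = 0.0

    # arm angle: calm posture segments during sleep (30-60 min apart,
    # jitter <= 1 deg inside a segment), per-epoch +/-20 deg swings awake
    sleep_idx = np.flatnonzero(labels == "sleep")
    angle[:] = 20.0 * np.where(np.arange(n_total) % 2 == 0, 1.0, -1.0) + rng.uniform(-5, 5, n_total)
    if len(sleep_idx):
        pos = 0
        base = rng.uniform(-45.0, 45.0)
        while pos < len(sleep_idx):
            seg = int(rng.uniform(30, 60) * epochs_per_min)
            # absorb a short tail so every posture span stays detectable
            if len(sleep_idx) - (pos + seg) < 10 * epochs_per_min:
                seg = len(sleep_idx) - pos
            sel = sleep_idx[pos : pos + seg]
            angle[sel] = base + rng.uniform(-1.0, 1.0, len(sel))
            base = float(np.clip(base + rng.uniform(-30, 30), -80, 80))
            pos += seg
    angle[nonwear_mask] = 0.0

    sd = rng.uniform(*_WEAR_SD, size=(n_total, 3))
    rg = rng.uniform(*_WEAR_RANGE, size=(n_total, 3))
    sd[nonwear_mask] = rng.uniform(*_NONWEAR_SD, size=(int(nonwear_mask.sum()), 3))
    rg[nonwear_mask] = rng.uniform(*_NONWEAR_RANGE, size=(int(nonwear_mask.sum()), 3))

    ts = log.bedtime + pd.to_timedelta(np.arange(n_total) * epoch_s, unit="s")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "enmo_mg": enmo,
            "arm_angle_deg": angle,
            "sd_x_mg": sd[:, 0],
            "sd_y_mg": sd[:, 1],
            "sd_z_mg": sd[:, 2],
            "range_x_mg": rg[:, 0],
            "range_y_mg": rg[:, 1],
            "range_z_mg": rg[:, 2],
            "true_label": labels,
        }
    )
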