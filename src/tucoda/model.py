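"""Longitudinal mixed models on balance coordinates.

After the ilr transform, each of the three balance coordinates is an
ordinary real-valued outcome and the change across the transition is
estimated with a linear mixed model: fixed effects of time (post = 1),
gender (man = 1, reference woman) and occupation (manual = 1, reference
non-manual), with a random intercept and a random slope of time per
participant.  Three nested fixed-effect structures are fitted:

* Model 1 — time + gender + occupation (main effects);
* Model 2 — adds time x gender and time x occupation (optionally the
  gender x occupation term some reports include);
* Model 3 — adds time x gender x occupation with all lower-order terms.

Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
intervals and p-values are Wald-type, appropriate at cohort sample
sizes.  Coordinates can be fitted on every valid day (the default —
with only two waves, day-level replication is what makes the random
slope variance identifiable) or on per-wave compositional means with a
random intercept only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .composition import DEFAULT_SBP, SequentialBinaryPartition, ilr_transform

__all__ = [
    "build_model_frame",
    "BalanceMixedLM",
    "BalanceMixedLMResults",
    "run_all_models",
    "FixedEffectsReport",
    "FOCAL_TERMS",
]

_COMP_COLS = ["sleep_min", "sed_min", "lpa_min", "mvpa_min"]

#: focal fixed-effect rows reported per model level
FOCAL_TERMS = {
    1: ["time", "gender_man", "occ_manual"],
    2: ["time:gender_man", "time:occ_manual"],
    3: ["time:gender_man:occ_manual"],
}


def build_model_frame(
    cohort: pd.DataFrame,
    sbp: SequentialBinaryPartition = DEFAULT_SBP,
    aggregation: str = "day_level",
) -> pd.DataFrame:
    """Long-format coordinate observations for mixed modelling.

    ``cohort`` holds zero-replaced day compositions (columns
    ``participant, gender, occupation, wave`` and the four ``*_min``
    parts; a ``valid`` column, if present, restricts to valid days).
    ``aggregation="day_level"`` keeps one row per valid day;
    ``"wave_mean"`` collapses each participant-wave to its compositional
    mean before transforming (for log-ratio coordinates the two orders
    agree: the ilr of a geometric mean is the mean of the ilrs).

    Participants missing either wave are dropped (they cannot inform
    the change) and reported via the frame's ``attrs["n_dropped"]``.
    """
    df = cohort
    if "valid" in df.columns:
        df = df[df["valid"]]
    have_both = df.groupby("participant")["wave"].transform(lambda w: {"pre", "post"} <= set(w))
    n_dropped = df.loc[~have_both, "participant"].nunique()
    df = df[have_both]

    if aggregation == "day_level":
        out = df[["participant", "gender", "occupation", "wave"]].copy()
        if "day" in df.columns:
            out["day"] = df["day"].to_numpy()
        comps = df[_COMP_COLS].to_numpy()
    elif aggregation == "wave_mean":
        vals = df[_COMP_COLS].to_numpy()
        if np.any(vals <= 0):
            raise ValueError("model frame needs strictly positive parts; run replace_zeros first")
        tmp = df[["participant", "gender", "occupation", "wave"]].copy()
        tmp[_COMP_COLS] = np.log(vals)
        agg = tmp.groupby(["participant", "wave"], sort=True).agg(
            gender=("gender", "first"),
            occupation=("occupation", "first"),
            **{c: (c, "mean") for c in _COMP_COLS},
        ).reset_index()
        out = agg[["participant", "gender", "occupation", "wave"]].copy()
        # exp of the mean log = component-wise geometric mean; closure is
        # immaterial for the ilr below
        comps = np.exp(agg[_COMP_COLS].to_numpy())
    else:
        raise ValueError("aggregation must be 'day_level' or 'wave_mean'")

    if np.any(comps <= 0):
        raise ValueError("model frame needs strictly positive parts; run replace_zeros first")
    z = ilr_transform(comps, sbp)
    out = out.reset_index(drop=True)
    for k in range(z.shape[1]):
        out[f"z{k + 1}"] = z[:, k]
    out["time"] = (out["wave"] == "post").astype(int)
    out["gender_man"] = (out["gender"] == "man").astype(int)
    out["occ_manual"] = (out["occupation"] == "manual").astype(int)
    out.attrs["n_dropped"] = int(n_dropped)
    out.attrs["aggregation"] = aggregation
    return out


def _formula(coordinate: int, level: int, gender_occupation: bool) -> str:
    base = f"z{coordinate} ~ time + gender_man + occ_manual"
    if level == 1:
        return base
    if level == 2:
        f = base + " + time:gender_man + time:occ_manual"
        if gender_occupation:
            f += " + gender_man:occ_manual"
        return f
    if level == 3:
        return f"z{coordinate} ~ time * gender_man * occ_manual"
    raise ValueError("level must be 1, 2 or 3")


class BalanceMixedLM:
    """Mixed model for one balance coordinate.

    Parameters
    ----------
    frame : DataFrame from :func:`build_model_frame`.
    coordinate : which balance (1-based).
    level : fixed-effect structure (1, 2 or 3, see module docstring).
    model2_gender_occupation : include the gender x occupation term in
        the level-2 structure (off by default; the time interactions
        are what level 2 is for).
    random_slope : give participants a random slope of time in addition
        to the intercept (forced off for wave-mean frames, where two
        observations per participant cannot identify it).
    random_correlated : allow the intercept and slope to covary.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        coordinate: int = 1,
        level: int = 1,
        model2_gender_occupation: bool = False,
        random_slope: bool | None = None,
        random_correlated: bool = True,
    ):
        if coordinate not in (1, 2, 3):
            raise ValueError("coordinate must be 1, 2 or 3")
        if random_slope is None:
            random_slope = frame.attrs.get("aggregation", "day_level") == "day_level"
        self.frame = frame
        self.coordinate = coordinate
        self.level = level
        self.formula = _formula(coordinate, level, model2_gender_occupation)
        self.random_slope = bool(random_slope)
        self.random_correlated = random_correlated

    def fit(self, reml: bool = True, maxiter: int = 200) -> "BalanceMixedLMResults":
        """REML fit; on non-convergence, refit with intercept-only
        random effects and carry the convergence flag."""
        used_slope = self.random_slope
        res = self._fit_once(used_slope, reml, maxiter)
        if res is None or not res.converged:
            fallback = self._fit_once(False, reml, maxiter)
            if fallback is not None and (res is None or fallback.converged):
                res, used_slope = fallback, False
        if res is None:
            raise RuntimeError("mixed model estimation failed for every structure")
        return BalanceMixedLMResults(self, res, used_slope)

    def _fit_once(self, random_slope: bool, reml: bool, maxiter: int):
        kwargs: dict = {"groups": "participant"}
        if random_slope and self.random_correlated:
            kwargs["re_formula"] = "~time"
        elif random_slope:
            kwargs["re_formula"] = "1"
            kwargs["vc_formula"] = {"time": "0 + time"}
        else:
            kwargs["re_formula"] = "1"
        model = smf.mixedlm(self.formula, self.frame, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return model.fit(reml=reml, maxiter=maxiter)
            except (np.linalg.LinAlgError, ValueError):
                return None


class BalanceMixedLMResults:
    """Fixed-effect estimates, Wald 95% CIs and p-values for one fit."""

    def __init__(self, model: BalanceMixedLM, smresults, used_random_slope: bool):
        self.model = model
        self._res = smresults
        self.used_random_slope = used_random_slope
        self.converged = bool(smresults.converged)
        fe = smresults.fe_params
        ci = smresults.conf_int().loc[fe.index]
        self.table = pd.DataFrame(
            {
                "term": fe.index,
                "estimate": fe.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
                "p_value": smresults.pvalues.loc[fe.index].to_numpy(),
            }
        ).reset_index(drop=True)

    @property
    def params(self) -> pd.Series:
        return self._res.fe_params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse.loc[self._res.fe_params.index]

    @property
    def n_participants(self) -> int:
        return int(self.model.frame["participant"].nunique())

    @property
    def n_obs(self) -> int:
        return int(len(self.model.frame))

    def conf_int(self) -> pd.DataFrame:
        return self._res.conf_int().loc[self._res.fe_params.index]

    def summary(self) -> str:
        head = (
            f"Balance coordinate {self.model.coordinate}, model level {self.model.level}\n"
            f"{self.n_participants} participants, {self.n_obs} observations; "
            f"random slope: {self.used_random_slope}; converged: {self.converged}\n"
        )
        body = self.table.to_string(
            index=False, float_format=lambda v: f"{v: .3f}"
        )
        return head + body


@dataclass(frozen=True)
class FixedEffectsReport:
    """Focal fixed effects for 3 coordinates x 3 model levels."""

    table: pd.DataFrame
    coordinate_labels: tuple[str, ...]

    def summary(self) -> str:
        lines = []
        for k, label in enumerate(self.coordinate_labels, start=1):
            lines.append(f"Coordinate {k}: {label}")
            sub = self.table[self.table["coordinate"] == k]
            for level, grp in sub.groupby("model"):
                lines.append(f"  Model {level}")
                for _, row in grp.iterrows():
                    lines.append(
                        f"    {row['term']:<28s} {row['estimate']: .2f} "
                        f"[{row['ci_low']: .2f}, {row['ci_high']: .2f}]  p={row['p_value']:.3g}"
                    )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_all_models(
    frame: pd.DataFrame,
    levels: tuple[int, ...] = (1, 2, 3),
    coordinate_labels: tuple[str, ...] = (
        "active vs passive behaviors",
        "LPA vs MVPA",
        "SED vs sleep",
    ),
    **model_kwargs,
) -> FixedEffectsReport:
    """Fit every (coordinate, level) model and collect the focal terms.

    The report mirrors the conventional layout: per coordinate, the
    level-1 main effects (time, gender, occupation), the level-2 time
    interactions, and the level-3 three-way interaction.
    """
    rows = []
    for coordinate in (1, 2, 3):
        for level in levels:
            res = BalanceMixedLM(frame, coordinate=coordinate, level=level, **model_kwargs).fit()
            tab = res.table.set_index("term")
            for term in FOCAL_TERMS[level]:
                rows.append(
                    {
                        "coordinate": coordinate,
                        "model": level,
                        "term": term,
                        "estimate": tab.loc[term, "estimate"],
                        "ci_low": tab.loc[term, "ci_low"],
                        "ci_high": tab.loc[term, "ci_high"],
                        "p_value": tab.loc[term, "p_value"],
                        "converged": res.converged,
                        "n_participants": res.n_participants,
                        "n_obs": res.n_obs,
                    }
                )
    return FixedEffectsReport(table=pd.DataFrame(rows), coordinate_labels=coordinate_labels)
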