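"""Outlier screening of paired pre/post compositions via log contrasts.

A participant whose change composition departs wildly from the cohort —
say a post sleep/SED ratio twenty times the typical change — distorts
compositional means and model fits.  Each participant's change is
summarised by the six pairwise log-ratio change scores

    s_ij = ln( (post_i / post_j) / (pre_i / pre_j) ),   i < j,

which are closure-invariant; a participant is flagged when any score is
a robust-z outlier (|score - median| / (1.4826 * MAD) beyond a
threshold) across the cohort.  Flagged participants are reported, never
silently dropped.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .composition import PARTS

__all__ = ["pairwise_logratio_changes", "flag_outliers"]

_MAD_SCALE = 1.4826  # consistency factor for normal data


def pairwise_logratio_changes(pre, post, parts: tuple[str, ...] = PARTS) -> pd.DataFrame:
    """The six pairwise log-ratio change scores per participant.

    ``pre`` and ``post`` are aligned ``(n, D)`` arrays of strictly
    positive compositions.  Columns are labelled ``"i/j"`` by part name.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be aligned arrays of equal shape")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("log contrasts need strictly positive parts")
    lpre, lpost = np.log(pre), np.log(post)
    cols = {}
    for i, j in combinations(range(pre.shape[1]), 2):
        name = f"{parts[i]}/{parts[j]}"
        cols[name] = (lpost[:, i] - lpost[:, j]) - (lpre[:, i] - lpre[:, j])
    return pd.DataFrame(cols)


def flag_outliers(
    pre,
    post,
    threshold: float = 3.5,
    parts: tuple[str, ...] = PARTS,
    min_cohort: int = 10,
) -> pd.DataFrame:
    """Robust-z screen of pairwise log-ratio change scores.

    Returns a DataFrame with one row per participant: the max absolute
    robust z over the six scores, the score attaining it, and the
    ``flagged`` verdict.  With fewer than ``min_cohort`` participants
    the medians and MADs are too unstable to screen on, so flagging is
    disabled with a warning.
    """
    scores = pairwise_logratio_changes(pre, post, parts)
    n = len(scores)
    if n < min_cohort:
        warnings.warn(
            f"cohort of {n} < {min_cohort}: outlier flagging disabled",
            stacklevel=2,
        )
        return pd.DataFrame(
            {
                "max_abs_z": np.zeros(n),
                "worst_score": [""] * n,
                "flagged": np.zeros(n, dtype=bool),
            }
        )
    med = scores.median(axis=0)
    mad = (scores - med).abs().median(axis=0) * _MAD_SCALE
    dev = (scores - med).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / mad
    # a column with zero spread: identical scores get z 0, any deviation is infinite
    z = z.where(~((mad == 0) & (dev == 0)), 0.0)
    worst = z.abs().idxmax(axis=1)
    max_abs = z.abs().max(axis=1)
    return pd.DataFrame(
        {
            "max_abs_z": max_abs.to_numpy(),
            "worst_score": worst.to_numpy(),
            "flagged": (max_abs > threshold).to_numpy(),
        }
    )
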