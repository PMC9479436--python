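"""Ternary geometry: barycentric coordinates and bootstrap confidence regions.

A 3-part composition lives on a triangle; its position encodes the
ratios of the three parts.  Uncertainty around a group's compositional
mean is summarised by bootstrapping the mean, assuming normality in a
2-D log-ratio plane, and drawing the Mahalanobis ellipse at the desired
coverage — then mapping the ellipse back onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import SequentialBinaryPartition, close, ilr_inverse, ilr_transform

__all__ = ["ternary_coords", "TernaryRegion", "confidence_region"]

_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_coords(x) -> np.ndarray:
    """Barycentric map of 3-part compositions onto the unit triangle.

    Vertices map to corners: (1,0,0) -> (0,0), (0,1,0) -> (1,0),
    (0,0,1) -> (0.5, sqrt(3)/2).  Invariant to rescaling of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 3:
        raise ValueError("ternary coordinates are defined for 3-part compositions")
    p = close(x, 1.0)
    return p @ _CORNERS


@dataclass(frozen=True)
class TernaryRegion:
    """A confidence region for a compositional mean on the 3-simplex.

    ``center`` is the point estimate (closed to 1), ``boundary`` an
    ordered loop of 3-part compositions tracing the contour, ``level``
    the nominal coverage.  ``center2``/``cov2`` hold the bootstrap mean
    and covariance in the internal 2-D log-ratio plane so membership can
    be tested without re-tracing the ellipse.
    """

    center: np.ndarray
    boundary: np.ndarray
    level: float
    center2: np.ndarray
    cov2: np.ndarray
    degenerate: bool = False

    def contains(self, composition) -> bool:
        """Is a 3-part composition inside the region?"""
        z = ilr_transform(close(composition, 1.0), _TRIPLE_SBP)
        if self.degenerate:
            return bool(np.allclose(z, self.center2))
        d = z - self.center2
        m2 = float(d @ np.linalg.solve(self.cov2, d))
        return m2 <= stats.chi2.ppf(self.level, df=2)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "degenerate": self.degenerate,
            "center": self.center.tolist(),
            "boundary": self.boundary.tolist(),
        }


_TRIPLE_SBP = SequentialBinaryPartition.triple()


def confidence_region(
    samples,
    level: float = 0.95,
    n_boot: int = 2000,
    seed=None,
    n_points: int = 128,
) -> TernaryRegion:
    """Bootstrap confidence region for the compositional mean of 3-part data.

    The compositional mean of each bootstrap resample is mapped to 2-D
    balance coordinates (where it is the arithmetic mean of the
    resampled coordinates); the region is the ellipse of squared
    Mahalanobis distance up to the ``level`` quantile of a chi-square
    with 2 df around the bootstrap mean, traced at ``n_points`` points
    and mapped back to the simplex.  Deterministic given ``seed``.

    A degenerate bootstrap covariance (e.g. all samples identical)
    collapses the region to a point.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("need an (n, 3) array of compositions")
    if len(x) == 0:
        raise ValueError("need at least one sample")
    z = ilr_transform(close(x, 1.0), _TRIPLE_SBP)
    n = len(z)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = z[idx].mean(axis=1)  # (n_boot, 2)
    center2 = boot_means.mean(axis=0)
    cov2 = np.cov(boot_means.T) if n_boot > 1 else np.zeros((2, 2))
    cov2 = np.atleast_2d(cov2)
    center = ilr_inverse(center2, _TRIPLE_SBP, kappa=1.0)
    sign, logdet = np.linalg.slogdet(cov2)
    if sign <= 0 or logdet < -80:
        return TernaryRegion(
            center=center,
            boundary=center[None, :],
            level=level,
            center2=center2,
            cov2=cov2,
            degenerate=True,
        )
    radius = np.sqrt(stats.chi2.ppf(level, df=2))
    chol = np.linalg.cholesky(cov2)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=0)
    ellipse = center2[:, None] + radius * (chol @ circle)
    boundary = ilr_inverse(ellipse.T, _TRIPLE_SBP, kappa=1.0)
    return TernaryRegion(
        center=center,
        boundary=boundary,
        level=level,
        center2=center2,
        cov2=cov2,
    )
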