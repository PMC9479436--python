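"""Aitchison-simplex primitives for time-use compositions.

A day's movement behaviors — sleep, sedentary time (SED), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA) — carve
up a fixed budget of minutes, so only their relative sizes are
informative.  This module provides the simplex operations that treatment
of such data requires: closure to a constant sum, multiplicative
replacement of zeros below a detection limit, the perturbation group
operation, the compositional (geometric) mean, leave-one-out
subcompositions, and the isometric log-ratio (ilr) transform defined by
a sequential binary partition (SBP), together with its inverse.

All functions are vectorised over the leading axes: a ``(..., D)`` array
of compositions in, a ``(..., D)`` or ``(..., D-1)`` array out.  Nothing
here hard-wires ``D = 4``; the movement-behavior part order and default
partition are module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARTS",
    "DEFAULT_SBP",
    "BALANCE_NAMES",
    "close",
    "replace_zeros",
    "perturb",
    "perturb_diff",
    "compositional_mean",
    "subcompositions",
    "SequentialBinaryPartition",
    "ilr_transform",
    "ilr_inverse",
]

#: canonical part order used throughout the package
PARTS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")

#: names of the three balance coordinates of the default partition
BALANCE_NAMES: tuple[str, ...] = ("active_vs_passive", "lpa_vs_mvpa", "sed_vs_sleep")

MINUTES_PER_DAY = 1440.0


def _as_parts(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("a composition needs at least two parts")
    return x


def close(parts, kappa: float = 1.0) -> np.ndarray:
    """Rescale compositions so each sums to ``kappa``.

    Parameters
    ----------
    parts : array-like, shape (..., D)
        Nonnegative part values; at least one part per composition must
        be positive.
    kappa : float
        Closure constant (1 for proportions, 1440 for minutes per day).

    Returns
    -------
    ndarray, shape (..., D)
    """
    x = _as_parts(parts)
    if np.any(x < 0):
        raise ValueError("compositional parts must be nonnegative")
    total = x.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("cannot close an all-zero composition")
    return kappa * x / total


def replace_zeros(parts, detection_limit: float = 1.0, fraction: float = 0.65) -> np.ndarray:
    """Multiplicative simple replacement of zero parts.

    Zeros (values a device could not resolve, e.g. a day with no
    recorded MVPA) are set to ``fraction * detection_limit`` and the
    remaining parts are scaled down multiplicatively so each
    composition's total is preserved.  Expressed on the scale of the
    data: with minutes summing to 1440 and a 1-minute detection limit, a
    zero becomes 0.65 min and every nonzero part is multiplied by
    ``(1440 - 0.65) / 1440``.

    ``detection_limit`` is interpreted in the same units as ``parts``
    (pass ``1/1440`` for data already closed to 1).
    """
    x = _as_parts(parts)
    if np.any(x < 0):
        raise ValueError("compositional parts must be nonnegative")
    total = x.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("cannot replace zeros in an all-zero composition")
    delta = fraction * detection_limit
    zero = x == 0
    imputed_sum = zero.sum(axis=-1, keepdims=True) * delta
    if np.any(imputed_sum >= total):
        raise ValueError("imputed mass would exceed the composition total")
    scale = (total - imputed_sum) / total
    return np.where(zero, delta, x * scale)


def perturb(x, y, kappa: float = 1.0) -> np.ndarray:
    """Perturbation, the simplex group operation: ``close(x * y)``."""
    return close(_as_parts(x) * _as_parts(y), kappa)


def perturb_diff(post, pre, kappa: float = 1.0) -> np.ndarray:
    """Compositional change from ``pre`` to ``post``.

    The component-wise ratio ``post / pre``, closed to ``kappa``: the
    simplex analogue of a paired difference.  A neutral change is the
    equal-parts composition.
    """
    pre = _as_parts(pre)
    if np.any(pre <= 0):
        raise ValueError("pre composition must be strictly positive")
    return close(_as_parts(post) / pre, kappa)


def compositional_mean(compositions, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Center of a compositional sample.

    The closure of the component-wise geometric means, rescaled to
    ``kappa`` (1440 min by default).  ``compositions`` is an ``(n, D)``
    array of strictly positive rows.
    """
    x = np.asarray(compositions, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        raise ValueError("cannot take the mean of an empty sample")
    if np.any(x <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    return close(np.exp(np.log(x).mean(axis=0)), kappa)


def subcompositions(x, parts: tuple[str, ...] = PARTS) -> dict[tuple[str, ...], np.ndarray]:
    """All leave-one-out subcompositions, each re-closed to 1.

    Returns a dict mapping the tuple of retained part names to the
    closed triple (for a 4-part input).  Ratios among retained parts are
    unchanged — subcompositional coherence.
    """
    x = _as_parts(x)
    d = x.shape[-1]
    if len(parts) != d:
        raise ValueError("part names must match the number of parts")
    out: dict[tuple[str, ...], np.ndarray] = {}
    for drop in range(d):
        keep = [i for i in range(d) if i != drop]
        names = tuple(parts[i] for i in keep)
        out[names] = close(x[..., keep], 1.0)
    return out


@dataclass(frozen=True)
class SequentialBinaryPartition:
    """A nested scheme splitting parts into +/− groups, one per balance.

    ``signs`` is a ``(D-1, D)`` integer array with entries in
    ``{+1, -1, 0}``.  Row ``k`` defines balance coordinate ``k`` as

        z_k = sqrt(r s / (r + s)) * ln( g(x_+) / g(x_-) )

    where ``g`` is the geometric mean over the positive (r parts) and
    negative (s parts) groups.  Rows must be nested: the parts split in
    a row lie entirely inside one sign group of every earlier row.

    The default partition for the 24-h behaviors puts the active
    behaviors {LPA, MVPA} against the passive {sleep, SED} (coordinate
    1), then LPA against MVPA (coordinate 2), then SED against sleep
    (coordinate 3).
    """

    signs: np.ndarray
    parts: tuple[str, ...] = PARTS
    names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        signs = np.asarray(self.signs, dtype=int)
        d = len(self.parts)
        if signs.shape != (d - 1, d):
            raise ValueError(f"expected a ({d - 1}, {d}) sign table, got {signs.shape}")
        if not np.isin(signs, (-1, 0, 1)).all():
            raise ValueError("sign entries must be -1, 0 or +1")
        for k, row in enumerate(signs):
            if not (row == 1).any() or not (row == -1).any():
                raise ValueError(f"row {k} must have at least one + and one - part")
            active = row != 0
            for j in range(k):
                prior = signs[j, active]
                if len(set(prior.tolist())) > 1:
                    raise ValueError(
                        f"row {k} is not nested within row {j}: its parts span "
                        "more than one group of the earlier split"
                    )
        object.__setattr__(self, "signs", signs)
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"z{k + 1}" for k in range(d - 1))
            )
        elif len(self.names) != d - 1:
            raise ValueError("need one balance name per row")

    @property
    def n_parts(self) -> int:
        return self.signs.shape[1]

    @property
    def basis_matrix(self) -> np.ndarray:
        """Orthonormal ilr contrast matrix ``V`` of shape (D-1, D).

        ``z = V @ ln(x)``; rows are orthonormal and sum to zero, so the
        transform is invariant to closure.
        """
        signs = self.signs
        v = np.zeros(signs.shape, dtype=float)
        for k, row in enumerate(signs):
            r = float((row == 1).sum())
            s = float((row == -1).sum())
            coef = np.sqrt(r * s / (r + s))
            v[k, row == 1] = coef / r
            v[k, row == -1] = -coef / s
        return v

    @classmethod
    def movement_behaviors(cls) -> "SequentialBinaryPartition":
        """The default partition: (LPA,MVPA | sleep,SED), (LPA | MVPA), (SED | sleep)."""
        return cls(
            signs=np.array(
                [
                    [-1, -1, 1, 1],
                    [0, 0, 1, -1],
                    [-1, 1, 0, 0],
                ]
            ),
            parts=PARTS,
            names=BALANCE_NAMES,
        )

    @classmethod
    def triple(cls, parts: tuple[str, str, str] = ("a", "b", "c")) -> "SequentialBinaryPartition":
        """A 3-part partition (first | rest), (second | third).

        Used as the 2-D log-ratio basis for ternary geometry; any
        orthonormal basis gives the same Mahalanobis ellipse.
        """
        return cls(signs=np.array([[1, -1, -1], [0, 1, -1]]), parts=parts)


#: default partition instance
DEFAULT_SBP = SequentialBinaryPartition.movement_behaviors()


def ilr_transform(x, sbp: SequentialBinaryPartition = DEFAULT_SBP) -> np.ndarray:
    """Balance coordinates of strictly positive compositions.

    ``x`` has shape ``(..., D)``; the result has shape ``(..., D-1)``
    with coordinate ``k`` the scaled log-ratio of the geometric means of
    row ``k``'s positive and negative groups.  Invariant to rescaling of
    ``x``.
    """
    x = _as_parts(x)
    if x.shape[-1] != sbp.n_parts:
        raise ValueError("composition and partition disagree on the number of parts")
    if np.any(x <= 0):
        raise ValueError(
            "balance coordinates need strictly positive parts; "
            "apply replace_zeros first"
        )
    return np.log(x) @ sbp.basis_matrix.T


def ilr_inverse(z, sbp: SequentialBinaryPartition = DEFAULT_SBP, kappa: float = 1.0) -> np.ndarray:
    """Map balance coordinates back to the simplex.

    The unique positive composition (closed to ``kappa``) whose balance
    coordinates under ``sbp`` equal ``z``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("balance coordinates must be finite")
    return close(np.exp(z @ sbp.basis_matrix), kappa)
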