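"""Agreement weight matrices for ordinal rating categories.

Weighted agreement coefficients give partial credit to near-diagonal
disagreements through a symmetric matrix of weights ``omega[i, j]`` with unit
diagonal and values in [0, 1].  Five schemes are supported, for categories
scored 1..q and distance d = |i - j|:

==============  ==========================================================
unweighted      1 if d = 0 else 0 (nominal agreement)
linear          1 - d / (q - 1)
quadratic       1 - d^2 / (q - 1)^2
radical         1 - sqrt(d) / sqrt(q - 1)
ordinal         1 - M(d) / M(q - 1), M(d) = C(d + 1, 2), the number of
                category pairs spanned by the two ratings
==============  ==========================================================

Quadratic weights penalise small disagreements least, radical weights most;
all schemes vanish at the maximal distance d = q - 1 except unweighted, which
is zero for every d > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt

import numpy as np

from .errors import InvalidDimensionError

#: The closed set of supported weighting schemes.
SCHEMES = ("unweighted", "linear", "quadratic", "radical", "ordinal")


def _validate_scheme(scheme: str) -> str:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; choose from {SCHEMES}")
    return scheme


@dataclass(frozen=True)
class WeightMatrix:
    """A q x q agreement weight matrix for one scheme.

    Attributes
    ----------
    q : int
        Number of ordinal categories.
    omega : numpy.ndarray
        Symmetric (q, q) array with unit diagonal, entries in [0, 1].
        The array is read-only.
    scheme : str
        One of :data:`SCHEMES`.
    """

    q: int
    omega: np.ndarray = field(repr=False)
    scheme: str

    def __post_init__(self) -> None:
        if self.q < 2:
            raise InvalidDimensionError("weight matrices require q >= 2")
        if self.omega.shape != (self.q, self.q):
            raise InvalidDimensionError(
                f"omega has shape {self.omega.shape}, expected {(self.q, self.q)}"
            )

    @property
    def total(self) -> float:
        """Sum of all weights, T_w (used by the AC2 and BP chance terms)."""
        return float(self.omega.sum())


def _omega(scheme: str, q: int, scores: np.ndarray) -> np.ndarray:
    span = scores[-1] - scores[0]
    d = np.abs(np.subtract.outer(scores, scores))
    if scheme == "unweighted":
        return (d == 0).astype(float)
    if scheme == "linear":
        return 1.0 - d / span
    if scheme == "quadratic":
        return 1.0 - d**2 / span**2
    if scheme == "radical":
        return 1.0 - np.sqrt(d) / sqrt(span)
    # ordinal: rank-based, ignores the numeric scores by construction
    idx = np.arange(q)
    dist = np.abs(np.subtract.outer(idx, idx))
    m = np.vectorize(lambda k: comb(int(k) + 1, 2))(dist).astype(float)
    return 1.0 - m / comb(q, 2)


_CACHE: dict[tuple[str, int], WeightMatrix] = {}


def build_weight_matrix(scheme: str, q: int, scores=None) -> WeightMatrix:
    """Construct the weight matrix for ``scheme`` over ``q`` categories.

    Parameters
    ----------
    scheme : str
        One of :data:`SCHEMES`.
    q : int
        Number of ordinal categories, at least 2.
    scores : array-like of float, optional
        Strictly increasing numeric category scores; defaults to 1..q.
        The ordinal scheme uses ranks only and ignores scores.

    Returns
    -------
    WeightMatrix
    """
    _validate_scheme(scheme)
    if q < 2:
        raise InvalidDimensionError(f"q must be >= 2, got {q}")
    default = scores is None
    if default and (scheme, q) in _CACHE:
        return _CACHE[(scheme, q)]
    x = np.arange(1, q + 1, dtype=float) if default else np.asarray(scores, float)
    if x.shape != (q,) or np.any(np.diff(x) <= 0):
        raise ValueError("scores must be a strictly increasing vector of length q")
    omega = _omega(scheme, q, x)
    omega.flags.writeable = False
    w = WeightMatrix(q=q, omega=omega, scheme=scheme)
    if default:
        _CACHE[(scheme, q)] = w
    return w
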