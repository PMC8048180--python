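"""Latent-variable generation of ordinal agreement tables.

Two raters' ordinal ratings are modelled as discretizations of a standard
bivariate normal latent pair (Y1, Y2) with correlation ``rho``: category i is
assigned when the latent value falls between consecutive cutoffs on the
standard-normal scale.  The joint cell probabilities are then bivariate
normal rectangle probabilities, and observed tables are multinomial draws of
size N over the q^2 cells.

The cutoffs control the marginal structure of the table:

* ``balanced`` — cutoffs at the standard-normal quantiles k/q, giving equal
  category probabilities 1/q;
* ``slightly_unbalanced`` — category probabilities proportional to 1..q;
* ``heavily_unbalanced`` — category probabilities proportional to 2^(i-1).

The two unbalanced quantile sets are package defaults (the skew levels are
not pinned by an external reference) and can be overridden with any strictly
increasing quantile vector.

The latent correlation maps onto the strength of agreement; the study design
uses rho = 0.1, 0.6, 0.9 for low, medium and high agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal, norm

from .errors import (
    InvalidCorrelationError,
    InvalidCutoffError,
    InvalidDimensionError,
    InvalidSizeError,
)
from .measures import ContingencyTable, CoefficientValue, ProbabilityTable, coefficient

#: Table structures and their conventional abbreviations.
STRUCTURES = ("balanced", "slightly_unbalanced", "heavily_unbalanced")
STRUCTURE_ABBR = {"BL": "balanced", "UB1": "slightly_unbalanced", "UB2": "heavily_unbalanced"}


@dataclass(frozen=True)
class LatentSpec:
    """Standard bivariate normal latent pair: means 0, variances 1."""

    rho: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise InvalidCorrelationError(f"rho must be in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class CutoffSet:
    """q - 1 strictly increasing thresholds on the standard-normal scale."""

    q: int
    structure: str
    cuts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.cuts, dtype=float)
        if c.shape != (self.q - 1,):
            raise InvalidCutoffError(
                f"expected {self.q - 1} cutoffs for q={self.q}, got shape {c.shape}"
            )
        if not np.all(np.isfinite(c)) or np.any(np.diff(c) <= 0):
            raise InvalidCutoffError("cutoffs must be finite and strictly increasing")
        c = np.ascontiguousarray(c)
        c.flags.writeable = False
        object.__setattr__(self, "cuts", c)

    @property
    def category_probs(self) -> np.ndarray:
        """Marginal probability of each category implied by the cutoffs."""
        cdf = np.concatenate(([0.0], norm.cdf(self.cuts), [1.0]))
        return np.diff(cdf)


def balanced_cutoffs(q: int) -> CutoffSet:
    """Cutoffs at the standard-normal quantiles k/q, k = 1..q-1."""
    if q < 2:
        raise InvalidDimensionError(f"q must be >= 2, got {q}")
    cuts = norm.ppf(np.arange(1, q) / q)
    return CutoffSet(q=q, structure="balanced", cuts=cuts)


def _default_quantiles(q: int, structure: str) -> np.ndarray:
    if structure == "slightly_unbalanced":
        probs = np.arange(1, q + 1, dtype=float)
    else:  # heavily_unbalanced
        probs = 2.0 ** np.arange(q)
    probs /= probs.sum()
    return np.cumsum(probs)[:-1]


def unbalanced_cutoffs(q: int, structure: str, quantiles=None) -> CutoffSet:
    """Cutoffs for a skewed marginal structure.

    Parameters
    ----------
    q : int
        Number of categories.
    structure : str
        ``slightly_unbalanced`` or ``heavily_unbalanced``.
    quantiles : array-like, optional
        Strictly increasing cumulative quantiles in (0, 1), length q - 1.
        Defaults to the package's documented skew levels.
    """
    if q < 2:
        raise InvalidDimensionError(f"q must be >= 2, got {q}")
    if structure not in ("slightly_unbalanced", "heavily_unbalanced"):
        raise ValueError(f"structure must be an unbalanced label, got {structure!r}")
    u = _default_quantiles(q, structure) if quantiles is None else np.asarray(quantiles, float)
    if u.shape != (q - 1,) or np.any(np.diff(u) <= 0) or u[0] <= 0 or u[-1] >= 1:
        raise InvalidCutoffError(
            "quantiles must be strictly increasing inside (0, 1) with length q - 1"
        )
    return CutoffSet(q=q, structure=structure, cuts=norm.ppf(u))


def make_cutoffs(structure: str, q: int, quantiles=None) -> CutoffSet:
    """Dispatch on structure name or abbreviation (BL, UB1, UB2)."""
    structure = STRUCTURE_ABBR.get(structure, structure)
    if structure == "balanced":
        return balanced_cutoffs(q)
    return unbalanced_cutoffs(q, structure, quantiles)


def _bvn_cdf_grid(cuts_x: np.ndarray, cuts_y: np.ndarray, rho: float) -> np.ndarray:
    """CDF of the standard bivariate normal on the cutoff grid incl. +-inf."""
    gx = np.concatenate(([-np.inf], cuts_x, [np.inf]))
    gy = np.concatenate(([-np.inf], cuts_y, [np.inf]))
    out = np.zeros((gx.size, gy.size))
    if rho == 0.0:
        return np.outer(norm.cdf(gx), norm.cdf(gy))
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    for i, x in enumerate(gx):
        for j, y in enumerate(gy):
            if np.isneginf(x) or np.isneginf(y):
                out[i, j] = 0.0
            elif np.isposinf(x):
                out[i, j] = norm.cdf(y)
            elif np.isposinf(y):
                out[i, j] = norm.cdf(x)
            else:
                out[i, j] = mvn.cdf([x, y])
    return out


def joint_probabilities(
    spec: LatentSpec | float, row_cuts: CutoffSet, col_cuts: CutoffSet
) -> ProbabilityTable:
    """Joint cell probabilities of the discretized latent pair.

    ``p[i, j]`` is the rectangle probability that Y1 falls in row category i
    and Y2 in column category j under the standard bivariate normal with
    correlation ``spec.rho``.
    """
    if not isinstance(spec, LatentSpec):
        spec = LatentSpec(float(spec))
    if row_cuts.q != col_cuts.q:
        raise InvalidDimensionError(
            f"row cutoffs have q={row_cuts.q} but column cutoffs have q={col_cuts.q}"
        )
    cdf = _bvn_cdf_grid(row_cuts.cuts, col_cuts.cuts, spec.rho)
    p = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return ProbabilityTable(p)


def sample_table(
    p: ProbabilityTable, n: int, seed: int | np.random.Generator
) -> ContingencyTable:
    """One multinomial draw of size ``n`` over the q^2 cells of ``p``."""
    if n < 1:
        raise InvalidSizeError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, p.p.ravel()).reshape(p.q, p.q)
    return ContingencyTable(counts)


def true_coefficient(
    p: ProbabilityTable, measure: str, scheme: str, n: int | None = None
) -> CoefficientValue:
    """Population value of a coefficient, computed from the joint probabilities.

    This is the "true kappa" against which sampled estimates are judged in
    the accuracy study.  Without ``n``, Krippendorff's alpha is returned in
    its asymptotic form (no finite-sample correction).
    """
    return coefficient(p, measure, scheme, n=n)
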