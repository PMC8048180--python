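"""Chance-corrected weighted inter-rater agreement coefficients.

All five measures share the generic form

    delta = (p_a - p_e) / (1 - p_e),

where ``p_a = sum_ij omega_ij p_ij`` is the weighted observed agreement and
``p_e`` is a measure-specific chance term built from the marginal
distributions (``pi_i = (p_i+ + p_+i) / 2`` denotes the averaged marginals,
``T_w`` the sum of all weights):

==================  ====================================================
cohen               p_e = sum_ij omega_ij p_i+ p_+j
scott               p_e = sum_ij omega_ij pi_i pi_j
krippendorff        as scott, but with the finite-sample correction
                    p_a' = p_a (1 - 1/(2N)) + 1/(2N) applied to p_a
gwet_ac2            p_e = T_w / (q (q - 1)) * sum_i pi_i (1 - pi_i)
brennan_prediger    p_e = T_w / q^2
==================  ====================================================

Cohen's kappa conditions on both raters' observed margins; Scott's pi and
Krippendorff's alpha assume a common marginal distribution; Gwet's AC2 and
Brennan-Prediger's S use chance terms that do not reward marginal
concentration, which makes them less sensitive to marginal heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyTableError,
    InsufficientDataError,
    InvalidDimensionError,
    UndefinedCoefficientError,
    UndefinedCVError,
)
from .weights import SCHEMES, WeightMatrix, build_weight_matrix

#: The closed set of supported agreement measures.
MEASURES = ("cohen", "scott", "gwet_ac2", "brennan_prediger", "krippendorff")

#: All measure x scheme combinations of the study design (5 x 5 = 25).
ALL_PAIRS = tuple((m, s) for m in MEASURES for s in SCHEMES)


@dataclass(frozen=True)
class ContingencyTable:
    """A q x q table of rating counts; rows are rater A, columns rater B."""

    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidDimensionError(f"counts must be square, got shape {c.shape}")
        if c.shape[0] < 2:
            raise InvalidDimensionError("contingency tables require q >= 2")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(c != np.floor(c)):
            raise ValueError("counts must be integers")
        c = np.ascontiguousarray(c, dtype=np.int64)
        c.flags.writeable = False
        object.__setattr__(self, "counts", c)

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Total number of rated subjects, N."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ProbabilityTable:
    """A q x q joint probability table summing to 1."""

    p: np.ndarray = field(repr=False)

    _SUM_TOL = 1e-8

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise InvalidDimensionError(f"p must be square, got shape {p.shape}")
        if p.shape[0] < 2:
            raise InvalidDimensionError("probability tables require q >= 2")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValueError(f"probabilities sum to {total!r}, expected 1")
        p = np.clip(p, 0.0, None)
        p = np.ascontiguousarray(p / p.sum())
        p.flags.writeable = False
        object.__setattr__(self, "p", p)

    @property
    def q(self) -> int:
        return self.p.shape[0]

    @property
    def row_margins(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.p.sum(axis=0)


@dataclass(frozen=True)
class CoefficientValue:
    """One agreement coefficient with its observed and chance components."""

    value: float
    measure: str
    scheme: str
    pa: float
    pe: float

    def round3(self) -> float:
        """The value rounded half-even to 3 decimals, as reported in output."""
        return round(self.value, 3)


def normalize(table: ContingencyTable) -> ProbabilityTable:
    """Convert a counts table to its joint probability table p_ij = m_ij / N."""
    n = table.n
    if n == 0:
        raise EmptyTableError("cannot normalize a table with zero total count")
    return ProbabilityTable(table.counts / n)


def observed_agreement(p: ProbabilityTable, w: WeightMatrix) -> float:
    """Weighted proportion of observed agreement, p_a = sum omega_ij p_ij."""
    if p.q != w.q:
        raise InvalidDimensionError(f"table has q={p.q} but weights have q={w.q}")
    return float((w.omega * p.p).sum())


def averaged_marginals(p: ProbabilityTable) -> np.ndarray:
    """Per-category average of the two raters' margins, pi_i = (p_i+ + p_+i)/2."""
    return (p.row_margins + p.col_margins) / 2.0


def expected_agreement(p: ProbabilityTable, w: WeightMatrix, measure: str) -> float:
    """Measure-specific weighted chance agreement p_e (see module docstring)."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if p.q != w.q:
        raise InvalidDimensionError(f"table has q={p.q} but weights have q={w.q}")
    q = p.q
    if measure == "cohen":
        return float((w.omega * np.outer(p.row_margins, p.col_margins)).sum())
    if measure in ("scott", "krippendorff"):
        pi = averaged_marginals(p)
        return float((w.omega * np.outer(pi, pi)).sum())
    if measure == "gwet_ac2":
        pi = averaged_marginals(p)
        return float(w.total / (q * (q - 1)) * (pi * (1.0 - pi)).sum())
    # brennan_prediger
    return float(w.total / q**2)


def coefficient(
    table: ContingencyTable | ProbabilityTable,
    measure: str,
    scheme: str,
    n: int | None = None,
) -> CoefficientValue:
    """Compute one chance-corrected agreement coefficient.

    Parameters
    ----------
    table : ContingencyTable or ProbabilityTable
        The agreement table.  A counts table is normalized internally and
        supplies the subject count N for Krippendorff's correction.
    measure, scheme : str
        Members of :data:`MEASURES` and :data:`~greykappa.weights.SCHEMES`.
    n : int, optional
        Subject count used by Krippendorff's finite-sample correction when a
        probability table is supplied.  Without it the asymptotic value
        (identical to Scott's pi) is returned.

    Returns
    -------
    CoefficientValue
        With ``value = (p_a - p_e) / (1 - p_e)``; exactly 1 when p_a = 1.
    """
    if isinstance(table, ContingencyTable):
        n = table.n if n is None else n
        p = normalize(table)
    else:
        p = table
    w = build_weight_matrix(scheme, p.q)
    pa = observed_agreement(p, w)
    pe = expected_agreement(p, w, measure)
    pa_used = pa
    if measure == "krippendorff" and n is not None:
        eps_n = 1.0 / (2.0 * n)  # 1 / (N * m) with m = 2 raters
        pa_used = pa * (1.0 - eps_n) + eps_n
    if pa_used >= 1.0 - 1e-15:
        value = 1.0
    elif pe >= 1.0 - 1e-15:
        raise UndefinedCoefficientError(
            f"chance agreement p_e = {pe} leaves {measure} undefined"
        )
    else:
        value = (pa_used - pe) / (1.0 - pe)
    return CoefficientValue(value=value, measure=measure, scheme=scheme, pa=pa, pe=pe)


def coefficient_grid(
    table: ContingencyTable | ProbabilityTable, n: int | None = None
) -> dict[tuple[str, str], CoefficientValue]:
    """All 25 measure x scheme coefficients for one table."""
    return {(m, s): coefficient(table, m, s, n=n) for m, s in ALL_PAIRS}


def cv_across_tables(values) -> float:
    """Coefficient of variation of a set of coefficient values.

    Sample standard deviation (divisor n - 1) divided by the arithmetic mean;
    used as the cross-scenario sensitivity summary of a measure/weight pair.
    """
    vals = np.asarray(
        [v.value if isinstance(v, CoefficientValue) else float(v) for v in values],
        dtype=float,
    )
    if vals.size < 2:
        raise InsufficientDataError("CV requires at least 2 values")
    mean = vals.mean()
    if mean == 0.0:
        raise UndefinedCVError("CV undefined for zero mean")
    return float(vals.std(ddof=1) / mean)
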