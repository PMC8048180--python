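import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from greykappa.errors import (
    EmptyTableError,
    InsufficientDataError,
    UndefinedCVError,
)
from greykappa.measures import (
    ALL_PAIRS,
    MEASURES,
    ContingencyTable,
    ProbabilityTable,
    averaged_marginals,
    coefficient,
    cv_across_tables,
    expected_agreement,
    normalize,
    observed_agreement,
)
from greykappa.weights import SCHEMES, build_weight_matrix

from _oracles import naive_coefficient

count_tables = arrays(
    np.int64, (3, 3), elements=st.integers(min_value=0, max_value=30)
).filter(lambda m: m.sum() >= 2)


def test_normalize_divides_by_total(original):
    p = normalize(original)
    assert p.p[0, 0] == pytest.approx(21 / 85)
    assert p.p.sum() == pytest.approx(1.0, abs=1e-12)


def test_normalize_point_mass():
    t = ContingencyTable(np.array([[7, 0], [0, 0]]))
    p = normalize(t)
    assert p.p[0, 0] == 1.0 and p.p.sum() == 1.0


def test_normalize_empty_table_errors():
    with pytest.raises(EmptyTableError):
        normalize(ContingencyTable(np.zeros((2, 2), dtype=int)))


def test_observed_agreement_worked_example(original_p):
    w_un = build_weight_matrix("unweighted", 4)
    assert observed_agreement(original_p, w_un) == pytest.approx(54 / 85)
    w_lin = build_weight_matrix("linear", 4)
    # distance-class counts read off the table: 54 at d=0, 28 at d=1, 3 at d=2
    expected = (54 + 28 * (2 / 3) + 3 * (1 / 3)) / 85
    assert observed_agreement(original_p, w_lin) == pytest.approx(expected)


def test_observed_agreement_perfect_diagonal():
    p = ProbabilityTable(np.diag([0.2, 0.5, 0.3]))
    for scheme in SCHEMES:
        assert observed_agreement(p, build_weight_matrix(scheme, 3)) == pytest.approx(1.0)


def test_averaged_marginals_worked_example(original_p):
    pi = averaged_marginals(original_p)
    assert pi * 85 == pytest.approx([30.5, 30.0, 22.5, 2.0])
    assert pi.sum() == pytest.approx(1.0)


@given(count_tables)
def test_averaged_marginals_sum_to_one(m):
    pi = averaged_marginals(normalize(ContingencyTable(m)))
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "measure, expected",
    [
        ("cohen", 2227 / 7225),
        ("scott", 2340.5 / 7225),
        ("gwet_ac2", (1 / 3) * (1 - 2340.5 / 7225)),
        ("brennan_prediger", 0.25),
    ],
)
def test_expected_agreement_unweighted_worked_example(original_p, measure, expected):
    w = build_weight_matrix("unweighted", 4)
    assert expected_agreement(original_p, w, measure) == pytest.approx(expected, abs=1e-12)


def test_coefficient_counts_equals_probability_path(original):
    """Counts table and its normalized table agree except for Krippendorff's
    finite-sample correction, which needs N."""
    p = normalize(original)
    for measure, scheme in ALL_PAIRS:
        from_counts = coefficient(original, measure, scheme).value
        from_probs = coefficient(p, measure, scheme).value
        if measure == "krippendorff":
            assert coefficient(p, measure, scheme, n=original.n).value == pytest.approx(
                from_counts, abs=1e-12
            )
        else:
            assert from_probs == pytest.approx(from_counts, abs=1e-12)


def test_perfect_diagonal_gives_one_everywhere():
    t = ContingencyTable(np.diag([5, 9, 2, 4]))
    for measure, scheme in ALL_PAIRS:
        assert coefficient(t, measure, scheme).value == 1.0


def test_independence_table_gives_zero_cohen():
    row = np.array([0.5, 0.3, 0.2])
    col = np.array([0.2, 0.3, 0.5])
    p = ProbabilityTable(np.outer(row, col))
    for scheme in SCHEMES:
        assert coefficient(p, "cohen", scheme).value == pytest.approx(0.0, abs=1e-12)


def test_cohen_weighting_double_inequality(original):
    """On the worked example: unweighted < linear < quadratic Cohen's kappa."""
    vals = [coefficient(original, "cohen", s).value for s in ("unweighted", "linear", "quadratic")]
    assert vals[0] < vals[1] < vals[2]


@given(count_tables)
def test_krippendorff_dominates_scott(m):
    """alpha >= pi on any counts table (the finite-sample correction only
    raises observed agreement), and the gap vanishes as N grows."""
    t = ContingencyTable(m)
    alpha = coefficient(t, "krippendorff", "linear").value
    pi = coefficient(t, "scott", "linear").value
    assert alpha >= pi - 1e-12
    big = ContingencyTable(m * 1000)
    assert coefficient(big, "krippendorff", "linear").value - coefficient(
        big, "scott", "linear"
    ).value == pytest.approx(0.0, abs=1e-3)


def test_against_naive_oracle(rng):
    """All 25 coefficients on random tables match the brute-force sums."""
    for _ in range(20):
        q = int(rng.integers(3, 5))
        m = rng.integers(0, 20, size=(q, q))
        m[0, 0] += 1  # never empty
        t = ContingencyTable(m)
        for measure, scheme in ALL_PAIRS:
            assert coefficient(t, measure, scheme).value == pytest.approx(
                naive_coefficient(m, measure, scheme), abs=1e-10
            )


@pytest.mark.parametrize(
    "values, expected",
    [
        ((0.850, 0.840, 0.869, 0.863), 0.015),
        ((0.812, 0.774, 0.830, 0.821), 0.030),
    ],
)
def test_cv_published_sensitivity_rows(values, expected):
    """CV (sample sd / mean) reproduces the published quadratic-weight rows."""
    assert round(cv_across_tables(values), 3) == expected


def test_cv_identical_values_is_zero():
    assert cv_across_tables([0.4, 0.4, 0.4]) == pytest.approx(0.0, abs=1e-14)


def test_cv_error_cases():
    with pytest.raises(InsufficientDataError):
        cv_across_tables([0.5])
    with pytest.raises(UndefinedCVError):
        cv_across_tables([0.5, -0.5])


def test_rounding_is_half_even(original):
    v = coefficient(original, "cohen", "unweighted")
    assert v.round3() == 0.473


@pytest.mark.parametrize("measure", MEASURES)
def test_coefficient_within_bounds(original, measure):
    for scheme in SCHEMES:
        v = coefficient(original, measure, scheme).value
        assert -1.0 <= v <= 1.0
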