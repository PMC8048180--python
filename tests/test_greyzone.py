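import numpy as np
import pytest

from greykappa.errors import UnreachableTargetError
from greykappa.greyzone import (
    apply_shift,
    cp_diagonal_step,
    cp_search,
    default_grey_category,
    matching_criterion,
    pa_lower_bound,
    pa_search,
    perfect_table,
)
from greykappa.measures import ProbabilityTable
from greykappa.tablegen import balanced_cutoffs, joint_probabilities, true_coefficient

BALANCED3 = perfect_table(balanced_cutoffs(3))


class TestApplyShift:
    def test_zero_rates_is_identity(self):
        p = apply_shift(BALANCED3, 2, 0.0, 0.0)
        assert np.array_equal(p.p, BALANCED3.p)

    def test_full_migration_on_perfect_table(self):
        """Moving both neighbour diagonal cells entirely into column 2."""
        p = apply_shift(BALANCED3, 2, 1.0, 1.0).p
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 1] = expected[2, 1] = 1 / 3
        assert p == pytest.approx(expected)

    def test_conservation_and_row_margins(self):
        cuts = balanced_cutoffs(4)
        base = joint_probabilities(0.6, cuts, cuts)
        shifted = apply_shift(base, 2, 0.4, 0.25)
        assert shifted.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert shifted.row_margins == pytest.approx(base.row_margins, abs=1e-15)

    def test_grey_column_margin_inflates(self):
        cuts = balanced_cutoffs(4)
        base = joint_probabilities(0.6, cuts, cuts)
        g = default_grey_category(4)
        shifted = apply_shift(base, g, 0.2, 0.2)
        assert shifted.col_margins[g - 1] > base.col_margins[g - 1]

    def test_extended_moves_off_diagonal_sources(self):
        cuts = balanced_cutoffs(4)
        base = joint_probabilities(0.6, cuts, cuts)
        basic = apply_shift(base, 2, 0.3, 0.3)
        ext = apply_shift(base, 2, 0.3, 0.3, extended=True)
        # extended drains (1,3) and (3,1) as well
        assert ext.p[0, 2] < basic.p[0, 2]
        assert ext.p[2, 0] < basic.p[2, 0]
        assert ext.col_margins[1] > basic.col_margins[1]

    def test_boundary_categories(self):
        p1 = apply_shift(BALANCED3, 1, 0.5, 0.5)  # no left neighbour
        assert p1.p[1, 0] == pytest.approx(1 / 6)
        pq = apply_shift(BALANCED3, 3, 0.5, 0.5)  # no right neighbour
        assert pq.p[1, 2] == pytest.approx(1 / 6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            apply_shift(BALANCED3, 0, 0.1, 0.1)
        with pytest.raises(ValueError):
            apply_shift(BALANCED3, 2, 1.5, 0.1)


class TestPABound:
    def test_published_6x6_limit(self):
        """Balanced 6x6, grey category 3, Cohen unweighted: floor is 0.6."""
        assert pa_lower_bound(6, 3) == pytest.approx(0.6, abs=1e-12)

    def test_3x3_floor_is_zero(self):
        assert pa_lower_bound(3, 2) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_no_move_is_one(self):
        start = perfect_table(balanced_cutoffs(4))
        assert true_coefficient(start, "cohen", "unweighted").value == 1.0


class TestPASearch:
    def test_target_one_needs_no_migration(self):
        res = pa_search(1.0, 4)
        assert res.converged and res.spec.lambda1 == 0.0 and res.iterations == 0

    def test_unreachable_target_raises(self):
        with pytest.raises(UnreachableTargetError):
            pa_search(0.5, 6, g=3)

    def test_reaches_target_and_verifies_independently(self):
        res = pa_search(0.8, 4, g=2, epsilon=0.01)
        assert res.converged
        recheck = matching_criterion(res.p_hat, 0.8, (("cohen", "unweighted"),))
        assert recheck <= 0.01
        assert 0.0 < res.spec.lambda1 < 1.0

    def test_achieved_kappa_monotone_in_lambda(self):
        start = perfect_table(balanced_cutoffs(4))
        values = [
            true_coefficient(apply_shift(start, 2, lam, lam), "cohen", "unweighted").value
            for lam in np.linspace(0.0, 1.0, 11)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestCPDiagonalStep:
    def test_zero_gamma_is_identity(self):
        p = cp_diagonal_step(BALANCED3, 1, 0.0)
        assert np.array_equal(p.p, BALANCED3.p)

    def test_downward_step_values(self):
        p = cp_diagonal_step(BALANCED3, 1, 0.01, direction=1).p
        assert p[0, 0] == pytest.approx((1 / 3) * 0.99)
        assert p[1, 1] == pytest.approx(1 / 3 + (1 / 3) * 0.01)

    def test_repeated_application_conserves_mass(self):
        p = BALANCED3
        for _ in range(100):
            p = cp_diagonal_step(p, 2, 0.01, direction=1)
        assert p.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            cp_diagonal_step(BALANCED3, 3, 0.01)


class TestCPSearch:
    def test_lambda_zero_converges_immediately(self):
        cuts = balanced_cutoffs(4)
        p = joint_probabilities(0.6, cuts, cuts)
        res = cp_search(p, lambdas=(0.0,))
        assert res.converged and res.iterations == 1
        assert np.array_equal(res.p_hat.p, p.p)

    def test_self_consistency_on_medium_agreement(self):
        """Matched-truth grey zone: independent recomputation satisfies the
        mean-absolute-difference criterion, and the grey column inflates."""
        cuts = balanced_cutoffs(4)
        p = joint_probabilities(0.6, cuts, cuts)
        res = cp_search(p, epsilon=0.01)
        assert res.converged
        assert res.spec.lambda1 > 0.0
        recheck = matching_criterion(res.p_hat, res.kappa_ref)
        assert recheck <= 0.01
        g = res.spec.g
        assert res.p_hat.col_margins[g - 1] > p.col_margins[g - 1]

    def test_scalar_target_override(self):
        cuts = balanced_cutoffs(4)
        p = joint_probabilities(0.6, cuts, cuts)
        kappa = true_coefficient(p, "cohen", "unweighted").value
        res = cp_search(p, target=kappa, pairs=(("cohen", "unweighted"),))
        assert res.converged
        achieved = true_coefficient(res.p_hat, "cohen", "unweighted").value
        assert abs(achieved - kappa) <= 0.01

    def test_nonconvergence_is_flagged_not_silent(self):
        cuts = balanced_cutoffs(3)
        p = joint_probabilities(0.9, cuts, cuts)
        # an impossible tolerance with a single large rate cannot converge
        res = cp_search(p, epsilon=1e-6, lambdas=(0.3,), max_evals=200)
        assert not res.converged
        assert res.achieved > 1e-6
        assert res.p_hat is not None
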