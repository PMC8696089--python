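"""Exact and relaxed log-ratio transforms: worked values and CoDa invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import codaratio as cr
from codaratio.data import DegeneratePartitionError


def positive_matrices(max_n=6, max_p=8):
    shapes = st.tuples(st.integers(1, max_n), st.integers(2, max_p))
    return shapes.flatmap(
        lambda s: hnp.arrays(
            np.float64, s,
            elements=st.floats(0.05, 50.0, allow_nan=False, allow_infinity=False),
        )
    )


def partition_for(p, rng_seed):
    """Deterministic valid partition of {0..p-1} derived from a seed."""
    rng = np.random.default_rng(rng_seed)
    labels = rng.integers(-1, 2, p)
    labels[0], labels[1] = 1, -1  # guarantee validity
    return cr.BalancePartition(
        tuple(np.flatnonzero(labels == 1)), tuple(np.flatnonzero(labels == -1))
    )


class TestSoftAssign:
    def test_known_values(self):
        np.testing.assert_allclose(cr.soft_assign([0.0, 0.0, 0.0]), [0, 0, 0])
        np.testing.assert_allclose(cr.soft_assign([np.log(3.0)]), [0.5], rtol=1e-12)
        assert abs(cr.soft_assign([50.0])[0] - 1.0) < 1e-9

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            cr.soft_assign([np.inf, 0.0])

    @given(hnp.arrays(np.float64, 5, elements=st.floats(-30, 30)))
    def test_range_and_monotonicity(self, w):
        wt = cr.soft_assign(w)
        assert np.all(np.abs(wt) < 1.0)
        order = np.argsort(w)
        assert np.all(np.diff(wt[order]) >= 0)

    def test_parts_decomposition(self, rng):
        wt = cr.soft_assign(rng.normal(0, 2, 50))
        pos, neg = cr.soft_parts(wt)
        np.testing.assert_allclose(pos - neg, wt)
        assert np.all(pos * neg == 0)

    def test_inverse(self, rng):
        w = rng.normal(0, 1.5, 20)
        np.testing.assert_allclose(cr.weights_from_soft(cr.soft_assign(w)), w, atol=1e-10)


class TestExactForms:
    def test_balance_worked_examples(self):
        x = cr.CompositionMatrix([[1, 1, 1, 1]])
        part = cr.BalancePartition((0, 2), (1,))
        np.testing.assert_allclose(cr.exact_balance(x, part), [0.0])

        x = cr.CompositionMatrix([[np.e**2, 1.0]])
        np.testing.assert_allclose(
            cr.exact_balance(x, cr.BalancePartition((0,), (1,))), [2.0]
        )

        x = cr.CompositionMatrix([[4.0, 9.0, 2.0]])
        np.testing.assert_allclose(
            cr.exact_balance(x, cr.BalancePartition((0, 1), (2,))), [np.log(3.0)]
        )

    def test_amalgamation_worked_examples(self):
        x = cr.CompositionMatrix([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(
            cr.exact_amalgamation(x, cr.BalancePartition((0, 1), (2,))), [0.0], atol=1e-15
        )
        x = cr.CompositionMatrix([[2.0, 8.0]])
        np.testing.assert_allclose(
            cr.exact_amalgamation(x, cr.BalancePartition((0,), (1,))), [-np.log(4.0)]
        )

    @pytest.mark.parametrize("fn", [cr.exact_balance, cr.exact_amalgamation])
    def test_degenerate_and_overlapping_partitions(self, fn, small_x):
        with pytest.raises(DegeneratePartitionError):
            fn(small_x, cr.BalancePartition((0, 1), ()))
        with pytest.raises(ValueError):
            cr.BalancePartition((0, 1), (1, 2))

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    @given(x=positive_matrices(), seed=st.integers(0, 10))
    def test_scale_invariance(self, ratio_type, x, seed):
        part = partition_for(x.shape[1], seed)
        c = np.random.default_rng(seed).uniform(0.1, 10.0, x.shape[0])
        a = cr.exact_ratio(cr.CompositionMatrix(x), part, ratio_type)
        b = cr.exact_ratio(cr.CompositionMatrix(x * c[:, None]), part, ratio_type)
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    @given(x=positive_matrices(), seed=st.integers(0, 10))
    def test_antisymmetry(self, ratio_type, x, seed):
        part = partition_for(x.shape[1], seed)
        xm = cr.CompositionMatrix(x)
        np.testing.assert_allclose(
            cr.exact_ratio(xm, part, ratio_type),
            -cr.exact_ratio(xm, part.swapped(), ratio_type),
            atol=1e-10,
        )

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    def test_subcompositional_locality(self, ratio_type, rng):
        """Output depends only on the columns inside J+ and J-."""
        x = rng.uniform(0.2, 5.0, (10, 8))
        part = cr.BalancePartition((0, 3), (5,))
        before = cr.exact_ratio(cr.CompositionMatrix(x), part, ratio_type)
        x2 = x.copy()
        x2[:, [1, 2, 4, 6, 7]] = rng.uniform(0.2, 5.0, (10, 5))
        after = cr.exact_ratio(cr.CompositionMatrix(x2), part, ratio_type)
        np.testing.assert_allclose(before, after)

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    def test_permutation_equivariance(self, ratio_type, rng):
        x = rng.uniform(0.2, 5.0, (12, 7))
        part = cr.BalancePartition((0, 2), (4, 6))
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        permuted_part = cr.BalancePartition(
            tuple(inv[list(part.j_plus)]), tuple(inv[list(part.j_minus)])
        )
        np.testing.assert_allclose(
            cr.exact_ratio(cr.CompositionMatrix(x), part, ratio_type),
            cr.exact_ratio(cr.CompositionMatrix(x[:, perm]), permuted_part, ratio_type),
        )


class TestRelaxedForms:
    def test_relaxed_balance_direct_evaluation(self):
        # p=2, x=(e,1), w_tilde=(0.5,-0.25): (0.5*1)/0.5 - (0.25*0)/0.25 = 1
        x = cr.CompositionMatrix([[np.e, 1.0]])
        w = cr.weights_from_soft([0.5, -0.25])
        np.testing.assert_allclose(cr.relaxed_balance(x, w), [1.0], rtol=1e-12)

    def test_relaxed_balance_unit_rows_are_zero(self, rng):
        x = cr.CompositionMatrix(np.ones((4, 6)))
        w = rng.normal(0, 3, 6)
        np.testing.assert_allclose(cr.relaxed_balance(x, w), np.zeros(4), atol=1e-12)

    def test_relaxed_amalgamation_weights_cancel(self):
        x = cr.CompositionMatrix([[2.0, 8.0]])
        w = cr.weights_from_soft([0.9, -0.9])
        np.testing.assert_allclose(
            cr.relaxed_amalgamation(x, w, eps=0.0), [-np.log(4.0)], rtol=1e-12
        )

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    @given(seed=st.integers(0, 30))
    def test_hard_assignment_limit(self, ratio_type, seed):
        """Saturated weights reproduce the exact forms."""
        rng = np.random.default_rng(seed)
        p = rng.integers(3, 15)
        x = cr.CompositionMatrix(rng.uniform(0.1, 20.0, (8, p)))
        part = partition_for(p, seed)
        w = cr.hard_weights(part, p)
        np.testing.assert_allclose(
            cr.relaxed_ratio(x, w, ratio_type),
            cr.exact_ratio(x, part, ratio_type),
            atol=1e-6,
        )

    def test_relaxed_scale_invariance_eps0(self, rng):
        x = rng.uniform(0.2, 5.0, (10, 6))
        w = rng.normal(0, 1, 6)
        w[0], w[1] = 2.0, -2.0  # both sides populated
        c = rng.uniform(0.1, 10.0, 10)
        a = cr.relaxed_balance(cr.CompositionMatrix(x), w, eps=0.0)
        b = cr.relaxed_balance(cr.CompositionMatrix(x * c[:, None]), w, eps=0.0)
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("ratio_type", ["balance", "amalgamation"])
    def test_negating_weights_negates_output(self, ratio_type, rng):
        x = cr.CompositionMatrix(rng.uniform(0.2, 5.0, (6, 5)))
        w = rng.normal(0, 2, 5)
        np.testing.assert_allclose(
            cr.relaxed_ratio(x, w, ratio_type),
            -cr.relaxed_ratio(x, -w, ratio_type),
            atol=1e-9,
        )
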