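"""Gaussian information estimators: worked examples, identities, errors."""

import itertools
import math

import numpy as np
import pytest

from hoinfo import (
    CorrelationMatrix,
    NotPositiveDefiniteError,
    Subset,
    co_information,
    description_complexity,
    dual_total_correlation,
    joint_entropy,
    mutual_info_pair,
    o_information,
    s_information,
    subset_matrix,
    total_correlation,
    tse_complexity,
)
from hoinfo.gaussian_info import LN_2PIE

from conftest import equicorrelated, random_correlation


def common_child_triad(r: float = 0.65) -> CorrelationMatrix:
    """Two independent parents, child correlated r with each (collider)."""
    vals = np.array([[1.0, 0.0, r], [0.0, 1.0, r], [r, r, 1.0]])
    return CorrelationMatrix(vals)


class TestJointEntropy:
    def test_univariate_standard_normal(self):
        assert joint_entropy(CorrelationMatrix([[1.0]])) == pytest.approx(
            0.5 * LN_2PIE, abs=1e-12
        )

    def test_independent_variables_add(self):
        assert joint_entropy(CorrelationMatrix(np.eye(2))) == pytest.approx(
            LN_2PIE, abs=1e-12
        )

    def test_correlated_pair(self):
        c = CorrelationMatrix([[1.0, 0.5], [0.5, 1.0]])
        assert joint_entropy(c) == pytest.approx(LN_2PIE + 0.5 * math.log(0.75), abs=1e-12)

    def test_rejects_indefinite(self):
        # strong inconsistent correlations: smallest eigenvalue well below 0
        vals = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(NotPositiveDefiniteError) as exc:
            CorrelationMatrix(vals)
        assert exc.value.min_eigenvalue < -0.1

    def test_exactly_singular_repaired_with_warning(self):
        # duplicated variable: eigenvalue at exactly zero is jitter-repairable
        with pytest.warns(RuntimeWarning, match="jitter"):
            c = CorrelationMatrix([[1.0, 1.0], [1.0, 1.0]])
        assert np.isfinite(joint_entropy(c))


class TestMutualInfoPair:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.0, 0.0), (0.5, -0.5 * math.log(0.75)), (-0.5, -0.5 * math.log(0.75))],
    )
    def test_closed_form(self, rho, expected):
        assert mutual_info_pair(rho) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_singular_rejected(self, rho):
        with pytest.raises(ValueError):
            mutual_info_pair(rho)


class TestTotalCorrelation:
    def test_identity_is_zero(self):
        for n in (2, 5, 9):
            assert total_correlation(CorrelationMatrix(np.eye(n))) == pytest.approx(0.0, abs=1e-12)

    def test_pair_equals_mutual_information(self):
        c = CorrelationMatrix([[1.0, 0.9], [0.9, 1.0]])
        assert total_correlation(c) == pytest.approx(mutual_info_pair(0.9), abs=1e-12)
        assert total_correlation(c) == pytest.approx(-0.5 * math.log(0.19), abs=1e-12)

    def test_matches_entropy_decomposition(self, rng):
        for n in (3, 5, 8):
            c = random_correlation(n, rng)
            marginals = n * 0.5 * LN_2PIE
            assert total_correlation(c) == pytest.approx(
                marginals - joint_entropy(c), abs=1e-10
            )


class TestDualTotalCorrelation:
    def test_identity_is_zero(self):
        assert dual_total_correlation(CorrelationMatrix(np.eye(4))) == pytest.approx(0.0, abs=1e-12)

    def test_pair_equals_mutual_information(self):
        c = CorrelationMatrix([[1.0, 0.5], [0.5, 1.0]])
        assert dual_total_correlation(c) == pytest.approx(mutual_info_pair(0.5), abs=1e-12)

    def test_matches_residual_entropy_definition(self, rng):
        # DTC = H(X) - sum_i H(Xi | X^-i), residual entropy via joint entropies
        for n in (3, 6):
            c = random_correlation(n, rng)
            h_full = joint_entropy(c)
            resid = 0.0
            for i in range(n):
                keep = [j for j in range(n) if j != i]
                resid += h_full - joint_entropy(c.values[np.ix_(keep, keep)])
            assert dual_total_correlation(c) == pytest.approx(h_full - resid, abs=1e-10)

    def test_nonnegative(self, rng):
        for n in (3, 4, 7):
            assert dual_total_correlation(random_correlation(n, rng)) >= -1e-10

    def test_requires_two_nodes(self):
        with pytest.raises(ValueError):
            dual_total_correlation(CorrelationMatrix([[1.0]]))


class TestOInformation:
    def test_identity_is_zero(self):
        assert o_information(CorrelationMatrix(np.eye(3))) == pytest.approx(0.0, abs=1e-12)

    def test_redundant_triple_positive(self):
        assert o_information(equicorrelated(3, 0.9)) > 0.1

    def test_common_child_negative(self):
        assert o_information(common_child_triad()) < -0.01

    def test_small_systems_warn_and_return_zero(self):
        with pytest.warns(RuntimeWarning):
            assert o_information(CorrelationMatrix([[1.0, 0.3], [0.3, 1.0]])) == 0.0

    def test_independent_node_append_invariance(self, rng):
        # a node uncorrelated with the rest changes none of TC, DTC, omega
        for n in (3, 5):
            c = random_correlation(n, rng)
            grown = np.eye(n + 1)
            grown[:n, :n] = c.values
            g = CorrelationMatrix(grown)
            assert total_correlation(g) == pytest.approx(total_correlation(c), abs=1e-10)
            assert dual_total_correlation(g) == pytest.approx(
                dual_total_correlation(c), abs=1e-10
            )
            assert o_information(g) == pytest.approx(o_information(c), abs=1e-10)

    def test_duplicated_node_increases_omega(self, rng):
        # appending a near-copy of a node injects pure redundancy
        for n in (3, 5):
            c = random_correlation(n, rng)
            eps = 1e-6
            grown = np.eye(n + 1)
            grown[:n, :n] = c.values
            grown[n, :n] = grown[:n, n] = c.values[0, :] * (1 - eps)
            grown[n, 0] = grown[0, n] = 1 - eps
            g = CorrelationMatrix(grown)
            assert o_information(g) > o_information(c)


class TestCoInformation:
    def test_identity_zero(self):
        assert co_information(CorrelationMatrix(np.eye(3))) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mat", [equicorrelated(3, 0.5), common_child_triad()])
    def test_equals_o_information_at_three_nodes(self, mat):
        assert co_information(mat) == pytest.approx(o_information(mat), abs=1e-10)

    def test_common_child_negative(self):
        assert co_information(common_child_triad()) < 0

    def test_requires_exactly_three(self):
        with pytest.raises(ValueError):
            co_information(CorrelationMatrix(np.eye(4)))


class TestDescriptionComplexity:
    def test_identity_zero(self):
        assert description_complexity(CorrelationMatrix(np.eye(5))) == pytest.approx(0.0, abs=1e-12)

    def test_equals_dtc_over_n(self, rng):
        for n in (2, 4, 9):
            c = random_correlation(n, rng)
            assert description_complexity(c) == pytest.approx(
                dual_total_correlation(c) / n, abs=1e-10
            )

    def test_pair_value(self):
        c = CorrelationMatrix([[1.0, 0.5], [0.5, 1.0]])
        assert description_complexity(c) == pytest.approx(mutual_info_pair(0.5) / 2, abs=1e-12)


class TestSInformation:
    def test_identity_zero(self):
        assert s_information(CorrelationMatrix(np.eye(4))) == pytest.approx(0.0, abs=1e-12)

    def test_pair_value(self):
        c = CorrelationMatrix([[1.0, 0.5], [0.5, 1.0]])
        assert s_information(c) == pytest.approx(2 * mutual_info_pair(0.5), abs=1e-12)

    def test_equals_sum_of_each_node_vs_rest(self, rng):
        # S(X) = sum_i I(Xi ; X^-i) with I from joint entropies
        c = random_correlation(5, rng)
        h_full = joint_entropy(c)
        total = 0.0
        for i in range(5):
            keep = [j for j in range(5) if j != i]
            total += 0.5 * LN_2PIE + joint_entropy(c.values[np.ix_(keep, keep)]) - h_full
        assert s_information(c) == pytest.approx(total, abs=1e-8)


def brute_force_tse(vals: np.ndarray) -> float:
    """Independent enumerator: entropy-based bipartition MI, scale by scale."""

    def H(idx):
        sub = vals[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sub)
        return 0.5 * (len(idx) * LN_2PIE + logdet)

    n = vals.shape[0]
    h_full = H(list(range(n)))
    total = 0.0
    for i in range(1, n // 2 + 1):
        mis = []
        for gamma in itertools.combinations(range(n), i):
            comp = [j for j in range(n) if j not in gamma]
            mis.append(H(list(gamma)) + H(comp) - h_full)
        w = 0.5 if (n % 2 == 0 and i == n // 2) else 1.0
        total += w * float(np.mean(mis))
    return total


class TestTSEComplexity:
    def test_identity_zero(self):
        assert tse_complexity(CorrelationMatrix(np.eye(6))) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_scale_total_correlation_form(self, rng):
        # bipartition-MI form vs the scale-wise TC-deficit form
        for n in (4, 5, 7):
            c = random_correlation(n, rng)
            tc_full = total_correlation(c)
            alt = 0.0
            for i in range(1, n + 1):
                tcs = [
                    total_correlation(c.values[np.ix_(g, g)]) if i > 1 else 0.0
                    for g in itertools.combinations(range(n), i)
                ]
                alt += i / n * tc_full - float(np.mean(tcs))
            assert tse_complexity(c, mode="exact") == pytest.approx(alt, abs=1e-8)

    def test_matches_independent_brute_force(self, rng):
        for n in (3, 4, 6, 8):
            c = random_correlation(n, rng)
            assert tse_complexity(c, mode="exact") == pytest.approx(
                brute_force_tse(c.values), abs=1e-8
            )

    def test_sampled_mode_approximates_exact(self, rng):
        c = random_correlation(8, rng)
        exact = tse_complexity(c, mode="exact")
        approx = tse_complexity(c, mode="sampled", samples_per_scale=3000, seed=1)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_exact_cap_enforced(self, rng):
        c = random_correlation(5, rng)
        with pytest.raises(ValueError, match="sampled"):
            tse_complexity(c, mode="exact", exact_cap=4)


class TestSubsetMatrix:
    def test_full_and_singleton(self, rng):
        c = random_correlation(4, rng)
        full = subset_matrix(c, Subset(range(4)))
        assert np.array_equal(full.values, c.values)
        single = subset_matrix(c, Subset([2]))
        assert single.values.shape == (1, 1) and single.values[0, 0] == 1.0
        assert single.node_ids == (c.node_ids[2],)

    def test_pair_extraction(self):
        vals = np.eye(3)
        vals[0, 2] = vals[2, 0] = 0.4
        c = CorrelationMatrix(vals)
        sub = subset_matrix(c, Subset([0, 2]))
        assert sub.values[0, 1] == pytest.approx(0.4)

    def test_out_of_range(self, rng):
        with pytest.raises(IndexError):
            subset_matrix(random_correlation(3, rng), Subset([0, 5]))


class TestCorrelationMatrixValidation:
    def test_rejects_asymmetric(self):
        vals = np.eye(3)
        vals[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationMatrix(vals)

    def test_rejects_bad_diagonal(self):
        vals = np.eye(3) * 1.1
        with pytest.raises(ValueError, match="diagonal"):
            CorrelationMatrix(vals)

    def test_near_singular_jitter_warning(self):
        eps = 1e-11
        vals = np.array([[1.0, 1.0 - eps], [1.0 - eps, 1.0]])
        with pytest.warns(RuntimeWarning, match="jitter"):
            c = CorrelationMatrix(vals)
        assert np.isfinite(total_correlation(c))
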