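"""Conditional effect estimation: linear-transform arithmetic, covariance
propagation against a generic matrix oracle, and the K-party generalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duogwas.conditional import (
    DUO_INVERSE,
    ConditionalResult,
    RelatednessDesign,
    conditional_covariance,
    conditional_estimates,
    kparty_conditional,
    two_sided_logp,
)

L = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])


@pytest.mark.parametrize(
    "b_f, b_m, expected",
    [
        (0.12, 0.06, (0.12, 0.0)),  # purely fetal locus: b_m = b_f/2
        (0.0, 0.0, (0.0, 0.0)),
        (0.05, 0.10, (0.0, 0.1)),  # purely maternal locus
    ],
)
def test_conditional_estimates_examples(b_f, b_m, expected):
    bf_hat, bm_hat = conditional_estimates(b_f, b_m)
    assert bf_hat == pytest.approx(expected[0], abs=1e-15)
    assert bm_hat == pytest.approx(expected[1], abs=1e-15)


def test_zero_coupling_conditional_correlation_is_minus_point_eight():
    v = 9e-4
    var_f, var_m, cov_fm = conditional_covariance(v, v, 0.0)
    assert var_f == pytest.approx(20 * v / 9)
    assert cov_fm / np.sqrt(var_f * var_m) == pytest.approx(-0.8, abs=1e-14)


def test_full_overlap_stress_variance():
    v = 9e-4
    var_f, _, _ = conditional_covariance(v, v, v / 2)
    assert var_f == pytest.approx(12 * v / 9)


def test_conditional_covariance_matches_matrix_oracle():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        se = rng.uniform(0.01, 0.1, size=2)
        r = rng.uniform(-0.9, 0.9)
        V = np.array([[se[0] ** 2, r * se[0] * se[1]], [r * se[0] * se[1], se[1] ** 2]])
        var_f, var_m, cov_fm = conditional_covariance(V[0, 0], V[1, 1], V[0, 1])
        oracle = L @ V @ L.T
        np.testing.assert_allclose([var_f, cov_fm, var_m],
                                   [oracle[0, 0], oracle[0, 1], oracle[1, 1]],
                                   rtol=1e-12)


def test_specific_covariance_entries_against_oracle():
    V = np.array([[9e-4, 2e-4], [2e-4, 1.6e-3]])
    var_f, var_m, cov_fm = conditional_covariance(9e-4, 1.6e-3, 2e-4)
    oracle = L @ V @ L.T
    assert var_f == pytest.approx(oracle[0, 0], rel=1e-12)
    assert var_m == pytest.approx(oracle[1, 1], rel=1e-12)
    assert cov_fm == pytest.approx(oracle[0, 1], rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(beta_f=st.floats(-0.1, 0.1), beta_m=st.floats(-0.1, 0.1))
def test_roundtrip_through_relatedness(beta_f, beta_m):
    """E[b] = A beta, and the conditional transform recovers beta exactly."""
    A = RelatednessDesign.duo().A
    b = A @ np.array([beta_f, beta_m])
    bf_hat, bm_hat = conditional_estimates(b[0], b[1])
    assert bf_hat == pytest.approx(beta_f, abs=1e-12)
    assert bm_hat == pytest.approx(beta_m, abs=1e-12)


def test_extreme_z_logp_matches_r_oracle():
    # R: pnorm(40, lower.tail=FALSE, log.p=TRUE) + log(2)
    assert two_sided_logp(40.0) == pytest.approx(-803.91529483319391, rel=1e-12)
    assert np.isfinite(two_sided_logp(300.0))


def test_result_object_consistency(rng):
    b_f, b_m = rng.normal(0, 0.02, 50), rng.normal(0, 0.02, 50)
    res = ConditionalResult.from_unconditional(b_f, b_m, 4e-4, 4e-4, 1e-4)
    np.testing.assert_allclose(res.p_f, np.exp(res.logp_f), rtol=1e-10)
    assert not res.flagged().any()
    assert np.all(np.abs(res.cov_fm) < res.se_f * res.se_m)


class TestKParty:
    def test_duo_inverse_matches_closed_form(self):
        np.testing.assert_allclose(np.linalg.inv(RelatednessDesign.duo().A), DUO_INVERSE,
                                   rtol=1e-14)

    def test_k2_reduces_to_duo_formulas(self):
        V = np.array([[9e-4, 2e-4], [2e-4, 1.6e-3]])
        b = np.array([0.05, 0.02])
        beta_hat, Sigma = kparty_conditional(b, V, RelatednessDesign.duo())
        np.testing.assert_allclose(beta_hat, conditional_estimates(b[0], b[1]), rtol=1e-14)
        var_f, var_m, cov_fm = conditional_covariance(V[0, 0], V[1, 1], V[0, 1])
        np.testing.assert_allclose(Sigma, [[var_f, cov_fm], [cov_fm, var_m]], rtol=1e-14)

    def test_trio_exact_inversion_roundtrip(self):
        design = RelatednessDesign.trio()
        beta = np.array([0.03, 0.02, 0.0])
        b = design.A @ beta
        beta_hat, _ = kparty_conditional(b, np.eye(3) * 1e-4, design)
        np.testing.assert_allclose(beta_hat, beta, atol=1e-14)

    def test_trio_covariance_against_monte_carlo(self, rng):
        """Sigma = A^-1 V A^-T agrees with brute-force propagation of
        multivariate-normal draws."""
        design = RelatednessDesign.trio()
        Q = rng.normal(size=(3, 3))
        V = Q @ Q.T * 1e-4 + np.eye(3) * 1e-4
        n = 200_000
        draws = rng.multivariate_normal(np.zeros(3), V, size=n)
        Ainv = np.linalg.inv(design.A)
        prop = draws @ Ainv.T
        emp = np.cov(prop.T)
        _, Sigma = kparty_conditional(np.zeros(3), V, design)
        # element-wise MC standard error of a covariance is O(Sigma_ii/sqrt(n))
        scale = np.sqrt(np.outer(np.diag(Sigma), np.diag(Sigma)))
        assert np.all(np.abs(emp - Sigma) < 3 * 2 * scale / np.sqrt(n))

    def test_invalid_relatedness_rejected(self):
        with pytest.raises(ValueError):
            RelatednessDesign(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD
        with pytest.raises(ValueError):
            RelatednessDesign(np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
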