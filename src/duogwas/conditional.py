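"""Conditional direct-fetal and indirect-maternal effect estimation.

A GWAS of own phenotype on own genotype (the "fetal" scan) and a GWAS of
offspring phenotype on maternal genotype (the "maternal" scan) each yield an
unconditional regression coefficient that confounds the direct and indirect
effect, because maternal and offspring genotypes are correlated by 0.5 under
random mating.  Writing the expected unconditional coefficients as
``E[b] = A @ beta`` with the relatedness matrix ``A = [[1, 0.5], [0.5, 1]]``,
the conditional (unbiased) estimates are obtained by inverting ``A``:

    beta_f_hat = (4/3) b_f - (2/3) b_m
    beta_m_hat = (4/3) b_m - (2/3) b_f

with sampling covariance propagated through the same linear map.  The duo
case is provided explicitly (vectorised over variants); ``kparty_conditional``
generalises to K genotyped relatives (e.g. mother, father, child) via an
arbitrary positive-definite relatedness matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConditionalResult",
    "RelatednessDesign",
    "conditional_estimates",
    "conditional_covariance",
    "conditional_tests",
    "two_sided_p",
    "two_sided_logp",
    "kparty_conditional",
]

#: inverse of the duo relatedness matrix [[1, .5], [.5, 1]]
DUO_INVERSE = np.array([[4.0 / 3.0, -2.0 / 3.0], [-2.0 / 3.0, 4.0 / 3.0]])


def conditional_estimates(b_f, b_m):
    """Unbiased conditional effects from unconditional duo coefficients.

    Parameters
    ----------
    b_f, b_m
        Coefficients (scalar or array) from the fetal scan (own phenotype on
        own genotype) and the maternal scan (offspring phenotype on maternal
        genotype), oriented to the same effect allele.

    Returns
    -------
    (beta_f_hat, beta_m_hat)
        ``(4/3) b_f - (2/3) b_m`` and ``(4/3) b_m - (2/3) b_f``.
    """
    b_f = np.asarray(b_f, dtype=float)
    b_m = np.asarray(b_m, dtype=float)
    return (4.0 * b_f - 2.0 * b_m) / 3.0, (4.0 * b_m - 2.0 * b_f) / 3.0


def conditional_covariance(var_bf, var_bm, cov_b):
    """Sampling covariance of the conditional estimates.

    Propagates the 2x2 covariance of ``(b_f, b_m)`` through the linear map
    ``A^-1`` (``L V L'`` with ``L = A^-1``), giving

        var(beta_f_hat) = 16/9 var_bf + 4/9 var_bm - 16/9 cov_b
        var(beta_m_hat) = 16/9 var_bm + 4/9 var_bf - 16/9 cov_b
        cov(beta_f_hat, beta_m_hat) = 20/9 cov_b - 8/9 (var_bf + var_bm)

    Returns ``(var_betaf, var_betam, cov_fm)``; all inputs may be arrays.
    """
    var_bf = np.asarray(var_bf, dtype=float)
    var_bm = np.asarray(var_bm, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    var_f = (16.0 * var_bf + 4.0 * var_bm - 16.0 * cov_b) / 9.0
    var_m = (16.0 * var_bm + 4.0 * var_bf - 16.0 * cov_b) / 9.0
    cov_fm = (20.0 * cov_b - 8.0 * (var_bf + var_bm)) / 9.0
    return var_f, var_m, cov_fm


def two_sided_p(z):
    """Two-sided standard-normal p-value, safe for large ``|z|`` (returns the
    smallest positive float rather than exactly 0 only below ~|z|=38.5)."""
    return 2.0 * stats.norm.sf(np.abs(z))


def two_sided_logp(z):
    """Natural log of the two-sided normal p-value, finite for any ``|z|``.

    Uses the log-scale survival function so genome-wide hits with |z| > 37,
    whose linear p underflows to zero, retain a usable value.
    """
    return np.log(2.0) + stats.norm.logsf(np.abs(z))


@dataclass
class ConditionalResult:
    """Conditional effect estimates at one variant (or arrays of variants).

    ``cov_fm`` is the sampling covariance between the two conditional
    estimates; note it is strongly negative even with independent scans
    (correlation exactly -0.8 when var_bf == var_bm and cov_b == 0).
    """

    beta_f_hat: np.ndarray
    beta_m_hat: np.ndarray
    se_f: np.ndarray
    se_m: np.ndarray
    cov_fm: np.ndarray
    z_f: np.ndarray = field(init=False)
    z_m: np.ndarray = field(init=False)
    p_f: np.ndarray = field(init=False)
    p_m: np.ndarray = field(init=False)
    logp_f: np.ndarray = field(init=False)
    logp_m: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z_f = np.asarray(self.beta_f_hat / self.se_f, dtype=float)
            self.z_m = np.asarray(self.beta_m_hat / self.se_m, dtype=float)
        self.p_f = two_sided_p(self.z_f)
        self.p_m = two_sided_p(self.z_m)
        self.logp_f = two_sided_logp(self.z_f)
        self.logp_m = two_sided_logp(self.z_m)

    @classmethod
    def from_unconditional(cls, b_f, b_m, var_bf, var_bm, cov_b) -> "ConditionalResult":
        """Build from unconditional coefficients and their covariance."""
        bf_hat, bm_hat = conditional_estimates(b_f, b_m)
        var_f, var_m, cov_fm = conditional_covariance(var_bf, var_bm, cov_b)
        return cls(bf_hat, bm_hat, np.sqrt(var_f), np.sqrt(var_m), np.asarray(cov_fm))

    def flagged(self) -> np.ndarray:
        """Boolean mask of variants whose Sigma is not positive definite."""
        var_f = self.se_f**2
        var_m = self.se_m**2
        return ~((var_f > 0) & (var_m > 0) & (var_f * var_m - self.cov_fm**2 > 0))


def conditional_tests(result: ConditionalResult):
    """Conditional one-df tests: two-sided p for each effect. Primarily a
    locus-characterisation tool (which genome drives the signal), not a
    discovery test."""
    return result.p_f, result.p_m


@dataclass
class RelatednessDesign:
    """Genotype-regression structure linking true conditional effects to
    expected unconditional coefficients, ``E[b] = A @ beta``.

    ``A`` has unit diagonal; off-diagonals are the genotype correlations
    between the individuals contributing to each scan (0.5 for parent-child,
    0 for mates under random mating).
    """

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("relatedness matrix must be symmetric")
        if not np.allclose(np.diag(self.A), 1.0):
            raise ValueError("relatedness matrix must have unit diagonal")
        # positive definiteness doubles as the singularity check
        try:
            np.linalg.cholesky(self.A)
        except np.linalg.LinAlgError as exc:
            raise ValueError("relatedness matrix must be positive definite") from exc

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @classmethod
    def duo(cls) -> "RelatednessDesign":
        """Mother-offspring duo: A = [[1, .5], [.5, 1]]."""
        return cls(np.array([[1.0, 0.5], [0.5, 1.0]]))

    @classmethod
    def trio(cls) -> "RelatednessDesign":
        """Child, mother, father under random mating (parents uncorrelated)."""
        return cls(np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]]))


def kparty_conditional(b, V, design: RelatednessDesign):
    """Conditional effects for K genotyped relatives.

    Parameters
    ----------
    b : (K,) array
        Unconditional coefficients, one per scan.
    V : (K, K) array
        Their sampling covariance.
    design : RelatednessDesign

    Returns
    -------
    (beta_hat, Sigma)
        ``A^-1 b`` and ``A^-1 V A^-T``.  For K=2 this reproduces
        :func:`conditional_estimates` / :func:`conditional_covariance`.
    """
    b = np.asarray(b, dtype=float)
    V = np.asarray(V, dtype=float)
    K = design.K
    if b.shape != (K,) or V.shape != (K, K):
        raise ValueError(f"expected b of shape ({K},) and V of shape ({K},{K})")
    Ainv = np.linalg.inv(design.A)
    beta_hat = Ainv @ b
    Sigma = Ainv @ V @ Ainv.T
    return beta_hat, Sigma
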