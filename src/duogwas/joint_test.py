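"""Multi-degree-of-freedom joint chi-square test of any parental/fetal effect.

The statistic is the quadratic form ``T = beta_hat' Sigma^-1 beta_hat`` of
the conditional effect vector against its sampling covariance; under the
joint null of no effect through any of the K genomes it is chi-square with
K degrees of freedom.  For the mother-offspring duo (K=2) this is the 2-df
test used for locus discovery; it spends one extra degree of freedom to
model both effects, which pays off precisely where a one-df meta-analysis
cancels discordant maternal and fetal effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, special, stats

__all__ = ["JointTestResult", "t2df", "tkdf", "t2df_arrays", "chi2_logsf"]

#: default genome-wide significance for the 2-df test
ALPHA_2DF = 6.6e-9
#: default genome-wide significance for one-df strategies (Bonferroni: two
#: tests per variant, alpha_2df / 2)
ALPHA_1DF = 3.3e-9


@dataclass
class JointTestResult:
    """Joint test at one variant.

    ``log_p`` is the natural-log p-value, finite even when ``p`` underflows
    (stat beyond ~3000); ``ok`` is False when Sigma was not positive definite,
    in which case ``p`` is NaN and the variant should be flagged, not used.
    """

    stat: float
    df: int
    p: float
    log_p: float
    ok: bool = True
    note: Optional[str] = None


def chi2_logsf(stat, df):
    """Natural-log chi-square survival probability, finite for any statistic.

    scipy's ``chi2.logsf`` underflows to -inf beyond stat ~1400; there the
    leading asymptotic term of the upper incomplete gamma,
    ``Q(a, x) ~ x^{a-1} e^{-x} / Gamma(a) * (1 + (a-1)/x)`` with ``a = df/2``
    and ``x = stat/2``, takes over (relative error O(1/x^2)).
    """
    stat = np.asarray(stat, dtype=float)
    out = stats.chi2.logsf(stat, df)
    a = df / 2.0
    x = stat / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = (a - 1.0) * np.log(x) - x - special.gammaln(a) + np.log1p((a - 1.0) / x)
    need = ~np.isfinite(out) & np.isfinite(stat) & (x > 1.0)
    return np.where(need, tail, out)[()]


def _chi2_result(stat: float, df: int, note: Optional[str]) -> JointTestResult:
    log_p = float(chi2_logsf(stat, df))
    return JointTestResult(stat=float(stat), df=df, p=float(np.exp(log_p)), log_p=log_p, note=note)


def tkdf(beta_hat, Sigma, note: Optional[str] = None) -> JointTestResult:
    """K-df joint test ``beta' Sigma^-1 beta`` with p from chi2(K).

    Uses a Cholesky solve rather than an explicit inverse; a Sigma that is
    not positive definite yields a flagged result with missing p rather than
    an exception (per-variant failures must not abort a genome-wide run).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    K = beta_hat.shape[0]
    if Sigma.shape != (K, K):
        raise ValueError(f"Sigma must be ({K},{K}) for a length-{K} effect vector")
    try:
        c, low = linalg.cho_factor(Sigma)
    except (linalg.LinAlgError, ValueError):
        return JointTestResult(stat=np.nan, df=K, p=np.nan, log_p=np.nan, ok=False,
                               note="Sigma not positive definite")
    stat = float(beta_hat @ linalg.cho_solve((c, low), beta_hat))
    return _chi2_result(stat, K, note)


def t2df(beta_hat, Sigma, note: Optional[str] = None) -> JointTestResult:
    """Two-df joint test of any maternal or fetal effect (duo case)."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.shape[0] != 2:
        raise ValueError("t2df expects a length-2 effect vector; use tkdf otherwise")
    return tkdf(beta_hat, Sigma, note=note)


def t2df_arrays(beta_f, beta_m, var_f, var_m, cov_fm):
    """Vectorised 2-df test over arrays of variants.

    Closed-form 2x2 quadratic form; variants with a non-positive-definite
    Sigma get NaN stat/p (flagged) instead of raising.

    Returns ``(stat, p, log_p, ok)`` arrays.
    """
    beta_f = np.asarray(beta_f, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    var_f = np.asarray(var_f, dtype=float)
    var_m = np.asarray(var_m, dtype=float)
    cov_fm = np.asarray(cov_fm, dtype=float)

    det = var_f * var_m - cov_fm**2
    ok = (var_f > 0) & (var_m > 0) & (det > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (beta_f**2 * var_m - 2.0 * beta_f * beta_m * cov_fm + beta_m**2 * var_f) / det
    stat = np.where(ok, stat, np.nan)
    log_p = chi2_logsf(stat, 2)
    p = np.exp(log_p)
    return stat, p, log_p, ok
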