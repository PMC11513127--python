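"""Overlap-aware one-df inverse-variance meta-analysis of duo GWAS scans.

To estimate the fetal effect, the maternal-scan coefficient is doubled
(mother-offspring genotype correlation 0.5 implies b_m estimates beta_f / 2
when no maternal effect exists) and combined with the fetal-scan coefficient
by inverse-variance weighting:

    w1 = 1 / var(b_f),   w2 = 1 / (4 var(b_m))
    beta_meta = (w1 b_f + 2 w2 b_m) / (w1 + w2)
    var(beta_meta) = (w1/(w1+w2))^2 var(b_f) + 4 (w2/(w1+w2))^2 var(b_m)
                     + 4 cov(b_f, b_m) w1 w2 / (w1+w2)^2

The covariance cross-term corrects for sample overlap between the scans.
The maternal-target analysis is the mirror image (double the fetal-scan
coefficient instead).  When both effects are truly present the combined
estimate is biased — discordant effects can cancel outright — so this is a
*discovery* statistic; effect interpretation belongs to the conditional
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditional import two_sided_logp, two_sided_p

__all__ = ["MetaResult", "meta_fetal", "meta_maternal", "meta_best_p"]


@dataclass
class MetaResult:
    """One-df meta-analytic estimate for one target (fetal or maternal).

    Fields may be scalars or variant-length arrays.
    """

    beta_meta: np.ndarray
    se_meta: np.ndarray
    target: str
    w1: np.ndarray
    w2: np.ndarray
    z: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)
    log_p: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z = np.asarray(self.beta_meta / self.se_meta, dtype=float)
        self.p = two_sided_p(self.z)
        self.log_p = two_sided_logp(self.z)

    def flagged(self) -> np.ndarray:
        """True where a pathological covariance drove var(beta_meta) <= 0."""
        return ~(np.asarray(self.se_meta) > 0)


def _ivw_pair(b_direct, var_direct, b_relative, var_relative, cov_direct_relative):
    """Inverse-variance combination of a direct-scan coefficient with a
    relative-scan coefficient rescaled by 2, with overlap cross-term.

    ``b_relative`` estimates (target effect)/2, so it enters as
    ``2 b_relative`` with variance ``4 var_relative`` and covariance
    ``2 cov`` against the direct coefficient.
    """
    w1 = 1.0 / var_direct
    w2 = 1.0 / (4.0 * var_relative)
    wsum = w1 + w2
    beta = (w1 * b_direct + 2.0 * w2 * b_relative) / wsum
    var = (
        (w1 / wsum) ** 2 * var_direct
        + 4.0 * (w2 / wsum) ** 2 * var_relative
        + 4.0 * cov_direct_relative * w1 * w2 / wsum**2
    )
    se = np.where(var > 0, np.sqrt(np.where(var > 0, var, np.nan)), np.nan)
    return beta, se, w1, w2


def meta_fetal(b_f, var_bf, b_m, var_bm, cov_b) -> MetaResult:
    """Meta-analytic fetal-effect estimate from both scans.

    Parameters are the unconditional coefficients, their sampling variances
    and the per-variant sampling covariance (from :mod:`duogwas.coupling`);
    scalars or arrays.
    """
    b_f = np.asarray(b_f, dtype=float)
    b_m = np.asarray(b_m, dtype=float)
    var_bf = np.asarray(var_bf, dtype=float)
    var_bm = np.asarray(var_bm, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if np.any(var_bf <= 0) or np.any(var_bm <= 0):
        raise ValueError("sampling variances must be positive")
    beta, se, w1, w2 = _ivw_pair(b_f, var_bf, b_m, var_bm, cov_b)
    return MetaResult(beta_meta=beta, se_meta=se, target="fetal", w1=w1, w2=w2)


def meta_maternal(b_f, var_bf, b_m, var_bm, cov_b) -> MetaResult:
    """Meta-analytic maternal-effect estimate: the fetal-scan coefficient is
    the rescaled relative-scan source (2 b_f, variance 4 var_bf)."""
    b_f = np.asarray(b_f, dtype=float)
    b_m = np.asarray(b_m, dtype=float)
    var_bf = np.asarray(var_bf, dtype=float)
    var_bm = np.asarray(var_bm, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if np.any(var_bf <= 0) or np.any(var_bm <= 0):
        raise ValueError("sampling variances must be positive")
    beta, se, w1, w2 = _ivw_pair(b_m, var_bm, b_f, var_bf, cov_b)
    return MetaResult(beta_meta=beta, se_meta=se, target="maternal", w1=w1, w2=w2)


def meta_best_p(fetal: MetaResult, maternal: MetaResult, alpha_1df: float):
    """Locus-discovery decision: significant iff either target's p is
    strictly below ``alpha_1df``.

    Returns ``(significant, min_p, targets)`` where ``targets`` lists which
    of "fetal"/"maternal" fired (scalars in, scalars out; arrays in,
    arrays/boolean masks out for the first two and a pair of masks for the
    third).
    """
    p_f = np.asarray(fetal.p)
    p_m = np.asarray(maternal.p)
    min_p = np.minimum(p_f, p_m)
    fired_f = p_f < alpha_1df
    fired_m = p_m < alpha_1df
    significant = fired_f | fired_m
    if np.ndim(significant) == 0:
        targets = [t for t, hit in (("fetal", fired_f), ("maternal", fired_m)) if hit]
        return bool(significant), float(min_p), targets
    return significant, min_p, (fired_f, fired_m)
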