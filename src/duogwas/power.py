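"""Asymptotic and simulated power for the three locus-discovery strategies.

Strategies compared, all at a per-variant significance level:

1. **separate** — the traditional pair of unconditional one-df scans (fetal
   and maternal), declared a discovery if *either* is significant at
   ``alpha_1df``;
2. **meta** — the overlap-aware one-df meta-analyses of the fetal and the
   maternal effect, again "either significant" at ``alpha_1df``;
3. **2-df** — the joint chi-square test at ``alpha_2df``.

The one-df strategies run two tests per variant, hence the convention
``alpha_1df = alpha_2df / 2`` (Bonferroni).

Asymptotics use the small-effect approximation ``var(b) = 1 / (N v_G)`` for
a unit-variance trait with ``v_G = 2 maf (1 - maf)``, expected unconditional
coefficients ``E[b_f] = beta_f + beta_m/2`` and ``E[b_m] = beta_m + beta_f/2``
(parent-child genotype correlation 0.5), and the design-mode coupling
``cov(b_f, b_m) = (N_s / sqrt(N_f N_m)) rho se_f se_m``.  "Either-test" power
is an exact bivariate-normal rectangle probability over the correlated pair
of Z statistics, not a Bonferroni bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from . import joint_test
from .conditional import conditional_covariance, conditional_estimates
from .coupling import CouplingEstimate, sampling_cov
from .meta import meta_fetal, meta_maternal
from .simulate import SimScenario, simulate_scan_pairs

__all__ = [
    "PowerScenario",
    "PowerResult",
    "EmpiricalPower",
    "expected_unconditional",
    "asymptotic_power",
    "simulate_power",
]

#: absolute tolerance for bivariate-normal rectangle probabilities
_MVN_ABSTOL = 1e-8


@dataclass(frozen=True)
class PowerScenario:
    """Design parameters shared by the analytic calculator and the simulator.

    ``n_s`` is the *effective* overlap (weight 1 for a woman in both scans,
    0.5 for a mother-offspring pair split across scans); ``rho`` the
    phenotype correlation among overlapping individuals.
    """

    beta_f: float
    beta_m: float
    rho: float
    n_f: int
    n_m: int
    n_s: float
    maf: float = 0.3
    alpha_1df: float = joint_test.ALPHA_1DF
    alpha_2df: float = joint_test.ALPHA_2DF

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0 < self.alpha_1df < 1 and 0 < self.alpha_2df < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_s > min(self.n_f, self.n_m):
            raise ValueError("effective overlap cannot exceed the smaller scan")

    @property
    def v_g(self) -> float:
        return 2.0 * self.maf * (1.0 - self.maf)


@dataclass
class PowerResult:
    """Asymptotic power of the three strategies plus the pieces behind it.

    NCPs are the one-df noncentralities (squared mean Z) and the 2-df
    quadratic-form noncentrality; ``corr_tests`` is the correlation between
    the two unconditional Z statistics, ``corr_meta`` between the two
    meta-analytic ones.
    """

    power_separate_either: float
    power_meta_either: float
    power_2df: float
    power_f: float
    power_m: float
    power_fmeta: float
    power_mmeta: float
    ncp_f: float
    ncp_m: float
    ncp_2df: float
    ncp_fmeta: float
    ncp_mmeta: float
    corr_tests: float
    corr_meta: float


def expected_unconditional(beta_f: float, beta_m: float):
    """Expected unconditional coefficients given true conditional effects."""
    return beta_f + 0.5 * beta_m, beta_m + 0.5 * beta_f


def _power_two_sided(mu: float, crit: float) -> float:
    """P(|Z| > crit) for Z ~ N(mu, 1)."""
    return float(stats.norm.sf(crit - mu) + stats.norm.cdf(-crit - mu))


def _rect_prob(mu1: float, mu2: float, corr: float, lo: float, hi: float) -> float:
    """P(lo < Z1 < hi, lo < Z2 < hi) for unit-variance normals with means
    (mu1, mu2) and correlation ``corr``.

    Conditioning on Z1 reduces the bivariate rectangle to a 1-D integral of
    normal CDF differences, evaluated deterministically by adaptive
    quadrature to absolute tolerance 1e-8.
    """
    from scipy.integrate import quad

    if abs(corr) >= 1.0 - 1e-12:  # degenerate: Z2 is (anti)identical to Z1
        s = np.sign(corr) if corr != 0 else 1.0

        def inside(x1):
            x2 = mu2 + s * (x1 - mu1)
            return 1.0 if lo < x2 < hi else 0.0

        val, _ = quad(lambda x: stats.norm.pdf(x - mu1) * inside(x), lo, hi,
                      epsabs=_MVN_ABSTOL, limit=200)
        return float(val)

    s2 = np.sqrt(1.0 - corr**2)

    def integrand(x1):
        m2 = mu2 + corr * (x1 - mu1)
        return stats.norm.pdf(x1 - mu1) * (
            stats.norm.cdf((hi - m2) / s2) - stats.norm.cdf((lo - m2) / s2)
        )

    val, _ = quad(integrand, lo, hi, epsabs=_MVN_ABSTOL, limit=200)
    return float(val)


def _power_either(mu1: float, mu2: float, corr: float, crit: float) -> float:
    """1 - P(|Z1| <= crit, |Z2| <= crit) for correlated unit-variance
    normals with means (mu1, mu2)."""
    return float(1.0 - _rect_prob(mu1, mu2, corr, -crit, crit))


def asymptotic_power(scenario: PowerScenario) -> PowerResult:
    """Closed-form power of all three strategies under the scenario."""
    sc = scenario
    var_bf = 1.0 / (sc.n_f * sc.v_g)
    var_bm = 1.0 / (sc.n_m * sc.v_g)
    se_bf, se_bm = np.sqrt(var_bf), np.sqrt(var_bm)
    coupling = CouplingEstimate.from_design(sc.n_s, sc.n_f, sc.n_m, sc.rho)
    cov_b = float(sampling_cov(coupling, se_bf, se_bm))
    eb_f, eb_m = expected_unconditional(sc.beta_f, sc.beta_m)

    crit1 = float(stats.norm.isf(sc.alpha_1df / 2.0))

    # -- separate unconditional scans
    z_f, z_m = eb_f / se_bf, eb_m / se_bm
    corr_tests = coupling.correlation
    p_f = _power_two_sided(z_f, crit1)
    p_m = _power_two_sided(z_m, crit1)
    p_sep = _power_either(z_f, z_m, corr_tests, crit1)

    # -- meta-analytic strategy (means and cross-correlation of the two
    #    estimators as linear combinations of (b_f, b_m))
    fm = meta_fetal(eb_f, var_bf, eb_m, var_bm, cov_b)
    mm = meta_maternal(eb_f, var_bf, eb_m, var_bm, cov_b)
    C = np.array([[var_bf, cov_b], [cov_b, var_bm]])
    a = np.array([fm.w1, 2.0 * fm.w2]) / (fm.w1 + fm.w2)       # fetal-target combo
    c = np.array([2.0 * mm.w2, mm.w1]) / (mm.w1 + mm.w2)       # maternal-target combo
    cov_meta = float(a @ C @ c)
    corr_meta = cov_meta / float(fm.se_meta * mm.se_meta)
    z_fmeta = float(fm.beta_meta / fm.se_meta)
    z_mmeta = float(mm.beta_meta / mm.se_meta)
    p_fmeta = _power_two_sided(z_fmeta, crit1)
    p_mmeta = _power_two_sided(z_mmeta, crit1)
    p_meta = _power_either(z_fmeta, z_mmeta, corr_meta, crit1)

    # -- 2-df joint test on the conditional scale
    beta = np.array(conditional_estimates(eb_f, eb_m))  # == (beta_f, beta_m)
    var_f, var_m, cov_fm = conditional_covariance(var_bf, var_bm, cov_b)
    Sigma = np.array([[var_f, cov_fm], [cov_fm, var_m]])
    ncp_2df = float(beta @ np.linalg.solve(Sigma, beta))
    crit2 = float(stats.chi2.isf(sc.alpha_2df, 2))
    p_2df = float(stats.ncx2.sf(crit2, 2, ncp_2df)) if ncp_2df > 0 else float(sc.alpha_2df)

    return PowerResult(
        power_separate_either=p_sep,
        power_meta_either=p_meta,
        power_2df=p_2df,
        power_f=p_f,
        power_m=p_m,
        power_fmeta=p_fmeta,
        power_mmeta=p_mmeta,
        ncp_f=z_f**2,
        ncp_m=z_m**2,
        ncp_2df=ncp_2df,
        ncp_fmeta=z_fmeta**2,
        ncp_mmeta=z_mmeta**2,
        corr_tests=corr_tests,
        corr_meta=corr_meta,
    )


def _wilson(k: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    z = stats.norm.isf((1.0 - level) / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


@dataclass
class EmpiricalPower:
    """Empirical rejection rates with Wilson 95% intervals."""

    power_separate_either: float
    power_meta_either: float
    power_2df: float
    ci_separate: tuple
    ci_meta: tuple
    ci_2df: tuple
    n_replicates: int
    extra: dict = field(default_factory=dict)


def simulate_power(scenario: PowerScenario, n_replicates: int, seed: int,
                   overlap_int: Optional[int] = None) -> EmpiricalPower:
    """Empirical power by full simulation of every strategy.

    Each replicate simulates the duo cohort, fits both scans, then applies
    the separate, meta-analytic and 2-df strategies exactly as they would be
    applied to real summary statistics (design-mode coupling with the
    scenario's N_s and rho).  ``overlap_int`` overrides the integer number of
    women shared between the scans when N_s is fractional.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    sc = scenario
    n_ov = int(round(sc.n_s)) if overlap_int is None else int(overlap_int)
    sim = SimScenario(sc.beta_f, sc.beta_m, sc.rho, sc.n_f, sc.n_m, n_ov, maf=sc.maf)
    reps = simulate_scan_pairs(sim, n_replicates, rng=np.random.default_rng(seed))

    b_f, se_bf = reps["b_f"], reps["se_bf"]
    b_m, se_bm = reps["b_m"], reps["se_bm"]
    var_bf, var_bm = se_bf**2, se_bm**2
    coupling = CouplingEstimate.from_design(sc.n_s, sc.n_f, sc.n_m, sc.rho)
    cov_b = sampling_cov(coupling, se_bf, se_bm)

    crit1 = stats.norm.isf(sc.alpha_1df / 2.0)
    sep_hit = (np.abs(b_f / se_bf) > crit1) | (np.abs(b_m / se_bm) > crit1)

    fm = meta_fetal(b_f, var_bf, b_m, var_bm, cov_b)
    mm = meta_maternal(b_f, var_bf, b_m, var_bm, cov_b)
    meta_hit = (np.abs(fm.z) > crit1) | (np.abs(mm.z) > crit1)

    bf_hat, bm_hat = conditional_estimates(b_f, b_m)
    var_f, var_m, cov_fm = conditional_covariance(var_bf, var_bm, cov_b)
    stat, _, _, ok = joint_test.t2df_arrays(bf_hat, bm_hat, var_f, var_m, cov_fm)
    crit2 = stats.chi2.isf(sc.alpha_2df, 2)
    t2_hit = ok & (stat > crit2)

    n = n_replicates
    return EmpiricalPower(
        power_separate_either=sep_hit.mean(),
        power_meta_either=meta_hit.mean(),
        power_2df=t2_hit.mean(),
        ci_separate=_wilson(int(sep_hit.sum()), n),
        ci_meta=_wilson(int(meta_hit.sum()), n),
        ci_2df=_wilson(int(t2_hit.sum()), n),
        n_replicates=n,
        extra={
            "power_f": float((np.abs(b_f / se_bf) > crit1).mean()),
            "power_m": float((np.abs(b_m / se_bm) > crit1).mean()),
            "power_fmeta": float((np.abs(fm.z) > crit1).mean()),
            "power_mmeta": float((np.abs(mm.z) > crit1).mean()),
            "mean_t2df": float(np.nanmean(stat)),
        },
    )
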