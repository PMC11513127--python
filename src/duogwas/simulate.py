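"""Single-locus mother-offspring duo simulator.

Generates three-generation genotype data (grandmother, woman, offspring) at
one biallelic additive locus under Hardy-Weinberg equilibrium and fair
Mendelian transmission, phenotypes for the woman and her offspring under
configurable direct-fetal and indirect-maternal effects with correlated
residuals, and the two GWAS fits that downstream modules consume:

* fetal scan  — woman's own phenotype regressed on her own genotype;
* maternal scan — offspring phenotype regressed on the woman's genotype.

The grandmother's genotype is simulated explicitly because the woman's *own*
phenotype carries an indirect maternal effect from *her* mother; omitting
that generation would break the symmetry that makes the conditional
transformation unbiased.

Phenotype model (unit-variance traits)::

    own_i       = beta_f * G_woman_i     + beta_m * G_grandmother_i + e1_i
    offspring_i = beta_f * G_offspring_i + beta_m * G_woman_i       + e2_i

with (e1, e2) bivariate normal, correlation ``rho`` (the residual
mother-offspring phenotype correlation) and common variance
``1 - v_G (beta_f^2 + beta_m^2 + beta_f beta_m)`` where
``v_G = 2 maf (1 - maf)``, so each phenotype has total variance 1.

Sample overlap follows the three canonical designs: none, 50% of the
maternal-scan women also in the fetal scan, or full (every maternal-scan
woman also in the fetal scan); arbitrary overlap counts are accepted too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SimScenario",
    "SimReplicate",
    "simulate_families",
    "simulate_phenotypes",
    "run_scan_pair",
    "simulate_scan_pairs",
]


@dataclass(frozen=True)
class SimScenario:
    """Design parameters for one simulation condition."""

    beta_f: float
    beta_m: float
    rho: float
    n_f: int
    n_m: int
    n_overlap: int
    maf: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_overlap < 0 or self.n_overlap > min(self.n_f, self.n_m):
            raise ValueError("n_overlap must lie in [0, min(n_f, n_m)]")
        if self.residual_variance <= 0:
            raise ValueError("effect sizes too large: residual variance non-positive")

    @property
    def v_g(self) -> float:
        """Genotype variance 2 maf (1 - maf)."""
        return 2.0 * self.maf * (1.0 - self.maf)

    @property
    def residual_variance(self) -> float:
        return 1.0 - self.v_g * (self.beta_f**2 + self.beta_m**2 + self.beta_f * self.beta_m)

    @property
    def n_pool(self) -> int:
        """Total distinct women simulated."""
        return self.n_f + self.n_m - self.n_overlap

    @classmethod
    def from_grid(
        cls,
        beta_f: float,
        beta_m: float,
        rho: float,
        n: int,
        overlap: str = "none",
        relative_size: str = "equal",
        maf: float = 0.3,
        seed: Optional[int] = None,
    ) -> "SimScenario":
        """Build a scenario from the canonical grid labels.

        ``overlap``: 'none', 'half' (50% of maternal-scan women also in the
        fetal scan) or 'full'.  ``relative_size``: 'equal' or 'maternal_half'
        (maternal scan half the size of the fetal scan).  ``n`` is the fetal
        scan size.
        """
        n_f = int(n)
        if relative_size == "equal":
            n_m = n_f
        elif relative_size == "maternal_half":
            n_m = -(-n_f // 2)  # ceil
        else:
            raise ValueError(f"unknown relative_size {relative_size!r}")
        try:
            n_ov = {"none": 0, "half": n_m // 2, "full": n_m}[overlap]
        except KeyError:
            raise ValueError(f"unknown overlap {overlap!r}") from None
        return cls(beta_f, beta_m, rho, n_f, n_m, n_ov, maf=maf, seed=seed)


@dataclass
class SimReplicate:
    """One draw of the paired GWAS coefficients."""

    b_f_hat: float
    se_bf: float
    b_m_hat: float
    se_bm: float
    scenario: SimScenario


def simulate_families(n: int, maf: float, rng: np.random.Generator, n_replicates: Optional[int] = None):
    """Genotype triads (grandmother, woman, offspring), additive 0/1/2 coding.

    Grandmother drawn Binomial(2, maf) under HWE; each child receives one
    fair-Mendelian allele from their mother plus one population allele
    (random mating, no assortment).  With ``n_replicates`` the returned
    arrays have shape ``(n_replicates, n)``, otherwise ``(n,)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shape = (n,) if n_replicates is None else (n_replicates, n)
    g_gm = rng.binomial(2, maf, size=shape)
    g_w = rng.binomial(1, g_gm / 2.0) + rng.binomial(1, maf, size=shape)
    g_o = rng.binomial(1, g_w / 2.0) + rng.binomial(1, maf, size=shape)
    return g_gm, g_w, g_o


def simulate_phenotypes(triads, beta_f: float, beta_m: float, rho: float, maf: float,
                        rng: np.random.Generator):
    """Own and offspring phenotypes for each woman, unit total variance.

    ``triads`` is the ``(g_gm, g_w, g_o)`` tuple from
    :func:`simulate_families` (any matching shapes).
    """
    g_gm, g_w, g_o = triads
    v_g = 2.0 * maf * (1.0 - maf)
    resid_var = 1.0 - v_g * (beta_f**2 + beta_m**2 + beta_f * beta_m)
    if resid_var <= 0:
        raise ValueError("effect sizes too large: residual variance non-positive")
    s = np.sqrt(resid_var)
    z1 = rng.standard_normal(np.shape(g_w))
    z2 = rng.standard_normal(np.shape(g_w))
    e1 = s * z1
    e2 = s * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    own = beta_f * g_w + beta_m * g_gm + e1
    offspring = beta_f * g_o + beta_m * g_w + e2
    return own, offspring


def _ols_rows(x, y):
    """Row-wise simple OLS with intercept: slope and its standard error.

    ``x``, ``y`` of shape (R, n); returns (slope, se) of shape (R,).
    """
    n = x.shape[-1]
    x = x.astype(float)
    xbar = x.mean(axis=-1, keepdims=True)
    ybar = y.mean(axis=-1, keepdims=True)
    dx = x - xbar
    dy = y - ybar
    sxx = np.einsum("...i,...i->...", dx, dx)
    sxy = np.einsum("...i,...i->...", dx, dy)
    syy = np.einsum("...i,...i->...", dy, dy)
    slope = sxy / sxx
    resid_var = (syy - slope * sxy) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return slope, se


def _scan_pair_batch(scenario: SimScenario, n_replicates: int, rng: np.random.Generator):
    """One batch of replicates, fully vectorised. Returns four (R,) arrays."""
    sc = scenario
    triads = simulate_families(sc.n_pool, sc.maf, rng, n_replicates=n_replicates)
    own, offspring = simulate_phenotypes(triads, sc.beta_f, sc.beta_m, sc.rho, sc.maf, rng)
    g_w = triads[1]
    # fetal scan: first n_f women; maternal scan: last n_m women — the
    # overlap block [n_f - n_overlap, n_f) sits in both
    lo = sc.n_f - sc.n_overlap
    b_f, se_f = _ols_rows(g_w[:, : sc.n_f], own[:, : sc.n_f])
    b_m, se_m = _ols_rows(g_w[:, lo : lo + sc.n_m], offspring[:, lo : lo + sc.n_m])
    return b_f, se_f, b_m, se_m


def run_scan_pair(scenario: SimScenario, rng: Optional[np.random.Generator] = None) -> SimReplicate:
    """Simulate one replicate and fit both scans."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    b_f, se_f, b_m, se_m = _scan_pair_batch(scenario, 1, rng)
    return SimReplicate(float(b_f[0]), float(se_f[0]), float(b_m[0]), float(se_m[0]), scenario)


def simulate_scan_pairs(scenario: SimScenario, n_replicates: int,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None):
    """Simulate many replicates; returns dict of (n_replicates,) arrays
    ``b_f``, ``se_bf``, ``b_m``, ``se_bm``.

    Replicates are generated in memory-bounded batches; output is
    deterministic given the seed (batching is a fixed function of the pool
    size, so it never alters the random stream).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
    # ~4e6 family draws per batch keeps peak memory in the low hundreds of MB
    batch = max(1, int(4_000_000 // max(1, scenario.n_pool)))
    out = {k: np.empty(n_replicates) for k in ("b_f", "se_bf", "b_m", "se_bm")}
    done = 0
    while done < n_replicates:
        m = min(batch, n_replicates - done)
        b_f, se_f, b_m, se_m = _scan_pair_batch(scenario, m, rng)
        sl = slice(done, done + m)
        out["b_f"][sl], out["se_bf"][sl] = b_f, se_f
        out["b_m"][sl], out["se_bm"][sl] = b_m, se_m
        done += m
    return out


def replicates_to_table(reps: dict, scenario: SimScenario):
    """Tabulate simulator output (one row per replicate) for TSV export."""
    import pandas as pd

    df = pd.DataFrame(reps)
    for name in ("beta_f", "beta_m", "rho", "n_f", "n_m", "n_overlap", "maf"):
        df[name] = getattr(scenario, name)
    return df
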