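"""Sampling covariance between coefficients of two overlapping GWAS scans.

When the same (or related) individuals contribute to both the fetal and the
maternal scan, the two per-variant coefficients are correlated.  The
per-variant sampling covariance is well approximated by

    cov(b_f, b_m) ~= (N_s / sqrt(N_f N_m)) * rho * SE(b_f) * SE(b_m)
                  =  intercept * SE(b_f) * SE(b_m)

where ``N_s`` is the *effective* number of overlapping individuals (weighted
by the genotype correlation between the persons contributing to each scan),
``rho`` the phenotypic correlation between own and offspring phenotype among
the overlapping individuals, and ``intercept`` the bivariate LD-score
regression intercept.  The intercept is always a user-supplied input here —
estimating it requires genome-wide LD scores and an external LDSC run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["CouplingEstimate", "sampling_cov", "effective_overlap"]


@dataclass
class CouplingEstimate:
    """Per-variant coupling between two scans.

    Exactly one of two modes:

    * ``intercept`` — the bivariate LDSC intercept, used directly as the
      correlation between the two coefficients;
    * ``design`` — computed from sample sizes, effective overlap ``n_overlap``
      (N_s) and phenotype correlation ``rho``.
    """

    mode: str
    intercept: Optional[float] = None
    n_overlap: Optional[float] = None
    n_scan1: Optional[int] = None
    n_scan2: Optional[int] = None
    rho: Optional[float] = None

    def __post_init__(self):
        if self.mode == "intercept":
            if self.intercept is None:
                raise ValueError("intercept mode requires an intercept value")
        elif self.mode == "design":
            if None in (self.n_overlap, self.n_scan1, self.n_scan2, self.rho):
                raise ValueError("design mode requires n_overlap, n_scan1, n_scan2, rho")
            if self.n_overlap < 0:
                raise ValueError("n_overlap must be non-negative")
            if self.n_overlap > min(self.n_scan1, self.n_scan2):
                raise ValueError(
                    "effective overlap cannot exceed the smaller scan "
                    f"(N_s={self.n_overlap}, min N={min(self.n_scan1, self.n_scan2)})"
                )
            if not -1.0 <= self.rho <= 1.0:
                raise ValueError("rho must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if abs(self.correlation) > 1.0:
            raise ValueError(
                f"implied coefficient correlation {self.correlation:.4g} exceeds 1 in magnitude"
            )

    @classmethod
    def from_intercept(cls, intercept: float) -> "CouplingEstimate":
        return cls(mode="intercept", intercept=float(intercept))

    @classmethod
    def from_design(cls, n_overlap: float, n_scan1: int, n_scan2: int, rho: float) -> "CouplingEstimate":
        return cls(
            mode="design",
            n_overlap=float(n_overlap),
            n_scan1=int(n_scan1),
            n_scan2=int(n_scan2),
            rho=float(rho),
        )

    @property
    def correlation(self) -> float:
        """Implied correlation between the paired coefficients (the quantity
        the bivariate LDSC intercept estimates)."""
        if self.mode == "intercept":
            return float(self.intercept)
        return float(self.n_overlap / np.sqrt(self.n_scan1 * self.n_scan2) * self.rho)


def sampling_cov(coupling: CouplingEstimate, se1, se2):
    """Per-variant sampling covariance ``corr * se1 * se2``.

    ``se1``/``se2`` may be scalars or arrays (must be positive); bilinear in
    the two standard errors.
    """
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    return coupling.correlation * se1 * se2


def effective_overlap(n_same_individual: float = 0, n_parent_child_pairs: float = 0) -> float:
    """Effective overlap N_s between a fetal and a maternal scan.

    Women contributing their own phenotype+genotype to the fetal scan *and*
    their genotype+offspring phenotype to the maternal scan count with weight
    1 (same genome in both scans).  Genotyped mother-offspring pairs in which
    the offspring sits in the fetal scan and the mother in the maternal scan
    count with weight 0.5, the parent-child genotype correlation.
    """
    if n_same_individual < 0 or n_parent_child_pairs < 0:
        raise ValueError("counts must be non-negative")
    return float(n_same_individual) + 0.5 * float(n_parent_child_pairs)
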