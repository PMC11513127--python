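"""Partition a variant's associations into direct-fetal and indirect-maternal
effects, with overlap-corrected standard errors and the 2-df joint test.

The two input coefficients come from a fetal scan (own phenotype on own
genotype) and a maternal scan (offspring phenotype on maternal genotype).
Because maternal and offspring genotypes correlate 0.5, a purely fetal locus
with b_f = 0.12 shows b_m = 0.06 in the maternal scan — the conditional
transform removes that contamination.
"""

import numpy as np

from duogwas import (
    ConditionalResult,
    CouplingEstimate,
    sampling_cov,
    t2df,
)

# unconditional coefficients at one variant (same effect allele in both scans)
b_f, se_bf = 0.12, 0.015
b_m, se_bm = 0.06, 0.017

# sample overlap between the scans, summarised by a bivariate LDSC intercept
coupling = CouplingEstimate.from_intercept(0.1)
cov_b = sampling_cov(coupling, se_bf, se_bm)

res = ConditionalResult.from_unconditional(b_f, b_m, se_bf**2, se_bm**2, cov_b)
print(f"conditional fetal effect    beta_f = {float(res.beta_f_hat):+.4f}  "
      f"SE = {float(res.se_f):.4f}  p = {float(res.p_f):.3g}")
print(f"conditional maternal effect beta_m = {float(res.beta_m_hat):+.4f}  "
      f"SE = {float(res.se_m):.4f}  p = {float(res.p_m):.3g}")
print(f"cov(beta_f, beta_m) = {float(res.cov_fm):.3e}  "
      f"(corr = {float(res.cov_fm / (res.se_f * res.se_m)):.3f})")

Sigma = np.array([[float(res.se_f**2), float(res.cov_fm)],
                  [float(res.cov_fm), float(res.se_m**2)]])
joint = t2df([float(res.beta_f_hat), float(res.beta_m_hat)], Sigma)
print(f"T_2df = {joint.stat:.2f} (df={joint.df}), p = {joint.p:.3g}")
print()
print("The maternal-scan signal here is exactly what a purely fetal locus")
print("induces (b_m = b_f/2): the conditional maternal effect is ~0, and the")
print("joint test carries the full discovery signal.")
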