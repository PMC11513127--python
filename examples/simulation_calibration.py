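"""Validate the analysis chain by simulation: null calibration and recovery.

Simulates mother-offspring duos at a single additive locus, fits both GWAS
scans per replicate, and checks that (i) the 2-df statistic is chi-square(2)
under the joint null and (ii) conditional estimates recover the simulated
effects with calibrated standard errors.
"""

import numpy as np

from duogwas import (
    ConditionalResult,
    CouplingEstimate,
    SimScenario,
    conditional_covariance,
    conditional_estimates,
    sampling_cov,
    simulate_scan_pairs,
    t2df_arrays,
)

N = 5_000
REPS = 4_000
rng = np.random.default_rng(7)

print(f"null calibration: N={N} per scan, full overlap, rho=0.5, {REPS} replicates")
sc = SimScenario(0.0, 0.0, 0.5, N, N, N, maf=0.3)
reps = simulate_scan_pairs(sc, REPS, rng=rng)
coupling = CouplingEstimate.from_design(N, N, N, 0.5)
cov_b = sampling_cov(coupling, reps["se_bf"], reps["se_bm"])
bf_hat, bm_hat = conditional_estimates(reps["b_f"], reps["b_m"])
var_f, var_m, cov_fm = conditional_covariance(reps["se_bf"]**2, reps["se_bm"]**2, cov_b)
stat, p, _, _ = t2df_arrays(bf_hat, bm_hat, var_f, var_m, cov_fm)
print(f"  mean T_2df = {stat.mean():.3f} (expect 2 under chi-square(2))")
print(f"  empirical size at alpha=0.05: {(p < 0.05).mean():.4f}")

print()
print(f"parameter recovery: beta_f = beta_m = 0.03, same design")
sc = SimScenario(0.03, 0.03, 0.5, N, N, N, maf=0.3)
reps = simulate_scan_pairs(sc, REPS, rng=rng)
cov_b = sampling_cov(coupling, reps["se_bf"], reps["se_bm"])
cond = ConditionalResult.from_unconditional(reps["b_f"], reps["b_m"],
                                            reps["se_bf"]**2, reps["se_bm"]**2, cov_b)
print(f"  mean beta_f_hat = {cond.beta_f_hat.mean():+.5f} (truth +0.03000)")
print(f"  mean beta_m_hat = {cond.beta_m_hat.mean():+.5f} (truth +0.03000)")
print(f"  empirical SD / mean analytic SE (fetal): "
      f"{cond.beta_f_hat.std(ddof=1) / cond.se_f.mean():.3f} (expect ~1)")
print()
print("Unconditional coefficients are biased (E[b_f] = beta_f + beta_m/2 =")
print(f"0.045 here; observed mean b_f = {reps['b_f'].mean():.4f}); the")
print("conditional transform removes the bias with correctly sized SEs.")
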