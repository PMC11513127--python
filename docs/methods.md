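# Methods

## Model

At a biallelic locus with additive coding G ∈ {0, 1, 2}, a perinatal
phenotype of a child and the "offspring phenotype" reported for a mother are
modelled as

    own_i       = β_f · G_woman_i     + β_m · G_grandmother_i + e1_i
    offspring_i = β_f · G_offspring_i + β_m · G_woman_i       + e2_i

on a standardized (unit-variance) trait.  β_f is the direct effect of an
individual's own genotype on their own phenotype; β_m the indirect effect of
the mother's genotype, mediated by the intrauterine environment.  A woman's
*own* phenotype therefore carries an indirect effect from *her* mother,
which is why the generative model (and the simulator) is three-generational.

Under random mating, parent–child genotypes correlate 0.5, so the two
feasible scans estimate mixtures:

    E[b_f] = β_f + β_m/2        (own phenotype ~ own genotype)
    E[b_m] = β_m + β_f/2        (offspring phenotype ~ maternal genotype)

i.e. E[b] = A β with relatedness matrix A = [[1, ½], [½, 1]].  Everything in
the package follows from inverting this map.

## Conditional estimation

β̂ = A⁻¹ b gives β̂_f = (4/3)b_f − (2/3)b_m and β̂_m = (4/3)b_m − (2/3)b_f.
The sampling covariance propagates as Σ = A⁻¹ V A⁻ᵀ, with
V = [[var(b_f), cov], [cov, var(b_m)]]:

    var(β̂_f) = 16/9 var(b_f) + 4/9 var(b_m) − 16/9 cov
    var(β̂_m) = 16/9 var(b_m) + 4/9 var(b_f) − 16/9 cov
    cov(β̂_f, β̂_m) = 20/9 cov − 8/9 (var(b_f) + var(b_m))

The off-diagonal is derived here by linear-map propagation and is locked by
a unit test against generic L·V·Lᵀ matrix arithmetic.  A consequence worth
knowing: with independent scans and equal variances, corr(β̂_f, β̂_m) = −0.8
— the conditional estimates are strongly anti-correlated by construction.
The K-party generalisation accepts any symmetric positive-definite
unit-diagonal A; the built-in trio design (child, mother, father) assumes
random mating, i.e. zero mother–father genotype correlation (configurable by
passing a different A).

## Sample-overlap coupling

When individuals (or relatives) contribute to both scans,
cov(b_f, b_m) ≈ (N_s/√(N_f N_m)) · ρ · SE(b_f)·SE(b_m), where N_s is the
effective overlap (weight 1 per woman in both scans, 0.5 per mother–offspring
pair split across scans — the parent–child genotype correlation) and ρ the
own/offspring phenotype correlation among the overlapping individuals.  The
whole prefactor is what a bivariate LD-score-regression intercept estimates,
so the package accepts either the intercept (the real-data route; estimating
it is an external LDSC task, deliberately out of scope) or the design
parameters (the simulation/power route).

In power and simulation work, ρ is taken as the *residual* correlation; the
extra phenotypic correlation contributed by the locus itself is O(β²) ≤ 10⁻³
for the effect sizes considered (≤ 0.03 on a unit-variance trait) and is
ignored analytically.  The simulator makes no such approximation, so the
asymptotic-vs-empirical power checks bound the error of this choice.

## Discovery tests

- **2-df joint test**: T = β̂' Σ̂⁻¹ β̂ ~ χ²(2) under β_f = β_m = 0, computed by
  Cholesky solve.  Because the quadratic form is invariant under the
  invertible map A⁻¹, T equals b' V⁻¹ b in the unconditional
  parameterisation — used as an internal consistency oracle.
- **One-df meta-analyses**: for the fetal target, combine b_f with 2·b_m
  (variance 4·var(b_m)) by inverse-variance weights w₁ = 1/var(b_f),
  w₂ = 1/(4 var(b_m)); the variance of the combination carries the
  cross-term 4·cov(b_f,b_m)·w₁w₂/(w₁+w₂)².  The maternal target mirrors
  this (2·b_f, variance 4·var(b_f), cross-covariance 2·cov).  Note the
  weights are the *marginal* inverse variances, not a full GLS solve: with
  overlap, the covariance enters only the variance of the estimate.  When
  both effects are present the combined estimate is biased — discordant
  effects can cancel exactly — so meta results are for discovery only;
  interpretation uses the conditional estimates.
- **Separate scans**: the traditional unconditional test per scan.

One-df strategies perform two tests per variant, so their default threshold
is half the 2-df one: α_1df = 3.3×10⁻⁹ vs α_2df = 6.6×10⁻⁹ (both
configurable; comparisons use strict `<`).  All p-values are carried in
natural-log form alongside the linear value; beyond |z| ≈ 37 (χ² beyond
~1400) the linear p underflows and log-scale survival functions (with an
asymptotic incomplete-gamma tail for the chi-square) keep results finite and
ordered.

## Power

Asymptotics use var(b) = 1/(N·v_G) per scan with v_G = 2·maf·(1−maf)
(unit-variance trait, small-effect approximation).  The 2-df noncentrality
is β' Σ⁻¹ β with power from the noncentral χ²(2) at the χ² critical value;
one-df powers are two-sided normal probabilities at noncentrality E[Z].
"Either-test" power for the paired one-df strategies is the exact bivariate
normal rectangle probability 1 − P(|Z₁| ≤ c, |Z₂| ≤ c) at the pair's
correlation (overlap-induced for the separate scans; structural for the two
meta estimators, which share inputs even without overlap).  The rectangle is
evaluated by conditioning on Z₁ and integrating normal-CDF differences with
adaptive quadrature to absolute tolerance 1e-8 — deterministic, unlike
QMC-based multivariate CDFs.

`simulate_power` replays the same strategies on simulator output and reports
Wilson 95% intervals.  Simulation-based checks run at α = 0.001 (empirical
rejection rates at 3.3×10⁻⁹ would need ~10⁹ replicates); the genome-wide
thresholds are evaluated analytically.

## Simulator

Grandmother genotypes are Binomial(2, maf) under HWE; each child receives
one fair-Mendelian maternal allele plus one population allele (random
mating, no assortment or inbreeding).  Residuals (e1, e2) are bivariate
normal with correlation ρ and common variance
1 − v_G(β_f² + β_m² + β_f β_m), so each phenotype has total variance 1.
Scans are ordinary least squares with intercept, no covariates, on raw
(unstandardized) genotypes.  Overlap designs: none, half (50% of
maternal-scan women also in the fetal scan), full, or any explicit count;
relative scan sizes equal or maternal-half.  Defaults that the validation
harness uses: maf = 0.3 (a common-variant frequency; exposed as a
parameter), ρ = 0.5 (a high mother–offspring phenotype correlation), effect
sizes on the grid {±0.01, ±0.03}, N per scan 10,000–50,000.

What the simulator does *not* emulate: linkage disequilibrium and multi-SNP
architecture, population stratification or assortative mating, genotyping or
imputation error, binary traits, and X-linked inheritance.  Passing
calibration here therefore validates the estimators' algebra and the
overlap correction under the stated sampling model, not robustness to those
real-data complications.

## Numerical and design choices

- Replicate batches in the simulator are a fixed function of the family-pool
  size, so results are bit-reproducible for a given seed regardless of
  replicate count ordering.
- A non-positive-definite per-variant Σ (possible under extreme intercepts)
  flags the variant (NaN p, `ok = False`) rather than aborting a genome-wide
  run; meta results with pathological negative combined variance are flagged
  the same way.
- Harmonization intersects on variant ID with a chrom/pos consistency check;
  swapped effect/other alleles flip the sign (and complement the frequency);
  strand-ambiguous A/T and C/G variants are retained and matched by label by
  default (suitable within a strand-consistent study) with a `drop` option;
  irreconcilable allele sets are dropped and counted.  Duplicated variant
  IDs are an error by default (`keep-first` available) — how the original
  birth-weight merges handled them is not documented, so the behaviour is a
  configuration choice, not an assertion.
- SEs reconstructed from (beta, p) use the upper-tail normal quantile at
  p/2; below the double-precision floor the quantile is taken from log-p via
  `ndtri_exp`, so genome-wide hits never degenerate to SE = 0.
- Locus reduction is greedy distance-based clumping (smallest p first,
  suppressing significant neighbours within ±500 kb by default).  r²-based
  clumping would need an external LD reference panel; the distance window is
  the panel-free approximation, and locus counts from the two schemes are
  not comparable.
- Validation problem sizes (20,000 replicates for null calibration and power
  agreement at N = 10,000 per scan; 1,000 replicates for parameter recovery
  at N = 20,000) were chosen so Monte-Carlo error is well below each check's
  tolerance band while a full validation pass stays in the minutes range on
  one CPU.

## Known limitations

- The bias of meta-analytic estimates under joint effects is accepted by
  design; only the conditional estimates are interpretable as β_f, β_m.
- The intercept route inherits whatever error the external LDSC fit has; no
  uncertainty in the intercept is propagated.
- The trio (3-df) extension uses the same machinery with the trio
  relatedness matrix and is an extension of the duo derivation, validated
  against matrix/Monte-Carlo oracles rather than an external reference
  implementation.
- Effective-overlap accounting covers same-individual and mother–offspring
  pair sharing; other relative classes (siblings, grandparents) would need
  their genotype correlation supplied through N_s manually.
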