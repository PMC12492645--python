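# Methods

This note documents the statistical model, the estimators, the numerical
choices, and the simulation engine, including the design decisions that
were genuinely open and the limitations a user should know about.

## Model and moment conditions

For standardized phenotype Y, standardized environment E, and standardized
genotypes G over M variants,

    Y_i = Σ_j G_ij β_j + Σ_j S_ij γ_j + ε₁_i E_i + ε₀_i,      S_ij = G_ij E_i,

with (β_j, γ_j) iid bivariate normal with variances h_g²/M, h_I²/M and
covariance ρ_IG/M, and residuals (ε₀, ε₁) bivariate normal with variances
(σ₀², σ₁²) and covariance ρ₀₁.  σ₀² is set so the phenotypic variance is 1.
h_I² is the G×E interaction proportion; ρ_IG = √(h_g² h_I²)·r_IG is the G×E
genetic covariance.

Let R be the LD (genotype correlation) matrix of one approximately
independent genomic block, R = U D Uᵀ its eigen-decomposition, and
z̃ = D^(−1/2) Uᵀ z the whitened Z-score vector of a scan restricted to the
block.  The diagonal moment conditions used are, per retained
eigencomponent j:

| channel | expectation |
|---|---|
| GWAS squares        | N_G h_g² D_jj/M + 1 |
| GWIS squares        | N_I h_I² D_jj/M + 1 + 2(h_I² + σ₁²) |
| GWAS×GWIS products  | √(N_G N_I) ρ_IG D_jj/M + 2N_S(ρ_IG + ρ₀₁)/√(N_G N_I) |

The cross-channel intercept contains the sample overlap N_S only; it is
fitted freely, so overlap between the two scans is irrelevant to the slope
and never needs to be known.

With a heritable environment E = Σ_j G_ij α_j + ε₂ and the trivariate
effect model — cov(β, γ) = ρ_IG, cov(β, α) = ρ_GE, cov(γ, α) = ρ_IE — the
GWIS-squares slope carries h_I² + 2ρ_IE², the GWAS×GWIS slope carries
ρ_IG + ρ_GE ρ_IE, and the E-GWAS×GWIS slope carries ρ_IE(1 + h_E²).  The
corrected estimates subtract the estimated confounding contributions; the
corrected h_I² therefore can never exceed the uncorrected one.  Under the
global null of no G×E interaction, ρ_IE is identically zero, so the
correction cannot inflate type-I error.  The noise-free inversion identity
of this five-parameter system (and the sign conventions above) was
verified against direct matrix-normal simulation before being trusted;
note that cov(β, α) must be ρ_GE and cov(γ, α) must be ρ_IE for the three
slopes to take these forms.

## Estimation

Each parameter is the slope of a weighted least-squares regression of a
product channel on the eigenvalues.  Weights are inverse variances of the
products,

    w_j = min(D_jj, 1) / T_jj,
    T_jj = (D_jj N_G h_g²/M + 1)(D_jj N_I h_I²/M + 1 + 2(h_I² + σ₁²))
           + (√(N_G N_I) ρ_IG D_jj/M + intercept)²,

the `min(D_jj, 1)` factor additionally shrinking large-eigenvalue
components whose products are noisy.  The marginal (squares) regressions
use the analogous weight with their own factor squared, refreshed over
three plug-in passes.  ρ_IG is fitted by iteratively reweighted least
squares: initialized at ρ_IG = 0 and intercept 0, alternating weight
construction and WLS until the relative change falls below 1e−6 (default
cap 10 iterations; non-convergence is flagged, and the last iterate
returned).  h_g², h_I², and σ₁² are estimated first and held fixed inside
the IRLS loop, matching their role as pre-estimated plug-ins.  σ₁² is
identified from the GWIS intercept given the slope-h_I²; under heritable-E
confounding the intercept uses the *uncorrected* slope, so reported σ₁²
absorbs −2ρ_IE².

Moment estimates are unbounded: variance components may legitimately come
out negative and are reported raw.  Clipping at zero happens only inside
weight construction, where T_jj must stay positive; truncating the reported
estimates would bias the downstream jackknife.

The correction chain runs h_E² → ρ_IE → corrected h_I² → ρ_GE → corrected
ρ_IG, with three passes refreshing the variance plug-ins inside the IRLS
weights (the estimates themselves stabilize after one pass; the iteration
schedule was an open choice).  The ρ_GE moment condition is taken as the
standard cross-trait form (slope √(N_G N_E)ρ_GE D_jj/M), an assumption
documented here because only the ρ_IE and h-channel conditions are pinned
down by the inversion identity.

The diagonal-LD baseline regresses raw per-variant Z products on LD scores
ℓ_j = (R²)_jj with the LD-score-regression weight 1/(max(ℓ_j,1)·T_j); it
uses only partial LD information and serves as the efficiency comparator,
including a diagonal version of the full correction chain.

## Inference

Uncertainty comes from the delete-block jackknife: contiguous groups of LD
blocks (default: one group per block, capped at 200) are deleted in turn,
the entire estimation chain is re-run on the remaining rows, and the
delete-group covariance is formed.  Blocks are the correct independence
unit — eigencomponents within a block share in-sample LD estimation noise
and effect draws, and a row-level jackknife demonstrably underestimates
the variance.

Two small-sample refinements matter when the group count g is small
(the scaled experiments have g = 10):

* **Off-diagonal shrinkage.**  The 2×2 jackknife covariance of
  (ĥ_I², ρ̂_IG) has an off-diagonal that is essentially noise at g = 10
  (its sampling SD is ~0.47 in correlation units while the true
  correlation under the null is ~0.01), which fattens the tail of the
  Mahalanobis statistic.  The Schäfer–Strimmer estimator shrinks the
  correlation toward zero with data-driven intensity Var̂(r̂)/r̂²; the raw
  covariance is available via `shrink_corr=False`.

* **Reference distributions.**  Wald tests use Student t with g−1 degrees
  of freedom.  The joint statistic d² = V̂ᵀΣ̂⁻¹V̂ follows the
  Korn–Graubard convention for Wald statistics built on replicate-based
  covariances: d²/2 is referred to F(2, g−2).  Alternatives are
  selectable — the asymptotic χ²(2), the classical Hotelling T² scaling
  d²(g−2)/(2(g−1)) ~ F(2, g−2), and the tail of T₁² + T₂² for independent
  t(g−1) variables (Gauss–Legendre quadrature); all converge to χ²(2) as
  g grows, and the default F convention sits between the last two in tail
  weight, which is where the null simulations put the truth.  With oracle
  covariance the plain χ²(2) test is exactly calibrated, so all of the
  small-g care is about covariance estimation, not the estimator itself.

Univariate tests are two-sided by default (variance components can be
negative under moment estimation); a one-sided option exists.  The
confounding test is the two-sided Wald test of ρ_IE = 0.

The expected PRS-by-E regression coefficient under a perfectly fitted
polygenic score is ρ_IG/h_g²; `prs_by_e_check` verifies this equivalence in
simulation with the oracle (true-β) score and demonstrates the attenuation
of the coefficient when the score carries measurement error.

## Simulation engine

The generator realizes the study conditions end to end: genotypes with
block LD, effect draws, phenotype, environment, and in-process vectorized
per-SNP scans (simple regression for GWAS/E-GWAS; the interaction
coefficient of y ~ g + e + g·e, one closed-form 4×4 solve per SNP, for the
GWIS).

Scaled defaults: n = 2,000 subjects, m = 1,000 variants in 10 blocks of
100, causal fraction 5%, all scans on the same subjects (complete sample
overlap, absorbed by intercepts).  Causal effect variances are h²/M₀ with
M₀ the causal count, so realized variance components match their nominal
values; `effect_scale="total"` switches to h²/M on the causal subset
(realized h²·M₀/M).  The environment is standard normal (standardized
in-sample); heritable E adds Gα with residual variance 1 − h_E².  Residual
variance of Y is 1 − h_g² − h_I² − σ₁².

**LD profile.**  Real LD references carry two features the estimators care
about: smooth within-block eigenvalue spectra and heterogeneity of LD
strength across the genome (without the latter, per-variant LD scores are
nearly constant and any diagonal-LD regression is close to degenerate).
The default profile is AR(1) within blocks with the lag-1 correlation
varying across blocks from 0.2 to 0.98.  This choice was driven by two
constraints evaluated during design: single-factor (exchangeable) blocks
concentrate each block's LD in one giant eigenvalue, making the squares
regressions ride on ~10 high-leverage chi-square(1) observations and
destroying jackknife t calibration (null rejection ~0.15), while
homogeneous profiles degrade the baseline comparator.  Heterogeneous AR(1)
calibrates all three tests and keeps both estimators unbiased.
Exchangeable and identity profiles and a thresholded-latent-Gaussian
dosage mode (MAF ~ U(0.05, 0.5), 0/1/2 dosages) remain available.

**Replication design.**  `run_experiment` shares a genotype panel across
replications (amortizing the LD eigen-decomposition) but redraws it every
50 replications: a single fixed panel leaves panel-conditional bias in
summary rates (extra-binomial variance across seeds), while the periodic
redraw recovers the marginal, panel-averaged expectations.  Per-replication
seeds derive deterministically from the master seed and the (scenario,
replication) index.  The in-sample LD of each panel is the reference — the
same design as using an in-sample reference panel on real data, and under
the null it makes the whitened products cleanly pivotal, which is what
keeps the tests calibrated.  An exact population-LD reference
(`population_ld_reference`) is available for studying the
negligible-reference-noise regime; it removes the mild (~4% relative)
attenuation that in-sample eigenvalue noise induces in slope estimates at
this panel size, at a small cost in conditional null pivotality.

## What the synthetic studies do and do not show

The generator emulates block-diagonal Gaussian LD, Gaussian polygenic
effects with 5% causal sparsity, a single standardized environment, and
complete sample overlap.  It does not emulate: real LD (long-range,
MAF-dependent, cross-block leakage), non-Gaussian or MAF-coupled effect
sizes, binary phenotypes or ascertainment, covariate adjustment, or
population structure.  Passing tests therefore demonstrate the internal
statistical contracts (calibration, unbiasedness, efficiency ordering of
the two estimators under the stated model), not robustness to those
real-data complications.  Two scale-dependent observations: the measured
efficiency advantage of full-LD whitening over the diagonal baseline
(~33% SD reduction on the grid at n = 2,000, m = 1,000; larger still for
the corrected covariance chain) depends on the scale and LD regime — the
relative penalty of using only LD scores shrinks as variant counts and
block counts grow; and the corrected ρ_IG carries a small (~−0.001,
statistically insignificant at 800 replications) plug-in bias from the
ρ̂_GE ρ̂_IE product that vanishes as scan sample sizes grow.

## Numerical choices and degenerate inputs

* Eigenvalue truncation: components with D_jj ≤ 1e−6 · D_max are dropped —
  D^(−1/2) explodes on near-null components.  At tol = 0 the retained
  eigenvalues sum to the block trace exactly.
* Eigenvector signs: the largest-magnitude element of each eigenvector is
  made positive, for reproducibility across linear-algebra backends.
* Degenerate regressions (all eigenvalues equal, as with identity LD for
  the baseline) raise informative errors rather than returning arbitrary
  slopes.
* Strand-ambiguous (A/T, C/G) variants are removed during harmonization —
  the schema does not guarantee allele frequencies to resolve them.
  Variant matching is by ID plus allele pair; per-variant sample sizes are
  summarized to a scan-wide median because the moment conditions use
  scalar N's.  Coordinates, where present, are 1-based.
* Monomorphic/collinear SNP designs in the scans are flagged and their
  Z-scores set missing rather than aborting the scan.
* A jackknife deletion that produces a degenerate design excludes that
  group with a warning; fewer than two usable groups is an error, as is a
  numerically singular joint covariance (condition number > 1e12).

## Limitations

Rare variants are outside scope (low LD makes LD-based summary methods
unreliable for them), as are binary phenotypes, annotation-stratified
variance components, and multi-environment joint fits.  The method is
genome-level: it detects and quantifies aggregate G×E signal but does not
localize it to variants.  The Gaussian-effects assumption matters for
point estimation (sparsity costs efficiency; non-Gaussianity can bias
estimates) though null calibration survives, since every effect-size
assumption collapses to zero under the null.
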