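# Methods

This note records the statistical models implemented in `qrgwas`, the
choices made where several defensible options existed, and what the
simulation-based tests do and do not establish about real data.

## Phenotype model and adjustment

Plot-level observations from a randomized-complete-block trial repeated
over environments follow

y_ijk = μ + a_j + g_i + ga_ij + b_k(j) + ε_ijk,

with fixed environment effects a_j (treatment contrasts plus intercept)
and independent normal random effects: genotype g_i ~ N(0, σ²_g),
genotype-by-environment ga_ij ~ N(0, σ²_ga), block-within-environment
b_k(j) ~ N(0, σ²_b), residual ε ~ N(0, σ²_e). Units are trait units
(days for phenology traits) and their squares for variances.

**REML.** Variance components maximize the restricted likelihood.
Writing V = σ²_e·H(γ) with variance *ratios* γ_r = σ²_r/σ²_e, σ²_e
profiles out in closed form and each evaluation of the profiled
restricted log-likelihood costs one Cholesky factorization of
Henderson's mixed-model coefficient matrix (size p+q ≈ 416 at trial
scale), via the identity log|V| + log|XᵀV⁻¹X| = Σ_r m_r log γ_r +
log|C(γ)|. The maximizer runs over log γ (L-BFGS-B with numerical
gradients, then a Nelder–Mead polish — the surface is smooth except at
the γ→0 boundary, which the log parameterization turns into a flat
clamp at log γ = −16; ratios ending on the clamp are reported as exact
zeros). Any REML maximizer agrees at the optimum; the test suite checks
the fit against a direct n×n-matrix likelihood on a coarse grid and
against lme4. A constant response is special-cased (all components
zero, μ̂ = the constant, log-likelihood undefined).

A design fact worth keeping in mind when reading variance components
from a trial of this shape: the block-within-environment variance is
informed by only J·K = 12 block levels (≈8 degrees of freedom after
environment means), so its REML estimate carries a sampling spread of
roughly ±50% of its value regardless of the estimator — lme4 produces
numerically identical estimates on the same data. Genotype, G×E and
residual components rest on 80, 320 and ~600 effective df and are
correspondingly tighter.

**Model comparison.** AIC = −2ℓ_R + 2q and BIC = −2ℓ_R + q·log n with q
counting variance parameters only (4 with G×E, 3 without) — the REML
convention; absolute values are not comparable across software that
includes different constants, but the full-vs-reduced ordering is. The
G×E likelihood-ratio statistic is referred to χ²(1) by default; because
σ²_ga = 0 lies on the boundary this is conservative, and the
0.5χ²₀+0.5χ²₁ mixture is available by flag.

**Heritability** is on an entry-mean basis, h² = σ²_g / (σ²_g + σ²_ga/J
+ σ²_e/(J·K)) for J environments and K replicates — the repeatability of
a cultivar's mean over the whole trial. Block variance cancels from
cultivar comparisons and is excluded.

**Adjusted phenotypes.** Y*_i defaults to the genotype BLUP ĝ_i (one
value per genotype; the scan's objective sums over genotypes).
A `plot_sum` mode — per-plot sum of all random-effect predictions plus
residual, averaged within genotype — is provided because "sum of random
effects" is ambiguous between the two; under balance both are monotone
transforms of the genotype means and rank cultivars identically.

**Genetic correlations** are Pearson correlations of per-genotype BLUPs
between traits (bivariate REML is out of scope); BLUP shrinkage makes
these mild underestimates of |r_g| when heritabilities differ.
Phenotypic correlations pair plot-level observations.

## Population structure

Covariance PCA (centered, unscaled dosages — correlation PCA by flag) of
the n × m dosage matrix, computed by SVD; explained proportions are
eigenvalues of the sample covariance over their sum across the
min(n−1, m) possibly-nonzero components. Signs are fixed by making each
component's largest-magnitude loading positive. Seven components enter
scan models by default, mirroring common practice for small panels; a
cumulative-variance rule is also provided since no numeric selection
rule is canonical.

## Quantile regression

The estimator at quantile τ minimizes Σ ρ_τ(y_i − x_iᵀβ), solved as a
linear program. The implementation solves the bounded *dual* (max yᵀa
s.t. Xᵀa = (1−τ)Xᵀ1, 0 ≤ a ≤ 1) with HiGHS — p constraints instead of
n, roughly 2 ms per fit at n = 80 and the reason a 384 SNP × 9 τ scan
takes seconds — and reads the coefficients off the equality multipliers;
the primal formulation is retained as a fallback and the reported
objective is recomputed from the residuals. HiGHS returns a vertex
(basic) solution; when the minimizer is an interval (even n,
intercept-only) the returned vertex is reported as-is, with no midpoint
convention. The dual variables themselves are reused: 1−a is the
fractional below-quantile membership (it sums to τn exactly), which
drives the scan's default test.

**Coefficient inference.** `qr_test` offers the Koenker non-iid Wald
sandwich — per-observation conditional densities from the difference
quotient of fitted quantiles at τ ± the Hall–Sheather bandwidth
(clamped into (0,1) with a warning), cov = τ(1−τ)(XᵀFX)⁻¹XᵀX(XᵀFX)⁻¹ —
and an (x,y)-pair bootstrap (normal approximation to the resampled
coefficient distribution; B ≥ 200; deterministic under a seed). When
the density-weighted design is singular in some direction (e.g. every
carrier of a rare allele receives zero density weight), the affected
coefficients report se = ∞ and p = 1 rather than a fabricated p = 0.
Both tests are asymptotically correct — the Wald se matches the
analytic sandwich at n = 5000 to 1% in the suite — but in an 80-line
panel at τ = 0.1 their far-tail calibration fails badly: measured
family-wise error of Bonferroni calls under the permutation null is
0.7–1.0 instead of 0.05. They are therefore *screening* tools here.

**Scan significance: exact conditional tail-enrichment test.** The
default p-value in `qr_scan` conditions on the below-τ tail of the
*null* fit (intercept + PCs) and tests whether that tail is enriched or
depleted in alternate alleles. With w = 1−a the membership weights and
k = τn the tail mass, the statistic s = xᵀw is referred to the exact
distribution of a dosage sum over a uniformly drawn k-subset of the
panel (trinomial hypergeometric, computed exactly; dosages rounded to
{0,1,2}). The test is two-sided (doubled smaller tail, capped at 1),
discrete, and measured family-wise valid (FWE ≈ 0.01 at the 5%
Bonferroni line over permutation nulls at 80 × 384). Its discreteness
means tied p-values across SNPs are expected, and its resolution is
bounded by the tail's combinatorics: with n = 80 and τ = 0.1 only ~8
observations sit in the tail, so even a maximally enriched tail cannot
produce arbitrarily small p-values. This is an information limit of
extreme-quantile inference in small panels, not an implementation
limit: at these dimensions *no* permutation-valid test can place a
dosage-coded scale effect far beyond the genome-wide line with high
probability. Consequences: (i) genome-wide calls are trustworthy;
(ii) power at the Bonferroni line for tail-specific effects is low at
n = 80 — the tail-vs-mean contrast is instead sharp at per-SNP levels
(≈55% detection at α = 0.05 for a strong scale effect that the mean
scan sees at its nominal size only).

**Goodness of fit.** R1(τ) = 1 − V̂_full/V̂_null with the null objective
from the intercept+PCs fit at the same τ, reported as a percentage; it
isolates the SNP's contribution beyond structure. Values are clipped at
0 against LP solver slack.

## Scans and thresholds

The mean scan residualizes y and all dosage columns on [1, PCs] once
(Frisch–Waugh) and computes every slope and two-sided t-test
vectorized; it matches per-SNP OLS exactly and underflows to p = 0 for
perfect signals (−log10 p capped at 300 for display). SNPs collinear
with the covariates are skipped and logged, and the Bonferroni m is the
number actually tested. Thresholds are −log10(α/m) at full precision
internally, truncated (not rounded) to two decimals for display —
3.8853 prints as 3.88; calls use ≥ at full precision, so exact ties are
significant. No additional correction is applied across the 9 quantiles
(the same two lines apply to every τ's Manhattan panel); users scanning
many quantiles should read near-threshold hits accordingly.

## Simulator

Genotypes: ancestral frequencies uniform on the MAF range (default
0.05–0.5), Balding–Nichols Beta perturbation per subpopulation at F_ST
(default two subpopulations, F_ST = 0.05 — visible to PCA but weak, to
mirror a lightly structured breeding panel), binomial dosages, SNPs
independent (no LD), equal-block subpopulation assignment. SNPs are
laid out contiguously over the 11 bean chromosomes at 1 Mb spacing.

Phenotypes follow the plot-level model above with equally spaced fixed
environment effects (step 2 days, centered — large enough that the
adjustment stage is exercised nontrivially). Defaults σ_g,poly = 2,
σ_ga = 1, σ_b = √0.5, σ_e = 1 (days), μ = 42, J = 4, K = 3, n = 80,
m = 384 — a days-to-flowering-like trait at the reference trial's
dimensions with strong genetic signal. Causal SNPs add x·β to the
genotype effect and scale the residual sd by (1 + x·γ), floored at 0.1
(warned when >1% of genotypes hit the floor). The scale architecture is
the canonical quantile-specific effect because its population quantile
slope is analytic, β + γσ_e·z_τ, giving the suite a closed-form oracle.

What the simulator does *not* emulate: linkage disequilibrium, dominance
and epistasis, spatial field trends, heterogeneous residual variances
per environment, genotype-level variance heterogeneity. The last point
matters for interpretation: a plot-level scale effect is largely
averaged away by BLUP adjustment over 12 plots, so tail-specific
signals that survive adjustment in real data must act at the genotype
level; passing tests on this simulator demonstrate correctness of the
machinery, not that any particular real trait harbors tail effects.

## Problem sizes used in the test suite

Estimator exactness is checked against brute-force vertex enumeration
on 100 random instances (n ≤ 12, p ≤ 2); analytic slope recovery uses
500 replicates at n = 2000; scan power and family-wise error studies
use 200 replicates/permutations at 80 × 384; REML recovery and LRT
operating characteristics use 200 balanced trials at 80 × 4 × 3 per
condition. These sizes keep the full suite within a half hour on one
CPU while leaving Monte-Carlo margins explicit in each assertion.

## Known limitations

- No kinship-based mixed-model association; structure correction is by
  PCs only, as in the reference design.
- Exact replication of historical Wald-style quantile p-values is out
  of scope: the inference method behind them is under-specified and, at
  these dimensions, anti-conservative.
- Genetic correlations via BLUP Pearson are approximations.
- No VCF/PLINK ingestion; the wide-CSV dialect targets small custom
  arrays.
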