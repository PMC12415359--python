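# Methods

This note documents the statistical models implemented in `domcode`, the
numerical choices behind them, what the synthetic data do and do not
emulate, and the known limitations.

## Codings and their HWE algebra

All analyses start from B-allele counts Z ∈ {0,1,2}. Six codings are
registered (`additive`, `het`, `carrier`, `orthogonal`, `half`, `third`);
each carries closed-form mean and variance under Hardy-Weinberg genotype
frequencies ((1−p)², 2p(1−p), p²), and the package verifies these against
probability-weighted enumeration in its test suite. Three identities
organize the family:

* Z_carrier = (Z_additive + Z_het)/2 and
  Z_orthogonal = (2p−1)·Z_additive + Z_het on every genotype class, so the
  dominance codings are linear recombinations of one additive axis and one
  heterozygote axis — they differ only in how the total genetic value is
  split between "additive" and "dominance" labels.
* cov(Z_additive, Z_dom) under HWE is 2p(1−p)(1−2p) for `het`,
  2p(1−p)² for `carrier`, and identically 0 for `orthogonal`. The
  orthogonal coding therefore yields the breeding-value / dominance-
  deviation partition; the other two let the dominance term absorb some
  additive-direction variance (and vice versa).
* `half` and `third` are affine shifts of `het`. Standardization removes
  the shift, so their standardized matrices and GRMs equal the `het` ones.
  They are resolved to `het` *before* standardization (the shift is applied
  to the raw codes, which is exact in floating point) so the equality is
  bit-identical rather than approximate, and the requested name is kept as
  an `alias` tag in the result's provenance.

Standardization always uses the theoretical moments at the supplied allele
frequency, not empirical column moments; the frequency is the sample
frequency of the full dataset at hand. In cross-validation the frequencies
and GRMs are computed once on the complete data so that training and test
blocks are sub-blocks of one consistent matrix; this matches the block
notation of the prediction equations and avoids re-deriving a different
coding per fold.

## GRMs

G = MMᵀ/m with M the standardized coding matrix. Since each standardized
column has unit theoretical variance, trace(G)/n → 1 for HWE data as m
grows, which `grm_diagnostics` reports (mean diagonal/off-diagonal, extreme
eigenvalues). GRMs are stored dense and un-ridged; any ridge needed for a
solve is added at solve time only, so diagnostics describe the matrix
actually built. Sample sizes in the low thousands keep dense algebra
comfortably within memory.

## REML

`reml_fit` maximizes the restricted likelihood of the intercept-only mixed
model with one (additive) or two (additive + dominance) GRM-structured
random effects. Updates are average-information (AI) steps with:

* an expectation-maximization warm-up iteration (robust far from the
  optimum),
* step-halving whenever an AI step would decrease the restricted
  likelihood, with an EM fallback step if halving fails,
* an active-set treatment of the boundary: components driven below the
  variance floor with a negative score are clamped at the floor and dropped
  from the Newton system, which prevents the slow EM-style crawl that
  otherwise occurs when a component (often σ²_e in small overdetermined
  problems, or σ²_d on additive-only traits) sits on the boundary.

Variance components are floored at 1e-8·var(y) rather than allowed to go
negative; convergence is declared when the restricted log-likelihood moves
by less than 1e-8 between iterations (default cap 200 iterations;
non-convergence is flagged on the result, not raised). Standard errors come
from the inverse AI matrix at the optimum. Single-GRM models are solved in
the GRM's eigenbasis, where each iteration is O(n) after one O(n³)
eigendecomposition (which can also be supplied precomputed when many
phenotypes are fitted against one GRM); two-GRM models use dense Cholesky
algebra with the projection matrix formed explicitly, fine at n ≤ a few
thousand. The reported log-likelihood is the restricted likelihood
including its constant, so nested models are comparable (A+D ≥ A is
asserted in the tests).

A point-estimation REML fitter was chosen over Bayesian Gibbs sampling for
the variance components deliberately: it is deterministic, fast enough to
re-estimate inside every cross-validation fold, and its information-based
standard errors are testable against brute-force likelihood surfaces (the
suite checks the optimum against an exhaustive grid over the variance
simplex at n = 30). Posterior standard deviations from a Bayesian fit are
not numerically comparable to these SEs.

BLUPs are ĝ_k = σ̂²_k K_k V̂⁻¹(y − μ̂) with μ̂ the GLS mean; the identity
y − μ̂ − ĝ_a − ĝ_d = σ̂²_e V̂⁻¹(y − μ̂) is used as an algebra check.
Cross-encoding Pearson correlations of ĝ_a, ĝ_d, ĝ_a+ĝ_d are classified
high (r ≥ 0.9), moderate (0.5 ≤ r < 0.9), low (r < 0.5, negatives
included).

## Genomic prediction

The two prediction equations are evaluated exactly as written (see README);
singular training systems get one ridge retry (1e-8 on the mean diagonal)
before failing. Cross-validation defaults to 5 folds × 5 repeats with
seeded partitions; variance components are re-estimated on each training
fold — the conservative choice that avoids information leakage (whether to
re-estimate per fold or reuse whole-data estimates was genuinely open; the
GRMs and frequencies, by contrast, stay whole-data as argued above).
Accuracy is the Pearson correlation between observed and predicted test
phenotypes, because that is the field's reporting convention; when ground
truth from the simulator is available, a supplementary correlation against
the true total genetic value can be recorded (`truth_total=`). A fold whose
predictions are constant contributes r = 0 with a warning.

## Two-step dominance GWAS

Step 1 fits the additive-dominance model *with the same encoding as the
scan* and removes ĝ_a from the phenotype. Using the A+D fit (rather than
the additive-only model) keeps the additive/dominance partition consistent
with the GRM used in the scan; the function accepts any `EffectVectors`, so
the additive-only variant is one call away. Step 2 estimates (σ²_d, σ²_e)
once on y_new under the dominance GRM and tests every marker by GLS with
those components fixed (P3D); re-estimating per marker would be
quadratically slower for no calibration benefit at these scales. The test
marker is not excluded from G_D (no leave-one-chromosome-out), matching the
single-G_D formulation of the model; with independent simulated markers the
resulting proximal contamination is negligible, which the null-calibration
test (KS uniformity of p-values) confirms. Monomorphic coded columns are
skipped with a logged reason. The genome-wide threshold defaults to
Bonferroni 0.05/m.

One algebraic point worth recording: under an allele-label flip
(g → 2−g, p → 1−p) the `het` column is unchanged; the additive column maps
to 2 − Z, so its effect estimate flips sign with |statistic| preserved; the
orthogonal column maps to an *affine shift* of itself (Z + (2−4p)), which
the intercept absorbs, so its effect estimate and statistic are unchanged —
not sign-flipped, as one might guess.

## Analytic power

Power of the 1-df dominance test is computed from the noncentral chi-square
model: NCP = N·var(X)·β²/σ², t the central χ²₁ critical value at α, power
= P(χ²₁(NCP) > t). Defaults (α = 0.05/47257, N = 1000, β = 1, σ² = 1)
reproduce a dense-panel regime; the frequency grid is 0.01–0.99 in steps of
0.001 with endpoints excluded because the marker variances vanish there.
Each coding's curve simply traces its var(X) profile: unimodal in p,
symmetric for `het`, equal to `het` at p = 0.5 for `orthogonal`, and lower
for `orthogonal` at extreme frequencies — which is why the heterozygote
indicator has more power for rare variants. A Monte-Carlo bridge test ties
the analytic curve to the scan: the empirical rejection rate of
`dominance_scan` at a planted effect with matched N, β, var(X) must fall
within 3 binomial SEs of the analytic power.

## Synthetic data

`simulate_genotypes` draws per-marker frequencies uniformly on a MAF window
(default [0.05, 0.5]) and genotypes i.i.d. Binomial(2, p): HWE holds
exactly and markers are mutually independent. `simulate_phenotypes` picks
`n_qtl` causal markers (default 100 of 2000 — a typical polygenic-sim
density of 5%), draws independent standard-normal additive effects on the
allele count and heterozygote effects on the 0/1/0 indicator, and rescales
so that var(g_a)/var(y) and var(g_d)/var(y) equal the targets *exactly
in-sample* (default 0.3/0.2): the residual is orthogonalized against
(1, g_a, g_d) and its variance absorbs the sampled additive-dominance
covariance, giving var(y) = 1 before the mean is added. Exact in-sample
rescaling makes recovery tests tight at desk scale; expected-variance
scaling would add target noise of order 1/√n_qtl on top of estimation
noise. Columns that come out monomorphic at small n are redrawn at the same
frequency so downstream standardization is always defined. Default sizes
(n = 1000, m = 2000) keep a full REML/CV/GWAS cycle in seconds while
leaving heritability standard errors around 0.06.

The heterozygote-indicator parameterization of the truth is deliberate: it
is the plain "extra effect of the heterozygote" and maps linearly onto
every other coding via the span identities above, so no encoding is
favored by construction beyond what the codings themselves imply.

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium (real panels tag causal
loci imperfectly; here every causal variant is genotyped), pedigree and
population structure, selection, inbreeding, non-Gaussian residuals,
effect-size/frequency coupling, and unequal dominance degrees across QTLs.
Real-data heritability and accuracy values will differ; the package's
claims on real data are structural (orderings, equivalences, calibration),
not numeric.

## Quality control

Markers are dropped for minor allele frequency below 0.01 or an exact HWE
test p-value below 1e-6 (both configurable). The HWE test is the exact
conditional enumeration over heterozygote counts (chi-square approximations
misbehave at low MAF); it is validated against an independent
log-gamma enumeration oracle. The HWE filter direction removes *low*
p-values — excluding markers that *fit* HWE would discard essentially the
whole panel, so the opposite direction is available only behind an explicit
flag. The counted allele is the first bim allele column by convention
(`count_allele2` flips), and missing genotypes fail fast unless mean
imputation is requested; proper genotype imputation is out of scope.

## Numerical conventions and degenerate inputs

* Standardization refuses columns whose theoretical variance is below
  1e-12, naming the offending markers (they should have been QC-removed).
* GRM symmetry is enforced to 1e-10 and PSD to an eigenvalue tolerance of
  −1e-8 (single-GRM path clips tiny negative eigenvalues to zero).
* The GWAS scan skips markers whose coded column is constant or collinear
  with the intercept (determinant tolerance 1e-12·a).
* p-values use the chi-square survival function, so they are exactly
  two-sided for the 1-df Wald statistic.
* All stochastic components (simulator, CV folds, per-trait effect draws)
  are seeded; per-trait streams are derived from the base seed plus a CRC32
  of the trait name so adding a trait never perturbs another trait's draw.

## Known limitations

* Fixed effects beyond the intercept are not supported (extension point).
* Two random GRM effects at most; no multi-trait or MCMC inference.
* Dense linear algebra bounds practical size to a few thousand
  individuals.
* The per-locus phenotypic-variance-explained decomposition for significant
  GWAS hits is not implemented; no published formula was adopted for it.
* X-chromosome dosage, multi-allelic sites, and VCF input are out of scope.
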