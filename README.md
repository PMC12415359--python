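# domcode

Dominance genotype encodings for genomic prediction and GWAS: build
encoding-specific dominance genomic relationship matrices (GRMs), estimate
additive and dominance variance components by REML, run GBLUP genomic
prediction with repeated cross-validation, perform two-step dominance GWAS,
and compute analytic statistical power across allele frequencies.

## Who this is for

Quantitative geneticists and animal/plant breeders who want to compare how
the choice of dominance coding changes heritability partitions, predicted
genetic values, association scans, and prediction accuracy on dense SNP
panels. Because typical livestock genotype data are proprietary, the
package ships a first-class simulator that generates Hardy-Weinberg (HWE)
genotypes and additive+dominance phenotypes with exact in-sample
heritability targets, so every analysis is reproducible end to end.

## The model

For a biallelic marker with B-allele frequency *p*, genotypes AA/AB/BB
(B-counts 0/1/2) are coded

| scheme       | codes (AA, AB, BB)   | HWE mean      | HWE variance            |
|--------------|----------------------|---------------|-------------------------|
| `additive`   | 0, 1, 2              | 2p            | 2p(1−p)                 |
| `het`        | 0, 1, 0              | 2p(1−p)       | 2p(1−p)(1−2p(1−p))      |
| `carrier`    | 0, 1, 1              | p²+2p(1−p)    | (1−p)²−(1−p)⁴           |
| `orthogonal` | 0, 2p, 4p−2          | 2p²           | 4p²(1−p)²               |
| `half`       | −1/2, 1/2, −1/2      | alias of `het` after standardization |
| `third`      | −1/3, 2/3, −1/3      | alias of `het` after standardization |

Columns are standardized by these theoretical moments at the sample allele
frequencies, M = (Z − E[Z])/√var[Z], and GRMs are G = MMᵀ/m. The additive
coding gives G_A; each dominance coding gives its own G_D. Under HWE the
covariance between the additive and dominance codes is 2p(1−p)(1−2p) for
`het`, 2p(1−p)² for `carrier`, and identically 0 for `orthogonal` — the
orthogonal coding partitions genetic values into breeding values and
dominance deviations.

Variance components are estimated by average-information REML in

    y = μ + g_a + e                    g_a ~ N(0, G_A σ²_a)
    y = μ + g_a + g_d + e              g_d ~ N(0, G_D σ²_d),  e ~ N(0, I σ²_e)

with h²_a = σ²_a/(σ²_a+σ²_e) in the additive-only model and
h²_a = σ²_a/(σ²_a+σ²_d+σ²_e), h²_d = σ²_d/(σ²_a+σ²_d+σ²_e) in the
additive-dominance model. GBLUP prediction for test individuals uses the
GRM blocks, e.g. ŷ₂ = μ̂ + (G_A21 σ̂²_a + G_D21 σ̂²_d)(G_A11 σ̂²_a +
G_D11 σ̂²_d + I σ̂²_e)⁻¹(y₁ − μ̂). The dominance GWAS is two-step: the
additive BLUPs are removed (y_new = y − ĝ_a), then each dominance-coded
marker is tested by generalized least squares under y_new = X_d b + g_d + e
with a 1-df Wald statistic (P3D: null variance components fixed across
markers). Analytic power uses the noncentral chi-square with
NCP = N·var(X)·β²/σ², where var(X) is the coding's HWE marker variance.

## Worked example

```
$ domcode simulate --n 800 --m 1500 --n-qtl 100 --h2a 0.3 --h2d 0.2 --seed 42 --out sim
wrote 800 x 1500 genotypes and 1 trait(s) to sim.*

$ domcode fit --bfile sim --pheno sim.pheno.tsv --trait trait --encoding het --model AD
model=AD encoding=het
sigma2_a=0.265215 (se 0.0813)
sigma2_d=0.305635 (se 0.0766)
sigma2_e=0.426936 (se 0.0742)
h2_a=0.2658 h2_d=0.3063
loglik=-1113.2897 converged=True iter=6
```

The additive-dominance REML fit recovers variance shares near the simulated
targets (0.3 additive, 0.2 dominance; at n = 800 the standard errors are
about 0.08, so the dominance share here sits one SE above its target). The
additive-only model on the same trait gives `h2_a=0.4110,
loglik=-1123.1671` — it absorbs part of the dominance signal into the
additive share and fits worse than the nested additive-dominance model, the
expected pattern when real dominance variance is present.

```
$ domcode gwas --bfile sim --pheno sim.pheno.tsv --trait trait --encoding het --out scan.tsv
scanned 1500 markers (skipped 0); 1 significant at p < 3.33e-05

$ domcode cv --bfile sim --pheno sim.pheno.tsv --trait trait --model AD --encoding het --folds 5 --repeats 2 --seed 7
mean accuracy over 5x2 folds: 0.2982
```

The scan finds one locus below the Bonferroni line (0.05/1500); the same CV
run with `--model A` yields 0.2340, so modelling dominance raises the
prediction accuracy on this dominance-rich trait. `domcode power` prints
each encoding's peak analytic power and `domcode study --config ... --out
...` runs the whole model x encoding comparison (heritability table, effect
correlations, CV accuracies, scans with overlap counts, power curves) into
diff-able TSVs plus a manifest.

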