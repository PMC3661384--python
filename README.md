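# drmanova

MANOVA association testing for multivariate dose-response phenotypes in
genome-wide association studies, with a full simulation and power-study
toolkit.

## Why

In cell-line pharmacogenomics a phenotype is not one number but a
*dose-response profile*: viabilities of an individual's cells measured at
d drug concentrations. The common practice of collapsing each profile to a
single summary — an IC50 or slope from a hill-equation fit, or an area
under the curve — and running a univariate ANOVA against genotype is
powerful only when the summary happens to capture the true
between-genotype difference. `drmanova` tests the whole profile jointly:
for each SNP it fits a multivariate linear model and tests the genotype
effect with Pillai's trace,

    V = tr( H (H + E)^(-1) ),

where `H` and `E` are the hypothesis and error SSCP matrices of the
genotype term (2 df genotypic coding by default, additive optional), with
the standard F approximation `F ≈ ((2n*+s+1)/(2m+s+1)) · (V/s)/(1−V/s)`,
`s = min(p, h)`. Confounding covariates (numeric or nominal) are projected
out in both models. The package also implements the four classical
univariate comparison methods (IC50, Slope, empirical AUC, pooled-
observation ANOVA), a dose-response simulator (gaussian errors with
empirical/compound-symmetric/autoregressive/independent covariance,
centred-gamma and Laplace alternatives, hill-curve populations), and a
resampling-based power and type-I-error study harness with Friedman
cross-method comparison and QQ calibration diagnostics.

Input formats are the field's standards: PLINK 1 binary genotypes
(.bed/.bim/.fam) and whitespace-delimited phenotype/covariate tables keyed
by FID/IID.

## Worked example

Simulate a 300-cell-line fixture with 12 SNPs (the first one causal for a
six-concentration viability profile), then scan it:

```sh
cat > sim.yaml <<EOF
means: {kind: synthetic_signal}
effect_size: 1.0
n: 300
n_snps: 12
EOF
drmanova simulate --config sim.yaml --out-prefix fix --seed 11
drmanova gwas --bfile fix --pheno fix.pheno.txt --covar fix.covar.txt --out results.tsv
```

`results.tsv` holds one row per SNP:

```
CHR  SNP   BP     A1  A2  N    STAT      F         DF1  DF2  P             NOTE
1    snp1  5000   B   A   300  0.186028  4.95671   12   580  7.558841e-08  .
1    snp2  10000  A   B   300  0.0425476 1.05058   12   580  4.003637e-01  .
1    snp3  15000  B   A   300  0.023797  0.582018  12   580  8.574699e-01  .
```

`STAT` is Pillai's trace for the 2-df genotype test on the 6-dimensional
profile (`s = 2`, so `0 ≤ V ≤ 2`), mapped to `F(12, 580)`. The causal
`snp1` is the only SNP below 0.05, at p ≈ 7.6e-08; the 11 null SNPs drift
across p ~ 0.09–0.99. Monomorphic or degenerate SNPs appear with
`NA` statistics and a reason in `NOTE`. Every run writes a
`*.manifest.json` (resolved options, seed, input digests) sufficient to
reproduce it bit-exactly.

The same machinery is scriptable from Python:

```python
import numpy as np
from drmanova import signal_config, simulate, evaluate_methods

ds = simulate(signal_config(effect_size=1.0), rng=np.random.default_rng(0))
for method, out in evaluate_methods(ds).items():
    print(f"{method:13s} F = {out.statistic:8.2f}   p = {out.p_asymptotic:.3g}")
```

```
MANOVA        F =     5.54   p = 3.21e-09
IC50          F =     0.53   p = 0.59
Slope         F =     0.62   p = 0.538
AUC_Emp       F =    11.31   p = 1.57e-05
ANOVA_pooled  F =    52.46   p = 4.06e-23
```

(The pooled-ANOVA F is inflated by design — it ignores within-individual
correlation; rank methods through the resampling harness, not through its
asymptotic p-values.)

Power studies and QQ diagnostics run from the same configs:

```sh
drmanova power --config sim.yaml --n-alt 200 --n-null 2000 --out-dir power_out
drmanova qq --config sim.yaml --n-reps 2000 --out qq.tsv --plot qq.svg
```

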