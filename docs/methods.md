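# Methods

## The statistical problem

In cell-line pharmacogenomics, each individual's phenotype is a
*dose-response profile*: a vector of viabilities measured at an ordered
series of drug concentrations. Classical GWAS pipelines collapse this
vector to one number per individual — an IC50 or slope from a fitted hill
curve, or an empirical area under the curve — and run a univariate ANOVA
against genotype. Whenever the true between-genotype difference is not
captured by the chosen summary, power is lost.

`drmanova` instead tests the full response vector jointly. For each SNP it
fits the multivariate linear model

    Y = X B + E,    Y : n x p  (p responses = p concentrations)

under a full design (intercept + covariates + genotype terms) and a reduced
design (intercept + covariates). With `E` the residual SSCP matrix of the
full model and `H` the extra SSCP explained by genotype, the test statistic
is Pillai's trace

    V = tr( H (H + E)^{-1} ),   0 <= V <= s,  s = min(p, h),

mapped to an F statistic by the standard approximation (exact when s = 1):

    m  = (|p - h| - 1)/2,  n* = (df_err - p - 1)/2
    F  = (2n* + s + 1)/(2m + s + 1) * (V/s) / (1 - V/s)
    df1 = s(2m + s + 1),  df2 = s(2n* + s + 1).

Genotype enters either as a 3-level factor (*genotypic*, h = 2; the
default, mirroring the two-indicator structure of the generating model) or
as the allele count (*additive*, h = 1). When only two genotype classes are
observed the genotypic design collapses to one indicator. `V` is computed
from the symmetric generalized eigenproblem `H v = theta (H+E) v` and
clamped to [0, s]; p-values are floored at the smallest positive double and
flagged rather than ever printed as 0.

Numerical safeguards: collinear covariate columns are dropped by pivoted QR
at relative tolerance 1e-8; a response block that the reduced model already
fits to machine precision (trace(H+E) below 1e-12 of the total sum of
squares) is reported as a null result rather than dividing two zeros;
monomorphic or otherwise degenerate SNPs become skipped rows with a note,
never exceptions.

## Data handling

PLINK 1 binary trios (.bed SNP-major v1.00, .bim, .fam) are decoded
directly from the two-bit codes. Genotypes are re-oriented per SNP to
minor-allele dosage, the minor allele being determined from observed
frequencies with an exact 50/50 tie resolving to allele1 (deterministic).
Phenotype and covariate tables are whitespace-delimited with FID/IID keys;
nominal covariates are dummy-expanded against the first observed level and
constant columns dropped. Alignment keeps the intersection of samples in
genotype order and applies a complete-case rule: MANOVA needs the whole
response vector, so an individual missing any concentration is dropped (and
counted, per reason, in the alignment log). Missing genotypes are handled
per SNP by complete-case subsetting. No imputation anywhere. The dose grid
is supplied as configuration (default 1..d equally spaced), never inferred
from column names.

## The four comparison methods

* **IC50** and **Slope** — each curve is fitted with the 4-parameter
  logistic on log10 dose,
  `y = Min + (Max - Min) / (1 + 10^{slope (log10 dose - log10 IC50)})`,
  and the named parameter (log10 IC50; slope) is the univariate response.
* **AUC_Emp** — trapezoid-rule area over the dose grid as given (a
  log10-dose spacing flag exists).
* **ANOVA_pooled** — all n x d observations stacked as one univariate
  response with dose as a nominal factor, genotype tested by F ignoring the
  within-individual correlation. This deliberately reproduces a
  historically used, miscalibrated analysis; its asymptotic p-values are
  only trustworthy under independent errors, which is why the power harness
  ranks methods through resampling p-values.

All four tests use the same genotypic coding as the multivariate engine, so
at d = 1 every route reduces to the identical classical ANCOVA F test
(verified to 1e-10 against an independent implementation).

### 4PL fitting

The fitter exploits the model's partially linear structure: for fixed
(log10 IC50, slope) the asymptotes solve in closed form, so a deterministic
17 x 8 multi-start grid over (log10 IC50, slope) costs four array
operations per grid point for an entire cohort, followed by
Levenberg-Marquardt refinement of the two nonlinear parameters using the
variable-projection (Kaufman) Jacobian, vectorised across curves with an
active-set that shrinks as curves converge. Noiseless curves are recovered
to better than 1e-10; a cohort of 500 six-dose curves fits in ~30 ms.

A fit is reported *failed* when the responses are flat, the fitted range
collapses, or a parameter runs to its search bound — IC50 outside
[dose_min/100, dose_max * 100] or |slope| at 50, both signatures of the
well-known 4PL runaway pathology on noisy few-dose curves. Failed fits are
excluded from the downstream ANOVA (complete case, counts logged); because
failure is independent of genotype under the null, the test remains valid,
at reduced n. On noisy six-dose curves (sigma = 0.05) roughly a quarter of
fits fail this way; the surviving median IC50 is within a few percent of
truth.

## Generating model

Phenotypes are simulated as

    Y_ijk = mu~_i + eps,   mu~_i = mu_0 + ES (mu_i - mu_0),   ES in [0, 1],

with genotypes drawn under Hardy-Weinberg equilibrium at the configured MAF
(default 0.5) and n = 500 by default. Errors are multivariate gaussian with
a configurable covariance (explicit matrix, compound-symmetric rho,
autoregressive rho^|i-j|, or independent; always verified positive
definite), or independent centred-gamma (default shape 8, scale 0.125,
variance 0.125) or Laplace components. The default Laplace scale 0.25 gives
variance 2 * 0.25^2 = 0.125, matching the gamma default so that error
families are compared at equal variance. `replicates_per_individual` is
supported and defaults to 1.

### The synthetic signal

Real estimated mean vectors and covariances for drug-response association
signals are not redistributable, so the package ships a clearly labelled
synthetic stand-in, `synthetic_signal`. Design reasoning, fixed once:

* Three monotone-decreasing 4PL mean curves over six equally spaced
  concentrations. Each minor allele shifts the curve toward resistance
  *with a change of shape*: log10 IC50 +0.08, transition steepness +0.35
  and lower plateau +0.02 per allele. The shape component reflects how a
  resistance mechanism alters the transition rather than uniformly
  offsetting viability — and it is precisely shape differences, set against
  correlated assay noise, that a joint multivariate test exploits and a
  single summary cannot.
* Covariance with per-dose SDs 0.14–0.24 (peaking mid-curve, where viability
  assays are noisiest) and correlations 0.9^|i-j| — strong between adjacent
  concentrations, decaying to ~0.6, as plate-based viability measurements
  on shared cultures typically show.

At these defaults and n = 500 the joint test's power at ES = 1 exceeds 0.99
and dominates every univariate summary, while at ES = 0.5 the ordering
(MANOVA ~0.89, AUC ~0.75, hill summaries far lower) leaves room to observe
how the ordering changes under modified correlation structures.

### Contrived 12-dose alternatives

`summary_driven_means` builds mean curves over 12 equally spaced doses in
which exactly one univariate summary differs across genotypes: a uniform
vertical offset (AUC), or a shift of the Min, IC50 or Slope hill parameter
by genotype count x shift. The base curve (Min 0.1, Max 1.0, IC50 2.5,
slope 4.0) traverses both plateaus within the dose window so that every
hill parameter is cleanly identifiable from a single curve; default
per-allele shifts (0.035 dose units for IC50, 0.15 for slope, 0.03 for
Min, 0.02 for AUC) put the tests in mid-power at n = 500 when paired with
the companion noise model, AR(0.25) correlation at sigma = 0.05. The small
sigma is deliberate: it represents a high-precision assay in which
per-curve parameter estimation operates near its efficient (delta-method)
regime. These constructions are one consistent realisation of
"difference = one summary", not a reconstruction of any published figure.

`hill_population` generates the complementary non-normal regime: each
individual's curve parameters are drawn from genotype-dependent
distributions, curves are evaluated on the dose grid and i.i.d. Laplace
noise added.

## The power/type-I harness

For each effect size, `run_power_experiment` simulates datasets and
evaluates *all* methods on the same dataset (paired design). A separate
null stream (effect size 0, disjoint seed stream derived through
`SeedSequence`) provides one null reference per method; empirical p-values
use the add-one convention `p = (1 + #{null >= stat}) / (1 + N_null)` so p
is never 0, with ties counting toward the null (conservative). Statistics
are compared on their F scale, so larger is always more extreme. The
experiment aborts if any method fails on more than 20% of replicates.
Power is the fraction of p <= alpha with binomial standard error; the
Friedman test across method columns (average ranks, tie-corrected) measures
whether methods differ systematically; `qq_data` supplies QQ pairs at
plotting positions (i - 0.5)/N plus a KS test for calibration diagnostics.
One null set is shared across effect sizes per generating model.

## What the tests show — and what they do not

The suite's study-level checks run at reduced replicate counts chosen to
keep a full run within minutes on one core while leaving 4-sigma binomial
margins: 10,000 nulls for calibration checks, 500 alternatives / 2,000
nulls for the Friedman separation, 300 alternatives / 1,000 nulls per
condition for the power orderings. They establish, on synthetic data:

* the asymptotic Pillai test is calibrated under correlated gaussian nulls
  (rejection 0.05 within ±0.0066 at 10,000 replicates);
* pooled-observation ANOVA is grossly anticonservative under strong
  compound-symmetric correlation (~0.5 rejection at nominal 0.05), while
  every method is calibrated under independent errors;
* the joint test dominates all univariate summaries on the correlated
  shape-changing signal, its advantage over the best univariate method
  shrinking monotonically as compound-symmetric correlation decays
  (~+0.22 at rho 0.75 to ~-0.04 at rho 0.25, measured at half effect size
  where nothing is saturated);
* with 12 doses, weak correlation and a difference carried by one
  well-identified hill parameter, the matching 1-summary test out-powers
  the 24-df joint test — the joint test's known weak spot.

Under independent centred-gamma errors the null statistic distribution
departs detectably from the reference F law (KS p < 0.01 at 10,000
replicates), but the departure is a distributional-shape effect: at
n = 500 the rejection rate at alpha = 0.05 itself stays within Monte-Carlo
bounds of nominal, as expected from the central limit theorem applied to
genotype-group mean vectors under skewed but light-tailed errors. A
materially inflated alpha-level error under these gamma errors is not
observed at this sample size.

Because every input is synthetic, passing tests demonstrate correctness of
the machinery and internal consistency of the simulation claims — not that
any particular real drug-response dataset satisfies the model. Real assay
data bring non-normality, batch structure, heteroscedasticity across
plates and linkage disequilibrium between SNPs, none of which the generator
emulates (covariates in real analyses are accepted but simulated
covariate confounding is out of scope).

## Defaults and units at a glance

| parameter | default | units / note |
|---|---|---|
| n (cohort) | 500 | individuals |
| d (doses) | 6 (12 for contrived alternatives) | equally spaced, ascending |
| MAF | 0.5 | HWE genotype draws |
| ES grid | 0 … 1 | 0 = null, 1 = full configured difference |
| alpha | 0.05 | rejection level |
| gamma errors | shape 8, scale 0.125 | variance 0.125 |
| Laplace scale | 0.25 | variance 0.125 (parity with gamma) |
| genetic model | genotypic (2 df) | additive available |
| replicates (full run) | 2,500 alt / 10,000 null | CLI flags scale down |

## Known limitations

* The Pillai F approximation is exact only at s = 1; at s = 2 and
  df_err ~ 500 the approximation error is negligible next to Monte-Carlo
  noise, but very small samples (df_err close to p) are untested territory.
* The 4PL fitter's failure rule discards runaway fits rather than
  constraining them; cohorts with very noisy few-dose curves can lose a
  quarter or more of individuals from the hill-summary methods.
* No kinship/mixed-model correction, no LD between simulated SNPs, no
  dosage genotypes, no PLINK 2 formats.
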