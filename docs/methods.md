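# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that are easy to miss when reading
the code.

## Fixed-model residualization

Phenotype and log2 expression are adjusted with the same fixed linear model

```
Y = G + Ba + Bo + A + e
```

with sex (G), slaughter batch (Ba) and boar (Bo) one-hot encoded (first
level dropped) plus an intercept, and age in days (A) numeric.  eQTL and
GWAS designs append the top five principal components of the
column-standardized dosage matrix.  Fitting is ordinary least squares via
`numpy.linalg.lstsq`; a pivoted QR check rejects rank-deficient designs and
names the aliased columns.  Samples with missing covariates are dropped
listwise (count logged); a warning is issued when any factor level has
fewer than 3 samples, since its effect is then poorly estimable.

Expression enters as log2(TPM + 1).  The +1 offset is a choice, not a
dogma: it is bounded, keeps zeros at zero, and the expression filter
(TPM > 0.01 in strictly more than 90% of samples, both inequalities strict)
has already removed genes near the floor where the offset matters most.
Both the offset and the filter thresholds are configurable.

## Trait–gene correlation and permutation FDR

Per gene, the product-moment Pearson r between residual expression and
residual phenotype, with the two-sided p from t = r·sqrt((n−2)/(1−r²))
against Student t with n−2 df.  Note the df convention: the t-test does not
discount the covariates already projected out, matching the
residualize-then-`cor.test` procedure the pipeline models.  The price is a
slightly anticonservative nominal p (the null fraction of p ≤ 0.05 at
n = 200 with ~13 design columns sits near 0.058 rather than 0.050); the
permutation FDR below inherits none of this, because the permuted p-values
are computed with the identical formula.

The permutation null jointly permutes the phenotype residual vector across
samples — one shuffle per round, all genes recomputed against it — which
preserves the gene–gene correlation structure and is the standard
trait-permutation null; a per-gene independent permutation scheme would give
the same marginal null at thousands of times the cost.  The FDR at an
observed p-value t is the pooled estimator

```
FDR(t) = [mean over rounds of #{perm p <= t}] / #{observed p <= t}
```

then made monotone non-decreasing in t by a step-up pass (running minimum
from the largest t downward) and clipped to [1e-5, 1].  The floor is the
resolution limit of the default 10,000 rounds; a per-gene permutation
p-value could never resolve below 1e-4 at that budget, which is why the
pooled estimator was chosen.  The permutation stream is drawn from a single
seeded generator; the seed is mandatory whenever the FDR runs.

## Association kernel (GWAS and eQTL)

One OLS kernel serves both scans, vectorized with the
Frisch–Waugh–Lovell decomposition: the response rows and the mean-imputed
dosage rows are residualized on the design once, after which each SNP is a
simple regression whose slope, SE, t and p are exactly those of the full
multiple regression (verified against statsmodels in the tests).  Dosage is
additive 0/1/2 with no dominance term; monomorphic SNPs are flagged and
skipped; missing dosages are mean-imputed inside the kernel only — the
stored matrix keeps its missing values.  Alongside the slope the kernel
reports the signed model correlation r = sign(t)·sqrt(t²/(t²+df)), the
statistic printed by MatrixEQTL-style tools.

For GWAS the phenotype is standardized to unit variance ("normalized"); a
rank-based inverse-normal transform is available as a switch.  cis/trans
classification uses the symmetric distance from the SNP to the gene body
[start, end] with a 1 Mb default window, boundary inclusive; strand is read
but ignored.  BH FDR is applied within the cis and trans scopes separately,
since the two p-value populations have very different densities.  The
genome-wide GWAS threshold is Bonferroni α/m over the tested panel.

## Allele-specific expression

Only heterozygous (dosage = 1) sample–site pairs with ≥ 10 reads are
tested: exact two-sided binomial test of the reference fraction against
p0 = 0.5, BH across each site's samples, flag at adjusted p ≤ 0.05.  A gene
is summarized by its reporting site — the one with the most testable
heterozygotes, ties broken by smaller median p, then SNP id — as het_n,
ase_n and ratio = ase_n/het_n.  Reference-mapping bias is not modeled
(upstream pipelines handle it with N-masked alignment); instead p0 is an
exposed knob.  In the pipeline a gene counts as an "ASE gene" for overlap
purposes when ase_n ≥ 2 (configurable): requiring two independently
imbalanced heterozygotes makes a false ASE gene need two site-level false
positives, keeping the gene-level false rate near zero while costing no
power at realistic depths.

## Preranked GSEA

Genes ranked by Pearson r descending; hit increments |r|^1 normalized by
the in-set sum, miss decrements 1/(N−Nh); ES is the running-sum extremum.
The null permutes gene labels (random same-size sets on the fixed ranking),
matching preranked practice.  NES = ES / mean(|null ES of the same sign|);
the FDR compares, per sign, the pooled normalized-null tail beyond each
observed NES with the observed tail; significance at FDR < 0.25.  Gene sets
come from GMT files; no curated collections are bundled — the simulator
emits toy sets (the planted positively/negatively correlated genes plus
random sets) for testing.

## Integration

Overlaps are exact set intersections with sorted membership lists; the
trans overlap is restricted to *specific* trans genes (trans signal, no cis
signal).  A SNP–gene–trait triple requires the identical marker to pass all
three filters — correlation permutation FDR ≤ 0.01, eQTL BH FDR < 0.05,
GWAS p ≤ 1e-3 — all configurable; the eQTL FDR cutoff of 0.05 was inferred
from the magnitude of the largest eQTL FDR such integrations report in
practice.  Nearest-correlated-gene assignment for a genome-wide lead SNP
minimizes interval distance on the same chromosome within 2 Mb, ties broken
by smaller correlation FDR then gene id.

## Synthetic-data generator

Defaults emulate the target study: 189 animals, sex/4 batches/8 boars,
age 210 ± 6 days uniform, phenotype mean 3.35 with residual SD ≈ 1.16 of
which qtl_h2 = 0.2 is genetic; SNPs in Hardy–Weinberg proportions at MAF ~
U(0.05, 0.5), drawn independently (no LD); planted trait–gene correlations
with magnitudes U(0.20, 0.37) (the range such analyses detect at this n),
random sign; cis effects of 1.0 on log2 expression from a SNP within 50 kb;
trans effects from a SNP on another chromosome; ASE tag sites inside gene
bodies with reference fraction 0.8 at mean depth 30, plus balanced null
sites so the false-positive rate is measurable.  Gene residual SD in log2
units is 0.5.  Covariate coefficients for phenotype and every gene are
drawn once per simulation and recorded, so residualization tests have a
known answer.

When correlated, cis and QTL effects are all requested, the generator
plants one *triple*: the first correlated gene is also the first cis gene
and its cis SNP doubles as the first QTL.  That gene's correlation sign is
forced positive — with a positive cis slope and a positive QTL weight the
dosage channel adds positive trait–gene correlation, and a negative planted
rho would destructively interfere, leaving a "planted" triple that no
method could (or should) recover.

What the generator does not emulate: linkage disequilibrium and population
structure (so genotype PCs capture nothing real and the PC adjustment is
exercised only mechanically), read-level noise (TPM is exponentiated
Gaussian, not count-based), reference-mapping bias, polygenic background
beyond the planted QTLs, and LD-induced clumping of GWAS signals.  Passing
tests therefore demonstrate the estimators are correct and calibrated under
clean conditions, not that the pipeline is robust to confounding in real
data.

## Problem sizes and numerical choices

The test suite and the acceptance script scale simulations to what the
statistics need rather than the study's full dimensions: calibration checks
use 200 samples with 1000–2000 genes or 2000 SNPs over 10–25 replicate
seeds; recovery checks use 200–300 genes; in-test permutation FDRs use
500–2000 rounds (the estimator is identical to the 10,000-round production
default, only the floor resolution differs).  All randomness flows from
explicit seeds through `numpy.random.default_rng`; reruns of the pipeline
with an identical config are byte-identical, which the suite asserts
file-by-file.  Result TSVs serialize p-values and FDRs in scientific
notation with 3 significant digits and ratios with 2 decimals;
re-serializing a read-back table is byte-identical, so downstream diffs are
meaningful.

Degenerate inputs are handled explicitly rather than silently: zero-variance
genes are flagged and excluded from FDR; monomorphic SNPs are flagged and
skipped; zero-coverage ASE pairs are dropped; gene sets covering none or
all of the ranking are an error; exact fits (zero residual variance) report
p = 0 and |r| = 1.

## Known limitations

The permutation FDR estimator is a plug-in pooled estimator, not a
per-gene adaptive one; with few tested genes it is coarse.  The eQTL scan
is all-pairs and dense — fine for chip-scale panels, not for sequencing-
scale ones.  The GSEA FDR follows the standard pooled positive/negative
procedure and shares its known conservatism when set sizes are few.  ASE
testing assumes counts at a site are independent across samples and ignores
overdispersion; a beta-binomial would be the next step.
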