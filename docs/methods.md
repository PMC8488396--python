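# Methods

## The evaluation model

Every stage fits or conditions on the animal model
`y = Xb + Za + Wc + e` with one record per fish: `X` carries an intercept
and drop-first dummies for sex and batch, `Z` maps records to the rows of a
relationship matrix `K`, and `W` maps records to rearing aquaria. The three
random terms are independent normals with variances
`sigma_a^2` (additive genetic, covariance structure `K`), `sigma_c^2`
(common environment, one level per aquarium) and `sigma_e^2` (residual).
Heritability is `sigma_a^2` over the sum of the three;
the common-environment ratio `c2` is defined analogously. The
common-environment term is dropped automatically when the grouping has a
single level, and is excluded by construction from the association scans.

Assumptions worth stating explicitly: traits are Gaussian after fixed-effect
adjustment; aquarium effects are exchangeable across aquaria (no tank
position/system structure); a single record per animal (no repeated
measures); and genotypes, where used, are biallelic autosomal SNPs.

## Relationship matrices

* **A** (pedigree) uses the tabular method on a topologically sorted
  pedigree; unknown parents contribute zero, so founders are assumed
  unrelated and non-inbred.
* **G** (genomic) is the cross-product of dosages centred at twice the
  observed allele frequency, scaled by total heterozygosity. Monomorphic
  SNPs are excluded from both numerator and denominator; missing calls are
  set to the centring value, contributing nothing. With observed
  frequencies the centred columns each sum to zero, so **G is always
  singular** (the ones vector is a null vector). Wherever an inverse is
  needed (mixed-model equations, the single-step formula) the package
  checks conditioning on the Cholesky factor and blends
  `(1-eps) G + eps I` with `eps = 0.01` only when required; the blend used
  is the same everywhere in a run, so GBLUP and ssGBLUP coincide exactly
  when every animal is genotyped.
* **H^-1** (single-step) adds `G^-1 - A22^-1` to the genotyped block of
  `A^-1`, ordering non-genotyped animals first; the returned id list is the
  ordering contract. No tau/omega weighting and no G-to-A22 rescaling is
  applied.

## REML

Variance components maximise the restricted likelihood by
average-information steps with step halving; whenever no damped AI step
improves the likelihood, an EM-style fixed-point update
(`theta_i <- theta_i * y'P C_i P y / tr(P C_i)`) is taken, which cannot
leave the parameter space. Variances are floored at `1e-8` of the
phenotypic variance; convergence is a relative log-likelihood change below
`1e-8` within 200 iterations, and non-convergence is flagged, never
silent. Standard errors of `h2` and `c2` come from the delta method on the
inverse of the final average-information matrix (the reference programs in
this area report SEs but not their method; the delta method is this
package's choice).

The bivariate fit stacks two traits with unstructured 2x2 genetic and
residual covariance blocks and a diagonal common-environment block (the
simulator draws aquarium effects independently per trait, and a shared
aquarium covariance would be weakly identified at these sizes). Covariance
starting values use the phenotypic correlation of the shared animals.
Non-PSD iterates of either 2x2 block are bent back by eigenvalue clipping
and flagged. When one trait's genetic variance collapses to the boundary
the genetic correlation is unidentified: the estimate is clipped to
[-1, 1] and its delta-method SE diverges, which is the honest outcome for
such datasets.

Breeding values solve Henderson's mixed-model equations at the estimates,
working from `K^-1` so the single-step inverse is used directly; EBVs are
returned for every animal in the kinship, phenotyped or not.

## Cross-validated prediction accuracy

Fivefold validation, two designs: `random_animal` partitions fish,
`random_family` partitions whole full-sib families (training and validation
then share no family). Per fold the validation phenotypes are removed from
the right-hand side, EBVs are re-predicted, and accuracy is
`r(EBV, y*) / h` on the held-out fish, with `y*` the phenotype minus the
full-data fixed-effect estimates (a raw-phenotype mode exists behind a
flag) and `h` from the full-data fit of the same model. Variance
components are, by default, estimated once on the full data and held fixed
across folds (refitting per training fold is available and logged); the
replicate-level, fold-averaged accuracies feed the model comparison
(Shapiro-Wilk normality per model, paired t-tests, Bonferroni adjustment
by the number of pairs, significance tiers at 0.05 / 1e-3 / 1e-5).

One convention matters under the default one-generation pedigree: when a
whole family is held out, its pedigree EBVs are exactly constant (the
equations contain no path from training phenotypes to the held-out block),
and the correlation of a constant predictor is undefined. Accuracy is
defined as 0 in that case — no ranking ability. A deep multi-generation
pedigree, which the simulator does not re-create, is what gives
pedigree-only evaluations their residual between-family accuracy in real
programs.

## Association scans

The scan is mixed-linear-model association with leave-one-chromosome-out
kinship: for each chromosome, variance components are re-estimated once
with `G` built from all other chromosomes, each SNP on the left-out
chromosome is added as a fixed covariate, and its GLS estimate is Wald
tested. SNPs without a reference position are collected on an artificial
chromosome and tested against the kinship of all placed chromosomes.
Thresholds are Bonferroni at alpha = 1 (suggestive) and alpha = 0.05
(genome-wide) over the tested SNP count. QTL windows extend 250 kb either
side of a significant SNP (coordinates 1-based inclusive; BED annotation is
converted on input), list overlapping features by any-overlap, and clip the
left bound at zero.

## Quality control

The cascade order is: sample call rate, then the SNP rules (call rate,
MAF, exact Hardy-Weinberg test) on the post-sample-filter data, then
duplicate removal. All thresholds are strict inequalities (call rate
< 0.95, MAF < 0.05, HWE p < 1e-6, PI_HAT > 0.7). MAF-after-sample-filter
is the default and configurable, since the two orders differ. The HWE test
is the exact conditional test (sum of probabilities of heterozygote counts
no more probable than observed, given the allele counts) — robust at the
rare-genotype counts that matter near the MAF boundary. Pairwise IBD uses
method-of-moments estimation from IBS counts; the allele-frequency product
moments are estimated by unbiased falling-factorial estimators rather than
plug-in frequencies, removing the finite-sample inflation of PI_HAT between
unrelated animals. State probabilities are truncated to [0, 1] and
renormalised, so PI_HAT between unrelated pairs is slightly positive on
sparse panels (the truncation bias shrinks with SNP count); both members of
any pair above the threshold are removed. PCA mean-imputes missing calls
per SNP (never writing imputations back), standardises, and reports percent
variance explained.

## The population simulator

The simulator emulates the recording design the analysis assumes: by
default 40 full-sib families from single-pair matings, 30 offspring per
family split over two 15-fish aquaria, four batches, two sexes, ~5 K SNPs
on 23 chromosomes plus a small unplaced set, trait means/SDs, per-trait
heritabilities (0.12-0.22), common-environment ratios (0.05-0.07) and the
genetic correlation matrix in the ranges estimated for feed-efficiency
traits with genomic relationship matrices. Raw measurement columns are
generated consistently with the simulated traits: start weights are drawn
positive, end weight = start + simulated BWG, and the simulated FI is
converted to integer pellet counts (16.4 mg per pellet) distributed over 13
meals, so the trait-derivation stage can recompute FI/BWG/FCR/RFI from raw
data. A TruthRecord stores every breeding value, effect and variance.

Two genome-model choices matter and are deliberate:

* **Linked gene-drop.** Transmission is by recombination mosaic (Poisson
  crossovers, one Morgan per placed chromosome; unplaced SNPs segregate
  independently). Independent per-SNP transmission would make marker
  subsets unable to track realized kinship at causal loci, erasing the
  marker-density plateau that motivates reduced panels.
* **Finite founder haplotype pool.** Founder chromosomes are drawn from 40
  ancestral haplotypes per chromosome, giving the haplotype-block LD of a
  closed, long-selected breeding strain; linkage-equilibrium founders are
  available via `founder_haplotypes=None`.

Per-SNP effects are drawn multivariate normal across traits with the
target correlation matrix and the per-trait breeding values rescaled to the
exact target genetic variance; planted QTL receive their stated fraction of
genetic variance through a single SNP effect. Attrition removes a uniform
random subset, never emptying a family unless the rate forces it.

What the simulator does not emulate — and hence what passing tests do not
show about real data: genotyping error and platform artefacts (QC
violations are planted, not emergent), selection and multi-generation
pedigree depth (founders are unrelated; real pedigree evaluations gain
between-family accuracy from deep pedigrees), aggression-structured
mortality, compensatory growth, non-Gaussian trait distributions, and any
real linkage map or gene annotation.

## Problem sizes in the test and acceptance runs

The checks run at desk scale, chosen so the full suite and the acceptance
script each finish in minutes on one CPU: REML recovery uses 30 simulated
datasets of 20 families (600 fish, 2 000 SNPs) for the univariate model
and 10 datasets of 14 families for the bivariate genetic correlation;
design-ordering cross-validation uses 20-family populations, and the
genomic-vs-pedigree contrast uses six 40-family populations (1 200 fish)
with six replicates each; the null association scan uses 5 000 SNPs on 10
chromosomes, and QTL power 20 datasets with a variant explaining 15% of
phenotypic variance; the density experiment runs on a 50 000-SNP panel so
that the 10% fraction corresponds to the ~5 K-SNP plateau, with the
full-panel heritability reused at every density.

## Known limitations

Dense linear algebra throughout: pedigrees and panels beyond a few
thousand animals would need sparse `A^-1` (Henderson's rules) and
iterative solvers. No multi-trait (>2) REML, no Bayesian alternatives, no
genotype imputation, and the association scan fits one SNP at a time (no
conditional or multi-SNP analysis). The single-step inverse is the
unweighted textbook formula; compatibility scaling between `G` and `A22`
(tau/omega) is not implemented.
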