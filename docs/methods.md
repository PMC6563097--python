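# Methods

`kinmeth` analyzes reduced representation bisulfite sequencing (RRBS) count
data from designs where the sampled individuals are related — families of
full and half sibs split across treatments, as in hatchery-versus-wild
rearing experiments on salmonids.  Relatedness is a first-order nuisance in
such designs: siblings share methylation patterns for genetic reasons, so a
treatment that is unevenly distributed over families will generate spurious
methylation associations unless kinship enters the model.

## The site-level model

For one CG site with methylated counts `y_i` out of `r_i` reads in samples
`i = 1..n`:

    y_i ~ Binomial(r_i, pi_i)
    logit(pi_i) = W_i a + x_i b + g_i + e_i
    g ~ MVN(0, sigma_g^2 K),   e_i ~ N(0, sigma_e^2)

`x` is the 0/1 predictor (rearing group, or timepoint for the developmental
contrast, where rearing group moves into the covariates `W`).  `K` is the
genetic relatedness matrix; `g` captures heritable covariation among
relatives and `e` captures independent extra-binomial dispersion, so the
marginal distribution of the counts is beta-binomial-like.  All parameters
are estimated independently per site; there is no information sharing
across sites.

### Estimation

The random-effect vector is integrated out by a Laplace approximation.  For
fixed variance components, the joint mode over the fixed effects and the
n-vector of random effects is found by damped Newton iterations (gradient
tolerance 1e-8, step halving, at most 100 iterations).  The outer search
over `(log sigma_g^2, log sigma_e^2)` maximizes a REML-style Laplace
criterion — the fixed effects are integrated out as well, adding a
`-0.5 log det(X' V^-1 X)` term to the marginal log-likelihood.  The REML
form matters: in confounded designs the predictor is nearly collinear with
the family random-effect space, and plain ML lets the variance components
collapse toward zero while the fixed effect absorbs family variance, which
destroys type-I error control.  The outer optimizer is Nelder-Mead with a
1e-6 function tolerance; both inner solutions are warm-started across
outer evaluations.  Variances fixed at zero reduce the fit to an ordinary
binomial GLM, which is tested against statsmodels.

### Inference

The predictor effect is tested by a Wald statistic with a
t(df) reference where df comes from a Satterthwaite approximation:
`df = 2 v^2 / (g' A g)` with `v = Var(b_hat)` from the joint Hessian at the
mode, `g` its finite-difference gradient in the active (non-boundary) log
variance components, and `A` the inverse finite-difference Hessian of the
REML criterion.  When a variance component sits at its boundary it carries
no curvature and is excluded; if no usable curvature remains the df falls
back to `n - p`.  This matters in family-nested designs, where the
effective replication is closer to the number of families than the number
of samples.  Sites that fail to converge, have fewer than 4 informative
samples, or a constant predictor are flagged and excluded from FDR control
(counts are logged).

On simulated null data from full-sib families with `sigma_g^2 = 0.5` and
four of five families nested within rearing group, this combination holds
the empirical p<0.05 rate near nominal, while refitting the same data with
`K = I` inflates it by roughly a factor of 1.7 — the quantitative version
of "ignoring kinship produces spurious associations".

### Accuracy checks

The Laplace fit is validated against two independent oracles: exact
marginal-likelihood estimation by adaptive Gauss-Hermite quadrature
(tensor-product rule recentered at the integrand mode and rescaled by its
curvature; 5 nodes per dimension at n = 6, converged to 4 decimals against
7 and 9 nodes), and a beta-binomial regression fit when `sigma_g^2 = 0`.
Agreement is within 0.05 on the logit scale in both cases at moderate
coverage (30 reads).  The Laplace point estimate carries a small
attenuation (~5-8% at `|b| = 1`, n = 60), which is visible in the recovery
simulations and inherent to mode-based approximations of logistic mixed
models.

## Multiple testing

Storey q-values: `pi0` is estimated on the grid `lambda = 0.05..0.95`
(step 0.05) via `pi0(lambda) = #{p > lambda} / (m (1 - lambda))`, smoothed
by a cubic least-squares fit and evaluated at `lambda = 0.95`, clamped to
(0, 1].  q-values are the usual step-up quantities scaled by `pi0`; with
`pi0 = 1` the procedure is exactly Benjamini-Hochberg (verified against
statsmodels).  A site is a DMC when `q < 0.10`, strictly — a q-value equal
to the threshold is not called.

## Filtering

The cascade runs in a fixed order, each step reported with its remaining
CG count:

1. **Coverage**: within each predictor group, at least half of the samples
   must have depth > 10 (i.e., >= 11 reads).  Both the fraction and depth
   are parameters; the default reading treats the depth rule as applying
   inside the per-group half-of-samples rule.
2. **Low variance**: drop sites at or below the 5% quantile of the
   per-site sample variance of methylation proportions.  The quantile uses
   the lower-interpolation convention and ties at the cutoff are dropped
   together (pinned by a sort-based oracle test).
3. **Hypo/hyper methylation**: drop sites with mean methylation <= 0.10,
   then >= 0.90; bounds inclusive; means are unweighted means of
   per-sample proportions, not pooled counts.
4. **C/T SNP masking**: a site is removed if either position of its CG
   dinucleotide (pos or pos+1) appears in the supplied SNP position set,
   since a C-to-T variant is indistinguishable from unmethylated cytosine
   after bisulfite conversion.

Bisulfite conversion efficiency is estimated from non-CpG-context counts
(`1 - meth/total`), and batches are compared with a Welch two-sided t-test.

## Relatedness

Two estimators share the `KinshipMatrix` container:

- **Pedigree**: the numerator relationship matrix by the recursive tabular
  method (full sibs 0.5, half sibs 0.25, diagonal 1 for non-inbred
  individuals).  Used as the generative truth and available when parentage
  is known.
- **Genotypes**: the allele-frequency-centered genomic relationship matrix
  (VanRaden's first form), `G = ZZ' / (2 sum p(1-p))` with `Z` the dosage
  matrix centered by `2p_hat` per SNP; monomorphic SNPs dropped, missing
  genotypes contributing zero after centering.  The matrix is then
  PSD-stabilized by the smallest diagonal inflation from
  {0, 1e-6, 1e-4, 1e-2, 1} that makes all eigenvalues non-negative, since
  the mixed model requires a valid covariance.  With 95 informative SNPs
  the mean estimate over full-sib pairs lands near the pedigree value 0.5,
  and the correlation with pedigree expectations rises with panel size.

Parentage assignment evaluates every dam x sire pair by the product over
SNPs of Mendelian transmission probabilities under a per-genotype error
model (observed = true with probability 1-eps, else uniform over the other
two states; eps defaults to 0.01), reporting the maximum-likelihood pair
plus its Mendelian exclusion count.  Ties are broken by exclusion count
then lexicographic parent ids, and flagged.

## DMR calling

A region qualifies if either (1) a 2 kb window centered on a DMC contains
at least two CGs with p <= 0.001, the DMC included, or (2) at least three
CGs with p < 0.001 span at most 2 kb (maximal runs found by a sorted
two-pointer sweep).  The inclusive/strict asymmetry between the two
criteria is deliberate and pinned by boundary tests.  Qualifying regions
whose contributing CG sets overlap are merged; the reported span is the
min-max of contributing CG positions, which is why DMR spans are typically
far below 2 kb.  The caller is verified exactly equal to an O(n^2)
enumeration on 1,000 randomized instances with p-values and spans
concentrated at the boundaries.  A consequence of merging is that a merged
span can in principle exceed 2 kb; equivalence with the enumeration oracle,
not a span cap, is the invariant enforced.

## Annotation and enrichment

Features (DMCs or DMRs) are associated with every gene whose span extended
by 10 kb they intersect (inclusive at exactly 10 kb), using an interval
tree.  The signed distance is 0 inside the gene body, negative upstream of
the transcription start and positive downstream of the end, strand-aware.
Enrichment is a one-sided Fisher exact test per gene set against a
user-supplied background (genes near any analyzed CG), with a set passing
only when p < 0.05 *and* it has at least 3 foreground hits.  Gene sets are
read from GMT files; no pathway database ships with the package.

## Global patterns

Sample-level analyses use methylation proportions at complete-case sites.
Distances are Euclidean or 1 - Pearson correlation (default); clustering
is average-linkage (scipy), exportable as Newick with branch lengths; PCA
is SVD on the column-centered proportion matrix.  ANOSIM uses tie-averaged
ranks of all pairwise distances, `R = (rb - rw) / (M/2)`, and a seeded
label-permutation p-value with the +1 correction (minimum attainable p is
`1/(n_perm+1)`).  The statistic is checked against scikit-bio.

## Synthetic data

The generator is the study-design mirror the tests run on.  Defaults: 22
families (one shared-sire and one shared-dam half-sib pair among them),
offspring split evenly between hatchery and stream groups, 95 SNPs with
MAF ~ U(0.2, 0.5), 2,000 CG sites, 10% effect sites at `|b| = 1` on the
logit scale with random sign (field data show hyper- and hypomethylated
DMCs in comparable numbers), `sigma_g^2 = sigma_e^2 = 0.5`, zero-truncated
negative-binomial coverage with mean 30 and dispersion 5, 5% per-cell
dropout, and 2% of CG sites carrying a segregating C/T SNP whose genotype
(dropped through the pedigree) dictates apparent methylation (~1/0.5/~0).
A scalar non-conversion rate (0.005) adds spurious methylation.  The
`confounded_families` option nests that many families wholly within
alternating rearing groups — the regime in which the kinship random effect
earns its keep.

Baseline methylation profiles: liver is a bimodal mixture (40% near 0.05,
40% near 0.95 on the proportion scale, 20% intermediate); sperm is
constitutively hypermethylated (95% of sites with baselines in
0.96-0.998).  These choices reproduce the qualitative filtering behaviour
of the two tissues: the hypermethylation filter removes >= 90% of covered
sperm sites but well under half of liver sites.

Simulated per-site depth is a free model: real RRBS depth distributions
are fragment- and digestion-structured in ways the negative binomial does
not capture, and coverage parameters here are knobs, not calibrated
values.  Other realism limits: no genome sequence, no read-level errors,
no strand structure, no correlated methylation between neighbouring CGs
beyond the shared random effects (so simulated DMRs arise only through
per-site effects), and missingness is independent per cell.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to everything real libraries do.

The generative model is exactly the model the tester fits, which makes
parameter recovery well-posed: recovery simulations measure estimator
quality, not model misspecification.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 50 six-sample
instances for the quadrature comparison; 2,000 null sites on 20 samples
(type-I error); 2,000 sites with 200 effect sites on 60 samples
(recovery); 1,000 random DMR instances; 5,000 uniform p-values; the
default 22-family design for parentage (88 offspring, 95 SNPs); a fixed
500-site fixture for the filter cascade; 4,000-site tissue-profile
datasets; and a 32-sample, 600-site sperm dataset for the family-signal
check.  These sizes give Monte-Carlo error comfortably inside the asserted
bands while keeping the whole suite desk-fast.

## Known limitations

- The Laplace point estimate of `b` is mildly attenuated at low coverage
  or extreme baselines; the recovery band (±0.15 at `|b| = 1`) reflects
  this.
- Per-site variance components from n ≈ 20 samples are noisy; the
  Satterthwaite df absorbs most but not all of the resulting inference
  error (residual type-I rate ~0.06 at nominal 0.05 in heavily confounded
  designs).  The same residual shows up in the far tail as realized FDR of
  roughly 0.13-0.16 at a nominal q < 0.10 in the recovery simulations.
- CpGs on opposite strands are not merged into dinucleotide units; the
  pipeline operates per position.
- The filter cascade's coverage rule has two defensible readings (depth
  within the per-group rule, versus an additional median-depth rule); the
  first is the default and both are expressible through parameters.
- Criterion 1 of the DMR rule ties the 0.001 threshold to the window
  contents including the anchoring DMC itself; alternative readings of the
  ambiguous rule are noted in code comments but not implemented.
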