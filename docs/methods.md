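# Methods

`snps2genes` implements a case-control "SNPs-to-genes" analysis chain: a
synthetic imputed-dosage cohort generator, cohort quality control, adjusted
single-marker/haplotype/diplotype association, three gene-based tests under
BH-FDR, and GO enrichment with directed-acyclic-graph decorrelation. This note
records the models, the defaults and why they hold, the numerical choices, and
the limits of what the synthetic experiments demonstrate.

## The synthetic cohort generator

Real imputed genotype cohorts of this kind are rarely redistributable, so every
stage of the package is exercised against a generator whose ground truth is
known exactly.

**Haplotype model.** Each LD block has a pool of `n_founders` founder
haplotypes; a sampled chromosome copies one founder and switches to a freshly
drawn founder between adjacent SNPs with probability `recomb_rate`. This
"founder mosaic" was chosen over Gaussian-threshold LD simulation because the
haplotypes are discrete, enumerable objects: a haplotype-association test can be
checked against the exact founder identity, and the block's LD matrix has a
closed form (the founder-pool correlation) that the cohort must reproduce.
Founder sampling weights default to equal frequency; a block may specify
`founder_weights` to realise haplotype frequencies off the k/n_founders grid
(for example an H2-like haplotype at frequency 0.22). Each SNP's carrier set
among founders is chosen so the induced allele-1 frequency lies in `maf_range`,
keeping allele 1 the minor allele by construction.

**Disease model and ascertainment.** Status is Bernoulli with

    logit P(case) = baseline_logit + sum_j log(OR_j) g_j + log(OR_sex) 1[female]
                    + sum_k structure_effect_k a_k
                    [+ log(OR_hap) x haplotype copies + log(OR_dip) x 1[homozygote]]

on minor-allele dosages g_j. Cases and controls are quota-sampled from this
population model (retrospective ascertainment), which leaves the covariate-
conditional odds ratios identifiable by logistic regression — the property all
recovery experiments rely on. `baseline_logit` defaults to -4 (rare disease),
making odds ratios approximate risk ratios; the quota sampler aborts with a
clear error when the prevalence implied by `baseline_logit` makes a quota
unreachable.

**Structure.** With `n_structure_axes >= 1`, samples split into two
subpopulations whose founder weights diverge by a Balding–Nichols-style
Dirichlet draw with concentration (1 − F)/F per founder, F = `fst` (default
0.02, a typical within-European value). Axis 1 of the disease model is the
centred subpopulation indicator; any further axes are N(0, 1) covariate scores
with no genetic footprint (the generator models one genetic axis; extra axes
exist to exercise covariate plumbing).

**Imputation quality.** Each SNP gets an Rsq drawn uniformly from `rsq_range`;
it is metadata for the QC filter. With `rsq_noise=True` dosages are additionally
shrunk toward 2·MAF with variance (1 − Rsq)·2·MAF·(1 − MAF) and clipped to
[0, 2], emulating the variance loss of imputed dosages.

**What the generator does not emulate:** coalescent genealogies, realistic
recombination maps or allele-frequency spectra, X-chromosome dosage, genotyping
batch effects, and imputation from reference panels. Passing tests therefore
demonstrate correctness of the statistics under a controlled LD/effect model,
not robustness to every artefact of real array data.

## Quality control

Markers: drop MAF < 0.01 or Rsq < 0.80 (boundaries retained). Samples:
structure PCA on dosages centred and scaled by sqrt(2p̂(1−p̂)) after greedy LD
thinning (r² < 0.2 in 50-SNP windows); outliers are samples beyond 6.0 SD on
any retained axis, iterated to a fixed point (max 5 rounds); relatedness by the
method-of-moments IBS→IBD estimator with PI_HAT = P(IBD=2) + P(IBD=1)/2,
removing one member of each pair above 0.1875 (midpoint of 2nd/3rd degree; the
member with the lower call rate). The estimator plugs in sample allele
frequencies without small-sample corrections, so its noise scales as
1/sqrt(markers); the pipeline skips the all-pairs screen below 500 markers
rather than flag unrelated pairs. PCA axis signs follow the convention that the
largest-magnitude loading is positive, making axes reproducible up to data,
not solver, choices.

## Single-marker and haplotype association

Per-SNP tests are Wald tests from a Newton-fitted logistic regression of status
on dosage with an intercept and caller-supplied covariates (sex plus four PCs
in the standard pipeline). Separation or non-convergence yields a flagged
result, never an exception, so genome scans do not die on degenerate markers.
Constant covariate columns are dropped (they duplicate the intercept). Wald
rather than likelihood-ratio tests match conventional GWAS output (OR with 95%
CI from exp(beta ± 1.96 se)).

Haplotype association enumerates observed haplotypes over a SNP set from known
phase (frequency ≥ 0.01 by default) and tests each additively (carrier count
0/1/2 vs all others) in the same adjusted logistic model, reporting case and
control haplotype frequencies. EM phasing is out of scope: phase comes from the
generator or pre-phased input. Diplotype classification for a two-haplotype
tag system labels each chromosome by majority vote over the tag alleles (so
isolated recombinants are kept, with a warning and count), then tests each
diplotype class as an indicator against the rest.

The sex-stratified analysis reports per-stratum fits plus a pooled model with a
sex × dosage product term; the interaction OR estimates OR(female)/OR(male), and
the plain ratio of stratum ORs is reported alongside because that ratio is the
conventional summary. Whether to adjust the interaction model for ancestry PCs
is left to the caller; the default mirrors the single-marker adjustment.

Suggestive tiers: tier 1 is p ≤ 1e-5; tier 2 is the follow-up band
1e-8 < p < 1e-4. The second band's bounds are deliberately ordered this way —
the convention it follows prints the band with its endpoints transposed.

## Gene-based tests

SNPs map to a gene when within its range ± 5 kb (1-based, boundaries
inclusive, strand ignored); a SNP may serve several overlapping genes.

**GATES.** SNP p-values are sorted ascending; the genotype correlation matrix
(Pearson r of dosages, a composite-LD surrogate) is mapped to a p-value
correlation matrix through the published sixth-order polynomial
0.2982r⁶ − 0.0127r⁵ + 0.0588r⁴ + 0.0099r³ + 0.6281r² − 0.0009r; the effective
number of tests is m_e(j) = j − Σ max(λ_i − 1, 0) over eigenvalues of the
leading j × j submatrix; the gene p is min_j m_e · p_(j) / m_e(j), clipped to
(0, 1]. With identity LD this is exactly Simes' procedure, an equality the test
suite enforces to 1e-10. SNPs at MAF ≤ 0.01 are pruned first (strict
inequality).

**Supervised PCA.** After the same MAF pruning, SNPs are ranked by the fitted
log-likelihood of a univariate logistic model (vectorised Newton across
columns) and the top 25% retained (ceil, minimum one; ties to the lower
index). The retained dosages are standardised; the first right-singular-vector
score (the "eigengene") is tested in a logistic regression, unadjusted by
default with covariate adjustment behind a flag. Because selection uses the
outcome, null p-values are stochastically small; this anti-conservatism is an
intrinsic property of the procedure as defined and is reproduced, not patched —
the calibration suite asserts its presence, and the FDR-selected output of this
method should be read as a ranking, not a calibrated error rate.

**SKAT.** The variance-component score statistic Q = (y − μ̂)ᵀGGᵀ(y − μ̂) with
an unweighted linear kernel and no MAF pruning; μ̂ comes from the null logistic
model (intercept + covariates, fit once per covariate set and reused across
genes). The asymptotic null is Σ λ_i χ²₁ with λ the eigenvalues of GᵀPG,
P = V − VX(XᵀVX)⁻¹XᵀV, V = diag(μ̂(1 − μ̂)). Tail probabilities are computed by
numerical inversion of the characteristic function (the Davies/Imhof integral):
the head of the integral by adaptive quadrature and the oscillatory tail by
Fourier-weighted (QAWF) quadrature on its two slowly varying amplitude
components, with a single eigenvalue reduced to an exact scaled chi-square. If
the quadrature's error estimate is untrustworthy or the result lies below
1e-14, a Liu-type four-moment fit takes over and the gene is flagged
(`note = "liu fallback"`).

*Small samples.* The asymptotic mixture is visibly off at small n (its error is
O(1/n); at n = 40 around 0.02–0.03 on the p-value). For covariate-free null
models with n < 100 the package therefore matches the exact finite-sample null:
Q = aᵀSa with S the centred Gram matrix of the gene and a the permuted null
residuals, and the first four moments of Q under random permutation have closed
forms, computed by Möbius inversion over the set-partition lattice of the index
slots (the implementation is verified against exhaustive permutation
enumeration at n = 7 to machine precision). The tail is then a Liu-style
(non)central chi-square matched on those four moments. Remaining error is the
distance between the true permutation law and a four-moment fit, empirically a
few 1e-3 on mid-range p-values for dosage data; for hard integer genotypes at
such sizes the permutation law carries point masses of order 1e-2 that no
continuous approximation resolves.

**FDR and selection.** BH step-up adjustment per method across genes
(`statsmodels.multipletests`), significance at adjusted p < 0.05. The
disease-associated gene list is the union of genes holding a single-marker
p < 1e-4 and genes at gene-based FDR < 0.1, with provenance flags.

## GO enrichment

The GO subset is a term→gene annotation plus is_a edges (child→parent),
cycle-checked at load, with annotations propagated so a parent's gene set
contains its descendants'.

**Clustering view.** Term p-values use the EASE variant of Fisher's test: the
hypergeometric upper tail with the observed overlap reduced by one (k = 0 gives
p = 1), which penalises single-gene overlaps; plain Fisher is a switch. Term
similarity is Cohen's kappa over the gene list (defined as 0 when expected
agreement is 1). Fuzzy clustering seeds a group around any term whose
kappa ≥ 0.85 neighbourhood reaches 3 members with majority pairwise agreement,
then merges groups sharing ≥ 50% of the smaller member set, in deterministic
term-id order. These three constants are the conventional "highest stringency"
functional-clustering settings; the exact originals are unpublished, so they
are declared configuration, not constants. Cluster score
ES = −log10(geometric mean of member term p-values); ES ≥ 1.3 (mean p ≤ 0.05)
is highlighted.

**Ranked view.** Gene score = the minimum available gene-based p-value. Each
term with ≥ 8 scored genes is tested by a one-sided two-sample KS test (member
scores stochastically smaller), exact when both groups are ≤ 25. DAG
decorrelation processes terms leaves-first: `elim` removes the genes of any
term with p < 0.01 from all its ancestors before they are tested; `weight01`
additionally down-weights, in each ancestor, genes claimed by a more
significant child by the factor (−log10 p_ancestor)/(−log10 p_child) capped at
1, with full removal below the elim cutoff, using a weighted one-sided KS
(effective sample size (Σw)²/Σw²) whenever any weight differs from 1. This
weight01 is a faithful-in-spirit reimplementation of the published heuristic —
deterministic and satisfying the decorrelation property that an ancestor's p
inflates when its signal lives in a child — but numerical equality with other
implementations is not claimed. Significant terms are reported in three groups
(p < 0.001, < 0.005, < 0.01).

The enrichment background defaults to the tested gene universe (all genes with
a score), the statistically correct baseline for a list selected from that
universe; a whole-annotation background is available as a switch.

## Pipeline, seeds, determinism

`run_all` executes QC → association → SNP-to-gene → gene tests → gene selection
→ enrichment from a single `RunConfig` (YAML-loadable). One global seed fans out
to named per-stage substreams (SHA-256 of the stage name mixed into a
`SeedSequence`), so editing one stage never perturbs another's randomness; the
JSON manifest records per-stage parameters, timings and output hashes, and
identical configs reproduce identical hashes.

## Problem sizes in the shipped experiments

The test and acceptance experiments run at deliberately modest scale chosen to
estimate each quantity to the precision its check needs: cohorts of 600–2,000
samples, 14–2,000 markers, 6–500 genes, 12–50 simulation seeds per recovery
estimate, 100,000 permutations for the SKAT oracle. These sizes keep every
sampling error term (binomial CIs, KS sensitivity, seed-to-seed SE) small
relative to the asserted tolerances.

## Known limitations

- No EM haplotype phasing; haplotype tests require phase.
- The IBD estimator omits small-sample bias corrections; it is screened off
  below 500 markers instead.
- sPCA p-values are not calibrated under the null (by design of the method);
  downstream FDR on them is a ranking device.
- weight01 is one concrete instantiation of an informally published heuristic.
- The SKAT small-sample moment match covers covariate-free null models; with
  covariates the asymptotic mixture is used at every n.
- GO namespaces are processed jointly unless a namespace filter is passed;
  cross-namespace edges are not rejected.
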