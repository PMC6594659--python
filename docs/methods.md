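# Methods

## The generative model

The simulator emulates a 3×3 allelic series over two paralogous
transcription-factor loci, sequenced as single embryos (default 10 per
genotype, 90 samples). A genotype is the pair (a, c) of functional
allele counts, (2,2) the wild type and (0,0) the double knockout.

**Regulatory activity.** Each locus contributes half of wild-type
activity in proportion to its functional alleles; when locus A is fully
knocked out, the locus-C contribution is multiplied by 1 + κ
(compensation boost):

    activity(a, c) = ½·(a/2) + ½·(c/2)·boost,  boost = 1 + κ iff a = 0.

Wild type has activity 1; (0,2) with κ = 0.5 has 0.75.

**Locus transcripts.** A functional allele emits its full share, a
non-functional allele only the residual fraction λ left after
nonsense-mediated decay (default λ = 0.3, i.e. mutant transcripts are
reduced ~70%). The locus-C transcript additionally carries the boost,
so in (0,2) its expected mean is baseline · 1.5 with the defaults —
the "~50% compensatory upregulation" the analysis is built to recover.

**Target-gene classes.** Every simulated gene belongs to one class:

| class | response |
|---|---|
| null | baseline everywhere |
| dosage_linear | baseline · 2^(β·d), d = max(0, 1 − (a+c)/2) |
| full_rescue | 2^β only at activity 0 |
| partial_rescue | 2^(β·(1 − activity)) |
| two_allele_rescue | 2^β whenever a = 0 and c < 2 |
| epidermal / neural_up | ∓\|β\| at activity 0 only |
| cis_block | baseline; per-sample haplotype factor (below) |

The lost-dose fraction d uses the total functional-allele count, which
pins d(0,0) = 1 and d(0,1) = ½ — the source of the exact 1:2 log2
fold-change ratio — and leaves single mutants (d = 0) transcriptionally
quiet, matching the qualitative observation that single-paralogue
knockouts change very few genes. Effects β are half-normal with scale
`beta_sd` (default 1.5) and random sign, or fixed magnitude via
`beta_fixed` for recovery tests; the magnitude distribution of real
target effects is unknown, so `beta_sd` is a free parameter.

**Noise.** Counts are negative binomial with variance μ + αμ²
(α default 0.05, a typical single-embryo dispersion); per-sample depth
factors are log-normal (sd 0.2) to exercise normalization. One shared
`numpy` Generator seeded once drives everything; no global RNG state.

**Cis-haplotype block.** `cis_block` genes are placed in a 10-Mb window
around the mutated locus on its chromosome (default "24"). Their
counts are multiplied per sample by 2^(β·(1 − a/2)) — apparent
expression tracks the inherited chromosome segment (the locus-A
genotype), not regulation. Optionally one homozygous embryo is made
recombinant (wild-type haplotype across the block), reproducing the
single-embryo signature by which such artifacts are recognised.

**What the generator does not emulate:** batch effects, 3'-tag vs
full-length coverage bias, sample swaps, outlier embryos, stage
mixtures within a library, or correlated gene-gene noise beyond the
planted classes. Passing recovery tests therefore demonstrates that
the estimators work under clean NB noise at the study's design scale,
not that they are robust to every real-data pathology.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference
over genes positive in all samples (a flagged pseudo-reference over
positive samples is the fallback). Dispersions are method-of-moments
on normalized counts pooled across within-genotype deviations, floored
at 1e-8, then shrunk on the log scale toward the 20%-trimmed mean with
weight 0.3 — a transparent stand-in for full empirical-Bayes dispersion
fitting. Each contrast fits the two group means by NB maximum
likelihood (Newton in log-mean, size factors as offsets, shared
gene-wise dispersion) and reports the Wald statistic
log2FC / se(log2FC) with the se from observed Fisher information.
Genes below a base-mean floor of 1, or all-zero in both groups, are
untested; a group with zero counts gets 0.5/mean(s) substituted for
reporting and is flagged. No fold-change shrinkage prior and no
outlier handling are applied: MLE fold changes feed the dose-ratio
regression directly, and the outlier question is left to an optional
sample-level PCA filter. BH adjustment is per contrast; Bonferroni is
reserved for ontology enrichment.

## Dose-ratio regression and selection bias

The 1:2 claim is tested by regressing the L2 log2FC on the L1 log2FC
through the origin over genes significant in L2 (the smaller list).
Because the response variable is also the selection variable, the naive
fit carries a winner's-curse bias (measured ≈ +0.01 at the default
design, enough to push a tight bootstrap CI off 0.5). The default
therefore first replaces each selected L2 estimate by the average of
itself and its conditional MLE under the two-sided truncated-normal
likelihood at the realised significance threshold — the compromise
estimator from the selection-bias literature, chosen because the pure
conditional MLE overcorrects borderline genes. `debias=False` restores
the plain fit; `include="union"` (no selection on L2) skips the
correction. The CI is a seeded 1000-resample percentile bootstrap over
genes. Regression through the origin is the default because the
dosage model predicts a zero intercept; an intercept fit is available.

## Enrichment

OBO parsing is delegated to `obonet`; only `is_a` edges are honoured
(part_of and other relations are a stricter annotation claim than the
true-path rule guarantees), obsolete terms are skipped, and multiple
roots are closed under a virtual root. Annotations are propagated to
all ancestors before testing. The Parent-Child-Union statistic tests
each term with ≥ 1 study gene against the genes annotated to the union
of its parents: p = P(X ≥ k) hypergeometric with population = parent
union, successes = term genes in the union, draws = study genes in the
union. The root is skipped and Bonferroni m counts tested terms only —
an interpretation of the reference tool's behaviour, recorded here
rather than claimed to match it bit-for-bit. On a flat ontology the
statistic reduces exactly to the plain hypergeometric test, which the
suite exploits as an oracle.

## Co-expression and diagnostics

Expression for correlation is log2(normalized counts + 1) (no transform
is canonical; this one is variance-stabilising enough at these depths).
Edges require Pearson r ≥ 0.7, positive only — anti-correlated modules
are deliberately separate clusters. MCL runs on the column-stochastic
adjacency with self-loop weight equal to the node's maximum incident
edge weight, expansion 2, inflation 2.2, pruning 1e-5, convergence at
max-change < 1e-6; clusters are connected components of the attractor
support, with clusters below 3 genes reported separately. Inflation
and minimum size are common defaults for this family of tools and are
configurable, as the upstream choice is not documented. The
cis-haplotype diagnostics are a per-chromosome upper-tail
hypergeometric over a DE list (BH across chromosomes, minimum-p
chromosome flagged below q 0.05) and a per-cluster colocation score
(modal-chromosome fraction, plus the fraction within a 10-Mb window
centred on the median position).

## Numerical choices and degenerate inputs

Newton steps in log-mean are clipped to ±5 with a 1e-10 convergence
tolerance; dispersions are floored at 1e-8 (Poisson limit); BH uses
the step-up with explicit monotonicity enforcement and ignores
untested genes in m; hierarchical clustering sorts gene ids before
linkage so ties break deterministically; MCL column sums are
renormalized after pruning every iteration. Degenerate cases raise
informative errors: contrasts with < 2 samples per group, constant
expression matrices, unpropagated annotations (detected when a child
outnumbers its parents' union), all-zero significance patterns.

## Problem sizes

The recovery suites simulate 200–5000 genes at the study design of
9 × 10 embryos, with 20–50 replicate simulations per claim — the
smallest sizes at which the targeted quantities (slope 0.5, fold 1.5,
type-I error 5%, FDR 10%, recall 0.8) are stable, keeping the whole
suite to well under a minute of simulation per claim.
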