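# Methods

## The model

`epiblup` implements multifactorial genomic prediction under the mixed
linear model

    y = Xb + Σᵢ uᵢ + e,        uᵢ ~ N(0, σᵢ² Sᵢ),   e ~ N(0, σₑ² I)

with one observation per individual.  Each variance component i is one
*effect type* with its own n×n relationship matrix Sᵢ: SNP additive (A),
SNP dominance (D), global epistasis compositions of orders 2–4
(A×A … D×D×D×D, fourteen SNP/epistasis types in total), and a haplotype
additive component (H).  The phenotypic covariance is
V = Σᵢ σᵢ² Sᵢ + σₑ² I; heritability of type i is
hᵢ² = σᵢ² · mean diag(Sᵢ) / (Σⱼ σⱼ² · mean diag(Sⱼ) + σₑ²), which reduces
to σᵢ²/(Σσⱼ² + σₑ²) for the normalized matrices the package produces.

## Relationship matrices

*Codings.*  Additive codes are mean-centered alt-allele dosages (x − 2p̄);
dominance codes are mean-centered heterozygosity indicators.  Under
Hardy–Weinberg proportions these keep A and D orthogonal.  Allele
frequencies are always taken from the analyzed sample.

*Normalization.*  Every matrix is scaled to mean diagonal 1.  With 15
heterogeneous effect types this puts all variance components on the same
phenotypic-fraction scale, which is what makes per-type heritabilities
comparable and summable.

*Epistasis, approximate vs exact.*  The approximate construction is the
Hadamard (elementwise) product of normalized first-order matrices; it
includes same-locus ("intra-locus") terms that correspond to no real
interaction.  The exact construction restricts the interaction design to
distinct loci.  Writing per-locus products a_k = w_xk·w_yk and
d_k = h_xk·h_yk for an individual pair (x,y), the exact entry for a
composition with α additive and δ dominance factors is the coefficient of
tᵅuᵟ in Π_k (1 + t·a_k + u·d_k).  We extract it with a truncated
exp(log(·)) series in the mixed power sums P(s,t) = Σ_k a_kˢ d_kᵗ, each of
which is a single Gram matrix of elementwise code powers.  For δ=0 the
expansion is exactly Newton's identities for elementary symmetric
polynomials; for mixed compositions it is inclusion–exclusion over shared
loci.  Cost is a handful of n×n products independent of the number of
loci.  A brute-force builder that enumerates every distinct-locus tuple
(one design column per unordered locus set with assigned A/D roles) is the
verification oracle; the test suite checks exact = brute force to 1e-10
relative Frobenius error for all 12 compositions of orders 2–4.

*Haplotypes.*  A block is a run of consecutive SNPs on one chromosome
(fixed SNP count, fixed-width windows anchored at position 1, or merged
BED regions with ≥2 SNPs).  Its alleles are the distinct phased haplotypes
observed in the sample; the H matrix is the Gram matrix of mean-centered
allele-count columns pooled over blocks, normalized to mean diagonal 1.
Centering makes the matrix invariant to dropping one reference allele per
block, so all alleles are kept.  Rare-allele pooling (`min_freq`) exists
but is off by default.

## REML estimation

Variance components are estimated by average-information (AI) REML with an
EM-REML fallback.  Implementation details that matter:

* **Active set.**  Components pinned at the floor (10⁻⁶·var(y)) with a
  gradient pushing further down are excluded from the Newton system and
  flagged as boundary solutions.
* **Levenberg–Marquardt escalation with line search.**  The undamped AI
  step is tried first, then progressively damped systems
  (AI + λ·mean-diag·I, λ ∈ {10⁻⁴, 10⁻², 1, 10}), each with step halving;
  the first feasible non-decreasing iterate is accepted, otherwise the
  monotone EM update is taken.  Damping is essential when several
  epistasis matrices are nearly collinear (their AI matrix is then
  ill-conditioned and raw Newton steps overshoot badly and are rejected),
  a situation that arises routinely with the order-2–4 ladder of matrices
  — with plain AI/EM alternation, full-model fits stall for hundreds of
  iterations with every component near its starting value.
* **Convergence** requires both |Δ log-likelihood| < 10⁻⁶ *and* a small
  Newton decrement on the free components.  The likelihood criterion alone
  would stop on near-flat ridges at a point determined by the starting
  values, leaving arbitrary splits between collinear components.
* **Starting values**: var(y) split equally across all components.

The restricted log-likelihood, its gradient, the AI matrix and the EM
update use the standard dense P-matrix formulas; everything is O(n³) per
iteration with Cholesky factorizations, intended for n up to ~10⁴.

## GBLUP

Fixed effects are estimated by GLS on the training individuals; genetic
values by û_i[target] = σᵢ² Sᵢ[target, train] V_train⁻¹ (y − Xb̂).  Masked
(validation) individuals never enter V_train, so altering their phenotypes
cannot change any prediction (asserted by a dedicated leakage test).  The
predicted quantity is the genetic value only; fixed effects are not added
(the predictive-ability statistic correlates genetic values with
phenotypes).  For an additive-only model the predictions coincide with
ridge/SNP-BLUP with shrinkage λ = σₑ²·normalizer/σ_A², which the tests use
as an independent oracle, and for target = train they solve Henderson's
mixed-model equations.

## Cross-validation and model selection

Individuals are shuffled once (seeded) into 10 folds: nine of size
⌊n/10⌋, the tenth takes the remainder.  Per fold, variance components are
re-estimated on the training rows only, validation rows are predicted with
phenotypes masked, and the fold's Pearson correlation between predicted
total genetic value and observed phenotype is recorded.  The predictive
ability is the arithmetic mean of fold correlations (not the pooled
correlation; the two are computed and asserted distinct in the tests);
its spread is the sample SD across folds.  Undefined correlations
(constant values) are dropped from the mean with a warning.

Model selection is two-stage.  The initial screen fits the full
14-SNP/epistasis-type model and keeps every type with ĥ² strictly greater
than 1%.  The final stage cross-validates nested candidate models
(prefixes of the initial model in canonical subscript order, all under the
same fold assignment) and picks the highest predictive ability, breaking
ties by fewest effect types, then by subscript order.  Accuracies are
compared after rounding to 3 decimals — the precision at which such
accuracies are reported and at which near-identical candidate models
should count as equivalent; without rounding, ties would almost never
occur and noise would decide between equivalent models.

## The synthetic-data generator

The generator emulates the data shape this analysis needs: a phased,
LD-blocked biallelic panel (MAF ≥ 0.05) on a *family-structured* sample,
with one phenotype record per individual.

*Genotypes.*  Per block, a pool of founder haplotypes (default 8) with
allele frequencies U(0.2, 0.8); founder-individual gametes are mosaics of
the pool with a per-SNP switch rate (default 0.01).  The sample is
organized into three-generation pedigrees of 13 (two grandparent couples,
three of their children, one in-marrying founder spouse, three
grandchildren and two first cousins); non-founder gametes segregate block
by block from the parental haplotypes.  This produces a *spectrum* of
additive relatedness (1/2, 1/4, 1/8, ≈0).  The spectrum is load-bearing:
with a single relationship class, elementwise powers of the additive
relationship matrix are linearly dependent with the identity and epistatic
variance components of different orders cannot be separated at all.  What
the generator does not emulate: genotyping error, sex chromosomes,
population stratification, assortative mating, and the long-range LD decay
of real genomes (between-block LD is zero by construction).  Passing tests
therefore show the pipeline recovers the architecture of data matching its
own covariance model on a family sample — not that real-data estimates at
biobank scale would behave identically.

*Effects.*  Genetic values are built from the same centered codings the
relationship matrices use.  Defaults are polygenic — 400 causal SNPs for A
and D, 2000 causal pairs/triples for interactions (capped at availability)
— because sparse architectures' realized covariance deviates from σ²Sᵢ and
biases component recovery.  Block-local high-order epistasis (`local3`) is
realized in *cis*: the product of three centered allele indicators on the
same gamete, summed over the two gametes.  This is the allele-configuration
signal a haplotype allele carries; a genotype-level three-way dosage
product is dominated by cross-gamete terms that no haplotype-additive (or
SNP-additive) model can represent, and produces no haplotype advantage.
Every component and the residual are standardized empirically, so the
configured variance fractions hold exactly in-sample.  Fixed effects: a
two-level classification variable (effect 0.5 SD) and one standard-normal
covariable (coefficient 0.2).

*Determinism.*  All outputs are pure functions of the configuration; the
three stages draw from independent seeded streams.

## Experiment sizes used by the test suite

The stochastic acceptance experiments use problem sizes chosen as the
package's own desk-scale study conditions: parameter recovery at n=1000
with 100 blocks × 20 SNPs over 10 replicates; end-to-end model selection
at n=400, 50 blocks × 8 SNPs over 20 replicates, with the truth anchored
to a lipid-trait-like architecture (additive 0.28, pairwise epistasis
0.42); haplotype-advantage comparison at n=400, 25 blocks × 8 SNPs over
10 replicates; CV null and additive checks at n=600–1000.

## Known limitations

* Fourth-order relationship matrices are weakly identified at n ≈ 10³:
  their informative off-diagonal features (r⁴ ≤ 1/16 even for sibs) are
  nearly collinear with the pairwise matrix and the identity, and their
  diagonal heterogeneity (4th powers of code magnitudes over ~10²
  independent blocks) lets them partially absorb residual variance.  The
  sampling SD of a fourth-order heritability estimate under a truth of
  zero is on the order of 0.1.  Screening decisions about fourth-order
  terms are therefore unreliable at this scale — they become reliable
  only with the far larger panels and samples such studies actually use.
* For the same reason, cross-validated comparisons between nested models
  at n of a few hundred have paired accuracy differences with noise on
  the order of 0.005–0.01 — the same magnitude as real component
  contributions — so automated model selection at this scale excludes
  correlated spurious interaction terms only unreliably.  The selection
  machinery is exact; the discrimination it can deliver scales with the
  data.
* Repeated phenotype records per individual (Z ≠ I), multiallelic
  variants, and imputation beyond mean dosage are out of scope.
* Standard errors of heritabilities come from the inverse AI matrix
  (asymptotic); no profile-likelihood intervals.
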