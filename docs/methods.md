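# Methods

## Scope and data model

The pipeline quantifies how pharmacogenomic variation stratifies across
self-identified population groups in a cohort. Its inputs are a diploid
biallelic genotype matrix (VCF with GT calls; dosage = alternate-allele
count, missing kept explicit), a sample-to-group label table, and a
PharmGKB-style annotation table (variant, rsID, gene, drugs, evidence
level, association type, mode of effect, effect allele). Positions are
1-based, GRCh38-style contig names; multiallelic records are rejected by
default (optionally split) because silent splitting changes
allele-frequency semantics. rsID is the primary key for joining
genotypes to annotations, with the positional `chr:pos:ref:alt` id as
fallback, since annotation sources key on rsIDs while cohort VCFs key on
coordinates.

## Allele frequencies and Hardy–Weinberg fractions

Per-(variant, group) frequency is computed from called alleles only:
`p = Σ dosage / (2 n_called)`. Missing genotypes never enter the
denominator and all-missing cells are flagged rather than imputed, which
matches the default behavior of standard frequency tools. Genotype
fractions used downstream are the Hardy–Weinberg expectations `p²`,
`2p(1−p)`, `(1−p)²` derived from the allele frequency rather than counted
genotypes: the adverse-reaction model below is defined in terms of these
population fractions, and using them keeps the statistic well-defined
even for frequency tables that arrive without genotype-level data.

## Genotype PCA and allele weights

Variants are standardized by the EIGENSTRAT/PLINK convention — centered
at the mean dosage `2p` and scaled by `sqrt(2p(1−p))` — with missing
dosages mean-imputed after frequency estimation (a dense decomposition
needs complete data; mean imputation is the neutral choice that adds no
between-group signal). Variants with zero dosage variance are dropped
with a logged count; they carry no information and break scaling.

The decomposition is an exact singular value decomposition for cohorts
up to 2000 samples and a seeded randomized truncated SVD above that,
mirroring how large-cohort PCA tools switch to approximate solvers at
scale while keeping small analyses exact. Scores satisfy the defining
identity `PC_i = Σ_j w_ij x_ij` with `w` the right singular vectors, so
an allele weight measures the variant's contribution to between-sample
divergence along that PC. PC signs are arbitrary; they are fixed so the
largest-magnitude weight per PC is positive. Explained-variance shares
are singular values squared over the total standardized variance.

**Divergence ranking.** The divergence score of a variant is
`max |w| over PC1 and PC2` (both per-PC weights are always reported, so
other combining rules remain recoverable); the sort is stable, so tied
variants keep their input order. The top of this ranking recovers
variants with large between-group frequency differences because such
variants dominate the leading axes of a group-structured cohort.

## Group classification

Three classifier families — k-NN, random forest, and RBF-kernel SVM —
predict group labels from the top PC scores. Hyperparameters are drawn
by randomized search (default 10 draws) over these spaces: k ∈ [3, 50];
trees ∈ [100, 800], depth ∈ [10, 150], min leaf ∈ [1, 8], min split ∈
[2, 10]; SVM C ∈ [1, 10⁵] and gamma ∈ [10⁻³, 10²], both log-uniform.
The search is nested inside each training fold of a stratified 5-fold
cross-validation (inner 3-fold), so model selection never sees the test
fold; the permutation-null test in the suite confirms that shuffled
labels score at chance. The SVM standardizes features inside its
estimator pipeline, which is standard practice for RBF kernels on
unequal-variance features such as PC scores. Accuracy is the plain
percentage of correct predictions, reported as mean ± sd across the five
test folds; every sample is tested exactly once, so the confusion matrix
aggregates the whole cohort. A sweep over contiguous PC counts
identifies the best accuracy and its PC count, ties going to the
smallest count. k-NN ties are resolved by scikit-learn's deterministic
neighbor ordering. An optional seeded down-sampling helper rebalances a
majority group before classification; it is off by default.

## Excess adverse drug reactions

For a toxicity-associated variant with effect-allele frequencies `p_a`
and `p_b` in two groups, the expected excess adverse reactions per 1000
treated, under Hardy–Weinberg genotype fractions, is
`1000 (p_a² − p_b²)` for a recessive effect (two effect alleles needed)
and `1000 [(p_a² − p_b²) + (2p_a(1−p_a) − 2p_b(1−p_b))]` for a dominant
effect — algebraically the carrier-frequency difference. The statistic
is kept signed internally (antisymmetric in the groups). Reports carry
the continuous value plus a rounded integer magnitude
(round-half-away-from-zero) and the direction of excess, because the
higher-risk group flips between variants and a magnitude-only report
would hide that. Frequencies are oriented to the annotated effect allele
(the stored allele's frequency is complemented when the effect allele is
the other allele of the biallelic pair — e.g. rs9694958, whose effect
allele is the reference allele). Published integer examples computed
from frequencies printed at three decimals carry about ±1 of rounding
slack, and the bundled demonstration values inherit that.

## Cohort simulator

The generator emulates the structure of a diverse biobank cohort, not
any particular genome. For variant *j*, an ancestral frequency `p_j` is
drawn uniformly on (0.05, 0.95) (avoiding near-monomorphic noise), and
each non-admixed group *g* draws
`p_gj ~ Beta(p_j(1−F_g)/F_g, (1−p_j)(1−F_g)/F_g)` — the Balding–Nichols
model, the standard FST-indexed divergence model — so `E[p_gj] = p_j`
and `Var[p_gj] = F_g p_j(1−p_j)`. Genotypes are `Binomial(2, p_gj)`.
Admixed samples draw per-sample ancestry proportions from a Dirichlet
over the non-admixed groups, and each of their two allele copies picks a
parental group independently, i.e. dosage `~ Binomial(2, w·p_j)` — the
simplest model that produces the dispersed PC-space cloud characteristic
of multi-ancestry groups. A ratio-of-averages Hudson-style estimator on
the drawn frequencies recovers the target F (calibration asserted at
F = 0.1 within ±0.03 over 10⁴ variants).

Planted divergent variants are redrawn (rejection sampling, ≤1000
attempts) until the maximum pairwise group difference reaches
`divergent_delta` (default 0.5); on failure one random group is set to
frequency 0.9 and the rest to 0.1. The default cohort mirrors a large
US biobank after majority down-sampling: four non-admixed groups with
strongly unequal sizes (2000/2128/1730/297 at full scale) plus one broad
admixed group (357, Dirichlet α = 1 over all four parents), 6000
variants of which 60 are planted divergent, and continental-scale
per-group F between 0.08 and 0.14.

**What the simulator does not model:** linkage disequilibrium between
variants (all sites independent), recombination maps, genotyping error,
missingness mechanisms, and phenotypes. Passing tests on simulated
cohorts therefore demonstrate the pipeline's statistical machinery —
frequency estimation, PCA recovery of group structure, classifier
behavior, ADR arithmetic — under idealized sampling; they do not certify
accuracy figures on real cohorts, where LD, platform artifacts, and the
social complexity of self-identified labels all matter.

## Problem sizes and numerical choices

The test suite and demo use deliberately scaled-down cohorts chosen to
exercise every code path with comfortable statistical margins: the
classification property tests run on a 1/10-scale cohort further scaled
to ~980 samples × 1000 variants (30 planted divergent), the
divergent-recovery check uses 3 × 300 samples with 20 planted variants
among 500 background at F = 0.05, and the bundled demo pipeline uses
~780 samples × 800 variants. PCA equivalence with a dense
eigendecomposition is asserted to 10⁻⁶ on matrices up to 100 × 100;
score orthogonality to |r| < 10⁻⁶; Hardy–Weinberg and ADR algebraic
identities to 10⁻⁹–10⁻¹² on dense grids. One global seed drives every
random draw; the pipeline derives per-stage seeds by hashing the stage
name with the global seed so stages can be re-run in isolation and TSV
outputs are bit-identical across reruns.

## Known limitations

- Frequencies, not genotype counts, drive the ADR statistic; departures
  from Hardy–Weinberg equilibrium in a real cohort are not reflected.
- The divergence score considers PC1/PC2 only by default; group
  structure confined to deeper PCs needs an explicit `pcs` argument.
- No projection of new samples onto a fitted PCA, no LD pruning, and no
  per-individual risk prediction: group-level frequency differences
  stratify expected risk, they do not predict any individual's genotype.
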