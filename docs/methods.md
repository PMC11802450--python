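# Methods

`cellgwas` maps polygenic GWAS signal onto transcriptomically defined cell
types. The analysis asks, for each cell type, whether genes that are
*specifically* used by that cell type are also the genes carrying the
phenotype's genetic association — the premise being that phenotype-associated
cell types preferentially use phenotype-associated genes. This note documents
the statistical model at each stage, the synthetic study the package ships
for end-to-end validation, the numerical choices, and the known limitations.

## 1. Expression specificity

Counts are transformed with ln(1 + x) (no per-cell depth normalization by
default; a config flag exists, off by default) and averaged over the cells
of each cluster, in that order: the mean of transformed counts, not the
transform of the mean. Gene filters are applied next, in a fixed order with
per-rule removal counts: genes without an annotation row or without a unique
cross-reference mapping; non-protein-coding genes; genes whose symbol is
shared with another gene (all carriers removed); genes with zero total
transformed expression; and genes whose 1-based inclusive interval overlaps
the MHC region at all (default chr6:25,000,000–34,000,000; configurable,
since the interval is genome-build dependent). The specificity of gene g in
cell type c is its cluster mean divided by the row total, so each retained
gene's scores sum to 1 over the retained cell types. A gene expressed
identically everywhere scores 1/C in every cell type (0.0022 at C = 461).
`downsample_clusters` thins every cluster to a common ceiling (uniform
sampling without replacement, seeded) for the robustness analysis that
recomputes specificity from 3,400 / 340 / 34 cells per cluster.

## 2. Gene-level association

SNPs are assigned to a gene when they fall in a strand-aware window from
35 kb upstream to 10 kb downstream of the gene body (1-based, inclusive at
both bounds, clipped at position 1; genes without strand are treated as
'+'). SNP p-values are probit-transformed, z = Φ⁻¹(1 − p), with p clamped
to [1e-300, 1 − 1e-16], and the gene statistic is T = Σ z². Under the null,
T is distributed as Σ λⱼ·χ²₁ with λ the eigenvalues of the member-SNP LD
correlation matrix (negatives clipped at 0; eigenvalues below 1e-4·λ_max
pruned, with the count recorded). The survival probability is computed by
Imhof's inversion integral (absolute tolerance 1e-12), by the exact
chi-square survival function when all weights are equal, and by the Kuonen
(Lugannani–Rice) saddlepoint approximation in the far tail (p < 1e-8) or on
non-convergence, flagged per gene. P-values are floored at 1e-300 so the
probit stays finite. No installed library provides this quadratic-form
survival function, so it is implemented here and cross-checked in the tests
against closed forms and Monte Carlo.

Per-gene covariates for the regression stage: SNP count ("gene size"), the
effective-test ratio (retained eigenvalue count / SNP count — our reading of
"gene density", validated behaviorally through null calibration rather than
against a printed formula), inverse mean minor allele count, mean GWAS
sample size, and natural logs of each.

The gene–gene correlation of the statistics induced by shared and adjacent
LD is computed for gene pairs whose windows lie within 5 Mb on one
chromosome as

    corr(T_g, T_h) = Σ_{i∈g, j∈h} r²_ij / sqrt(S_g · S_h),   S_g = Σ_{i,i'∈g} r²_{ii'} ,

which is the exact null correlation of the two quadratic forms (S_g reduces
to the SNP count when within-gene SNPs are independent). The matrix is
ridge-repaired to positive semidefiniteness (add δI with δ = |min
eigenvalue| + 1e-8, then rescale to unit diagonal) when sampling noise makes
it slightly indefinite.

## 3. Gene-property regression

For each cell type c the model is Z = β₀ + P_c β₁ + C β₂ + ε with ε
multivariate normal with correlation R (the gene–gene matrix above). Gene
z-scores Z = Φ⁻¹(1 − P_g) are truncated at mean − 3 sd and mean + 6 sd;
specificity columns symmetrically at mean ± 5 sd. Truncation statistics are
computed once on the raw vector (no iteration), making both clamps
idempotent. The fit whitens by the Cholesky factor of R and solves least
squares; the test of β₁ is one-sided (H₁: β₁ > 0 — a negative relation
between specificity and association is not of interest) with df = G −
(k + 2). Cell types are flagged at the Bonferroni threshold α/C (0.05/461 ≈
1e-4 at full scale).

Covariate columns with zero variance (e.g. mean sample size when the GWAS
N is uniform) are dropped before the fit, as are columns linearly dependent
on the intercept or earlier covariates — with near-discrete covariates the
log versions can be *exactly* affine in the raw ones (the log of a
two-valued column always is). Genuine collinearity between the specificity
column and the rest of the design still raises an error naming the column.
The scan over cell types shares one whitening and one QR of the base design
and obtains each cell type's slope test by residualization, which is
algebraically identical to the full GLS fit (verified against an
explicit-inverse oracle in the tests).

## 4. Conditional analysis and selection

The conditional model adds a second specificity column: Z = β₀′ + P_c1 β₁′ +
P_c2 β₂′ + C β₃′ + ε, with both columns truncated exactly as in the marginal
scan. Proportional significance PS(c1|c2) = −log P(c1|c2) / −log P(c1)
(base-invariant) measures the fraction of marginal significance surviving
conditioning. Forward-stepwise selection initializes the selected set S with
the most marginally significant cell type and visits the remaining
Bonferroni-significant candidates in order of increasing marginal P (ties
broken by cell-type id). Candidate c joins S only if, against every s ∈ S,
either both PS(c|s) and PS(s|c) are ≥ 0.8 (independent) or both lie in
[0.5, 0.8) and the *conditional* P of c given s is ≤ 0.05 (partially
independent; the conditional reading is chosen because every candidate's
marginal P is already far below 0.05, which would make the rule vacuous — a
config switch restores the marginal reading). When an established member
loses its own signal against the candidate, PS(s|c) < 0.2 ≤ PS(c|s), the
selection order reverses: s is excluded as explained and c takes its place.
PS values in [0.2, 0.5) against any member exclude the candidate. Pairs with
|corr| > 0.9999 between truncated columns are flagged indistinguishable and
the candidate is excluded. Every pairwise comparison and the rule fired are
logged in an audit table, and the procedure is deterministic and invariant
to the storage order of cell types.

## 5. Robustness machinery

*Permutation null.* Gene labels of the gene-statistic table are shuffled
(one shuffle per iteration, shared by all cell types), breaking the
gene–specificity link while preserving both marginals, and the full scan is
rerun. The statistic's covariates and its LD correlation are properties of
the GWAS side and travel with it, so the shuffle is applied to the
specificity rows — the same permutation seen from the other side. Expected
chance counts are analytic: n_perm × C × α hits at α (23,050 for 1,000
permutations × 461 cell types at 0.05) and n_perm × α at the Bonferroni
threshold (50).

*Effective sample size* of a case-control GWAS: n_eff = 4/((1/cases) +
(1/controls)), equal to the total n when balanced.

*Cell-count diagnostic*: Pearson r between −log₁₀(P) and cells per cluster,
reported with its two-sided p, never thresholded.

*SEG annotations*: per cell type, the ceil(0.10·G) most specific genes
(ties by gene id) with 100-kb flanks, clipped at 1, merged when
overlapping; written as BED (0-based half-open) for use with LD-score
partitioned-heritability tools. Running LDSC itself is out of scope.

*Power harness*: reruns the full synthetic pipeline over a grid of GWAS
sample sizes with fixed ground truth and counts significant and selected
cell types per size.

## 6. The synthetic study

The generator plants a known causal structure at desk scale; defaults are
fixed once and shared by the tests:

| parameter | default | meaning |
| --- | --- | --- |
| n_haplotypes | 1,000 | panel haplotypes (≈ 1000 Genomes EUR scale) |
| n_chromosomes × n_blocks × snps/block | 5 × 100 × 10 | 5,000 SNPs |
| within_block_r | 0.5 | target allele-level LD inside a block |
| n_genes | 500 | 10-kb genes, end-to-end with 50-kb gaps |
| n_clusters / cells_per_cluster | 20 / 50 | cluster-labelled cells |
| cluster_tree_correlation | 0.5 | sibling-profile similarity |
| enrichment_effect | 10 | causal-gene mean multiplier in causal clusters |
| gwas_effect_scale | 30 | per-gene χ² noncentrality at the reference GWAS size |
| gwas_n | 100,000 | GWAS sample size (scales noncentrality linearly) |

*Genotypes* come from a Gaussian copula: equicorrelated latent normals per
block, thresholded at the allele frequency (drawn per block from
U(0.05, 0.5)). Dichotomization attenuates correlation, so the latent value
is calibrated per block by solving the bivariate-normal orthant equation,
making realized allele LD match `within_block_r`. Blocks are independent;
positions strictly increase within chromosomes.

*Expression* follows a binary-tree hierarchy: a child's log-mean profile is
its parent's plus independent noise scaled by (1 − cluster_tree_correlation),
so numerically adjacent clusters are correlated siblings — the structure the
conditional analysis must disentangle. Counts are negative binomial with
dispersion 0.5 and lognormal (σ = 0.3) library-size factors, reproducing the
overdispersion and zeros the ln(1+x) transform is meant to tame. Causal
genes' means are multiplied by `enrichment_effect` in causal clusters.

*GWAS z-scores* are multivariate normal per block with the block's empirical
allele correlation; SNPs inside a causal gene's window share a mean shift
whose squares sum to the gene's noncentrality ν = gwas_effect_scale ×
gwas_n / 100,000 (the 100k reference makes `gwas_effect_scale` the
noncentrality at the default GWAS size, giving the power harness a real
dial). P is the two-sided normal tail, so null SNP p-values are exactly
uniform. All generators are pure functions of (config, seed) with named
substreams, bit-identical across processes.

What the generator does *not* emulate: realistic human LD maps and
recombination structure, ancestry stratification, sex chromosomes,
imputation quality, cell-type abundance skew, batch effects, or ambient
RNA. Passing tests therefore demonstrate the statistical machinery —
calibration, recovery, monotonicity — under the stated generative model,
not performance on real atlases.

## 7. Numerical choices and problem sizes

Truncation sds use ddof = 1. The Imhof integral uses scipy's adaptive
quadrature (absolute tolerance 1e-12, 500 subdivisions); the saddlepoint
root is bracketed in (−10⁴, 1/(2λ_max)). Whitening adds a 1e-10 ridge only
if the Cholesky factorization fails. Degenerate inputs are errors, not
silent repairs: negative counts, all-zero gene rows reaching the
specificity step, empty gene intersections, zero-variance SNP sets,
marginal P = 1 in a PS ratio. Zero-variance truncation inputs pass through
with a warning.

Validation scales, chosen to exercise every stage while staying
desk-sized: null calibration uses 20 clusters × 500 genes × 100
permutations (2,000 test instances) plus ten full-pipeline replicates at
461 cell types; recovery experiments use 20 replicates of the default
configuration; the power grid is 20k / 100k / 400k participants averaged
over six replicates. The end-to-end fixture (20 clusters, 500 genes, 5,000
SNPs) completes in seconds on one CPU.

## 8. Known limitations

The gene–gene correlation is derived for the quadratic forms on the raw z
scale, while the regression errors live on the probit scale of the gene
p-values; the two agree to the accuracy the calibration tests measure, and
the residual misspecification shows up as a percent-level excess of small
scan p-values at the 461-cell-type scale (within the tolerance of the null
checks). The mixture null uses the signed allele LD matrix although the
two-sided-p probit transform slightly decorrelates the transformed
statistics; this makes gene p-values mildly conservative under strong LD.
The "gene density" covariate follows our effective-test reading, not a
printed formula. Selection behavior for PS in [0.2, 0.5) is an exclusion by
construction. None of these affect the planted-truth recovery experiments,
which operate far from the affected corners.
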