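# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated on, the numerical choices, and the limits of what
passing tests demonstrate.

## Study design being emulated

The pipeline targets a common-garden transcriptome design: ~11 natural
populations, ~241 genotypes of which most carry two clonal replicates in
different blocks (459 samples at full scale), RNA sampled over a two-week
window (block, date and hour as candidate nuisance factors), a genomic
relationship matrix from a SNP panel, and a handful of quantitative traits.
The synthetic generator reproduces this structure at configurable size; all
validation runs use 11 populations and 200 genotypes unless a test needs
less.

## Synthetic data

**Population structure and kinship.** SNP panels follow a Balding–Nichols
model: per-population allele frequencies are Beta draws around a common
ancestral frequency with variance controlled by a divergence parameter `d`
(F_ST-like, in [0,1)). Two levels of drift are simulated: populations
(default `d = 0.1`) and sib-like families of 6 genotypes inside each
population (family divergence 0.35, roughly full-sib-level relatedness).
The family level is essential, not decorative: if every pair within a
population is exchangeable, the between- and within-population kinship parts
span nearly the same covariance space and the σ_b²/σ_w² split is
unidentifiable — the REML likelihood is flat in exactly the direction Q_ST
measures. Natural collections are never exchangeable in this way. The
relationship matrix is the VanRaden cross-product of the simulated panel, so
kinship, SNP statistics and expression simulation are mutually consistent.

**Expression.** The latent log2 value of gene g in sample s of genotype i is

    z[g,s] = b[g,i] + w[g,i] + loading_g · F[module(g), i]
             + cofactor shifts + e[g,s]

with `b ~ MVN(0, σ_b² K_b)` and `w ~ MVN(0, σ_w² K_w)` over genotypes.
Module factors F are themselves drawn with covariance `K_w` (module activity
is heritable), so `loading²` adds to the within-population variance in the
same units the estimator uses; the planted truth records
`σ_w,total² = σ_w² + loading²` and computes h²/Q_ST from it. Loadings
decrease linearly from 1.0 at the module hub to 0.3 at the periphery.
Counts are negative binomial with gene-specific dispersion (log-normal,
median ≈ 0.05), gene-specific base means (log-normal around ~90 counts) and
log-normal library-size multipliers (SD 0.25). Defaults for dispersion and
library spread are free realism choices — no study values exist for them.

**Traits.** Each trait is driven by one or two modules: its additive effect
genes are the hub-most genes of those modules with coherent within-module
coefficient signs, plus optional products of hub genes across modules
(factor-by-factor epistasis), plus Gaussian noise scaled so the generating
predictor explains a planted signal fraction `q`. The coherent-sign choice
makes the trait track module activity the way real traits track module
eigengenes; with random signs the factor contributions cancel and the trait
degenerates into an idiosyncratic sparse signal no shrinkage regression can
recover at n ≈ 120 training genotypes.

## Kinship-split REML

`K_b` replaces each block of the relationship matrix by its population-pair
mean (within-population diagonals by the mean self-kinship, within-block
off-diagonals by the off-diagonal mean); `K_w` keeps kinship inside
populations and is zero elsewhere; both receive a 1e-6 ridge. The solver
runs 8 multiplicative fixed-point iterations (EM-flavoured, positivity
preserving) and then average-information Newton steps with step halving and
projection onto the non-negative orthant; a projected-gradient probe decides
boundary convergence. Non-convergence after 60 iterations is flagged on the
result, never silent. BLUPs are `û = σ̂² K Z' P y` at the final estimates;
the reported genetic value is `b̂ + ŵ`.

Cofactors flagged by the PCA check enter as fixed effects (block
categorical, date and hour continuous). Population may be flagged by the
PCA — genetic structure is visible in expression — but is never used as a
correction covariate, because it would absorb σ_b².

**Precision.** A Cramér–Rao analysis at the study design (11 populations,
200 genotypes, 2 replicates) gives a per-gene standard deviation for Q̂_ST
of ≈ 0.14–0.2 even for an efficient estimator; the observed median absolute
recovery error (≈ 0.10–0.12 over 500 genes) matches the bound, so the
estimator is essentially efficient and the residual error is an information
limit of having 11 population-level draws, not an implementation defect.
h² recovery is comfortably inside ±0.10.

## Network construction

Everything is rank-based: genes are Spearman-ranked once and all
correlations, kME values and module–trait correlations use the same choice
(a deliberate simplification versus mixing rank and bi-weight correlations;
one consistent correlation keeps the pipeline self-checking). Adjacency is
`((1+ρ)/2)^β`; the soft threshold is the smallest candidate whose signed
scale-free fit reaches R² = 0.85, else the recommended default 12.

Module detection is a simplified dynamic cut on topological-overlap
dissimilarity: average-linkage tree; candidate cuts at several join-height
quantiles (0.70–0.99) are scanned and the finest cut producing the most
clusters of at least `min_size = 30` wins — over-splitting is healed by the
eigengene merge rule (merge while any eigengene pair correlates above
1 − 0.25), under-splitting is unrecoverable, which is why a single fixed
cut height is fragile. A kME sweep then reassigns every gene to its best
module when |kME| ≥ 0.3 and to grey otherwise; this peels chained noise
genes off the branches. Grey has no eigengene; grey genes keep their best
|kME| over real modules as centrality.

## Gene sets, selection, prediction

Set sizes are `floor(0.10 · universe)` everywhere (3,422 at the full study
scale of 34,229 genes). The shadow-feature selection appends one freshly
permuted copy of every feature per iteration, fits a random forest
(100 trees, √p features per split, impurity importance — the standard
choices of the widely used Python port; out-of-bag permutation importance
costs two orders of magnitude more per iteration for no calibration gain at
these sizes), credits hits against the maximum shadow importance, and
decides features by a two-sided binomial test at p_hit = 0.5 with Bonferroni
correction over the undecided. Tentative features count as "not rejected"
when pooling.

Ridge is solved in closed form (dual form when p > n) with the penalty
chosen by 2-fold cross-validation on the training set over a 17-point
log-spaced grid. The neural network is a two-hidden-layer perceptron
trained by mini-batch Adam (batch 32): the random search covers
rectifier/tanh × with/without dropout, the six layer-size structures from
{h, 2h/3, h/3} with the second layer no larger than the first, input
dropout {0, 0.2} and L1/L2 penalties on [0, 1e-4] in 5e-6 steps, at most
100 candidates, winner by validation RMSE. Validation is scored every 5
epochs with patience 10 and tolerance 1e-3; the default budget of 200
epochs reflects that at ~120 training genotypes an epoch is only four
gradient steps — a 10-epoch budget leaves the network at initialization.
Accuracy is `R² = 1 − SSE/SST` on the untouched test set, never clipped;
squared correlation is available as an option. One split is shared across
all sets and algorithms per trait so set contrasts are not confounded by
split noise; `skip_full_nn` reproduces the practice of not fitting the
network on the full gene set.

## Validation benchmarks and their problem sizes

The benchmark module regenerates all inputs from a seed and reports:
design constants (459 samples; 3,422-gene sets; 272 module–trait tests;
6 network structures; 4,950 random-set pairs); h²/Q_ST recovery at
500 genes × 200 genotypes; module recovery on a planted 2-module + grey
design built at the genotype scale the network operates on (unit hub
loading, residual variance 0.25/2 — the per-sample noise SD of 0.5 after
averaging two replicates); selection calibration at 200 features ×
150 samples × 20 seeds; prediction sanity at 1,000 genes (ridge) and
300 genes (network contrast); F_ST recovery at 2,000 SNPs. These sizes keep
a full validation run to a few minutes on one CPU while staying at the
study's genotype and population counts.

Two calibration facts worth knowing. Nei's G_ST carries an inherent
(1 − 1/k) deflation with k demes, so a planted divergence of 0.2 is
recovered as ≈ 0.185 at k = 11 — recovery is tested at the study's deme
count. And with module-driven traits, random gene sets predict nearly as
well as planted-signal sets whenever the trait's module is large (the
redundancy phenomenon the analysis is about); the null-calibration
benchmark therefore plants the trait in a module covering 5% of genes.

## What the synthetic data does not show

The generator omits read-level artifacts (mapping bias, GC effects),
expression-dependent dispersion trends, linkage between the SNP panel and
the expression loci, genotype-by-environment interaction, and any family
structure more complex than equal-sized sib groups. Passing recovery tests
therefore demonstrates the estimators are correct and calibrated under the
stated generative model — not that the biological conclusions of any real
study are reproduced. The Q_ST information limit discussed above is a
property of the 11-population design and applies to real data too.
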