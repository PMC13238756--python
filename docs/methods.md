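# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## The synthetic landscape

The generator produces the data structure the analysis assumes rather than a
sequence-level simulation (no coalescent, no recombination map, dosages
rather than genotype likelihoods).

* **Geometry.** Populations are placed on a 1-D coastline with random
  segment lengths of 30–120 distance units; marine distance is the path
  distance, which makes it an exact metric and keeps IBD tests
  interpretable. A 1-D coastline (not a 2-D grid) matches coastal sampling
  designs and makes path distances exact.
* **Ancestry cline.** Per-site ancestry q follows a logistic in scaled
  coastline position with noise added on the logit scale,
  `q = logistic(s·(x - 0.7) + ε)`, `ε ~ N(0, 0.15)` truncated at ±0.45.
  Putting the noise inside the logit keeps the infinite-steepness limit
  exactly two pure blocks. The midpoint at 70% of the coastline gives the
  default cline its asymmetric span (≈ 0.05 at one end to ≈ 0.8 at the
  other), emulating a secondary-contact system in which one end is pure
  ancestral lineage and the other strongly admixed. The north/south flag is
  q thresholded at 0.5.
* **Environment.** Each variable is a standardized Gaussian process on the
  coastline (squared-exponential kernel, length scale one fifth of the
  coastline) — spatially autocorrelated like real climate layers. Variable 1
  is constructed as `ρ·standardize(q) + sqrt(1-ρ²)·GP` so the
  environment-ancestry confounding has a controlled magnitude
  (`env_ancestry_corr`, default 0.5).
* **Allele frequencies.** Balding–Nichols throughout: lineage frequencies
  `a, b ~ Beta(x(1-F_div)/F_div, (1-x)(1-F_div)/F_div)` around an ancestral
  `x ~ U(0.05, 0.95)`; the population base frequency is the admixture
  `m = q·a + (1-q)·b`; local drift draws `p ~ Beta` with mean m and
  F = `f_drift`. Balding–Nichols was chosen because it is the standard
  analytically checkable drift model: the tests verify realized FST against
  a brute-force Monte-Carlo of this hierarchy. Defaults F_div = 0.3 (deep
  lineage split), f_drift = 0.05 (moderate within-lineage drift) put
  pairwise FST in the few-percent range typical of strong philopatry.
* **Adaptive genes.** `n_adaptive_genes` (default 20 of 1000) are drawn at
  random; every SNP in an adaptive gene receives `logit(m) += β·env_value`
  before drift, with driver variables cycling through the environment
  table. Applying the effect on the logit scale keeps frequencies in (0,1)
  and makes β interpretable as a log-odds shift per environmental SD
  (default β = 1.5 — a strong, detectable but not fixed-difference signal).
* **Sampling and missingness.** Per-SNP per-population allele-copy counts
  are `2 × Binomial(n_ind_per_pop, 1 - missing_rate)` (default 20
  individuals, 20% missingness), emulating low-coverage data where the
  number of usable individuals varies by SNP. Missingness is independent
  Bernoulli per SNP×population (and per genotype in the dosage table) —
  real coverage is correlated along the genome and across individuals; the
  generator does not emulate that, so the tests say nothing about
  missingness that is structured or ancestry-biased.
* **What the table stores.** The frequency table holds the *true*
  post-drift population frequencies (the analogue of well-estimated
  population MAFs), not binomially resampled estimates. Consequence: the
  Hudson estimator's finite-sample correction slightly over-corrects at
  small n, and limit tests (FST → 0) use large n.

## Distances

Hudson/Bhatia FST with ratio-of-averages combination was chosen for its
unbiasedness from allele frequencies, independence from within-population
diversity, and the existence of a trivial per-SNP oracle. SNPs enter a pair's
estimate when the global folded MAF exceeds `maf_min` (default 0.01, strict
inequality) and both populations have ≥ 2 allele copies; the MAF mask is
global, not per-pair, so all pairs see the same SNP set. AFD is the mean
absolute per-SNP difference — literal, bounded, and robust. The p-distance
works on dosages (|Δg|/2 over co-observed SNPs); the scaled variant
multiplies by n_SNPs / genome_length to express differences per genome site.
Environmental distance standardizes variables, takes PCA, and keeps the
smallest axis count reaching the variance threshold (default 0.92);
an explicit axis count overrides it.

BIONJ follows Gascuel's variance-weighted reduction
(λ chosen to minimize the variance of the reduced distances, clamped to
[0,1]); agglomeration ties break on label order after sorting, so topology
is invariant to input order. Negative branch lengths are reported as
computed — clamping would destroy the exact-additivity property the tests
rely on.

## Structure summaries

PCA centers frequency matrices (populations as rows) or
Patterson-standardizes genotype matrices by sqrt(2p̄(1-p̄)) with per-SNP
mean imputation; axis signs are fixed by making the largest-magnitude
loading positive. LD is the squared Pearson correlation of dosages over
co-observed individuals within a 500 kb window; pruning builds a graph of
pairs with bp ≤ 200 kb and r² > 0.1 and repeatedly deletes the
highest-degree node (ties: larger incident r² sum, then larger position,
then id), a fully specified deterministic rule whose postcondition is
asserted.

Admixture inference itself is out of scope; the module post-processes
replicate Q matrices. Similarity between two runs is
`1 - (1/2N)·Σ|Q - Q'_aligned|` with the column alignment chosen by optimal
assignment — 1 for identical solutions up to label switching, and the 0.85
threshold then has the intended "same solution" semantics. Modes are
connected components at that threshold; the major mode is the largest
(ties: higher mean log-likelihood), averaged after aligning members to the
highest-likelihood member and re-normalizing rows. The Evanno statistic is
|L̄(K+1) - 2L̄(K) + L̄(K-1)| / sd(L(K)), undefined at the endpoints, +∞
with a warning when sd = 0.

## Mantel machinery and the isolation decomposition

Mantel r is the Pearson correlation of lower-triangle vectors; p-values are
one-sided (positive alternative — isolation hypotheses are directional)
from joint row/column permutations of the first matrix with the
(1+b)/(1+B) convention, so p is never 0. The partial test residualizes both
triangles on the covariate triangle and recomputes the residual correlation
for each permutation of the first matrix's labels; permuting labels rather
than residuals preserves the covariate's structure. If either matrix is
numerically fully explained by the covariate, the partial r is defined as 0.

The decomposition fits OLS of genetic distance on ancestry distance plus a
per-category intercept (category from the two sites' north/south flags).
No ancestry×category interaction is included by default — the simplest
model that "accounts for the pair category" — but `interaction=True`
exposes the alternative. Residuals are refolded into a symmetric matrix
whose diagonal is zero by convention and ignored. Per-variable IBE uses
|v_i - v_j| as the distance for each variable with marine distance as the
covariate; constant variables yield NaN rows rather than aborting the table.

## Scans and gene-environment association

The PCA-outlier scan standardizes genotypes, regresses each SNP on the
first k components (z-score = coefficient / residual SD), and converts the
k-dimensional z-vectors to robust Mahalanobis distances using an OGK
scatter estimate (normal-consistent MAD scale, Gnanadesikan–Kettenring
pairwise covariances, one orthogonalization pass) — implemented here
because no installed library provides OGK. Distances are rescaled by the
genomic inflation factor λ = median(D²)/median(χ²_k) and converted to
upper-tail χ² p-values with df = k by default; the df is exposed separately
because published analyses sometimes use k-1 degrees of freedom with k
components.

RDA centers the site×SNP frequency matrix (no Hellinger or per-SNP
scaling — frequencies are already bounded summaries), standardizes
predictors, fits by least squares, and takes canonical axes from the SVD of
the fitted values. For pRDA both response and predictors are first
residualized on the covariate (with intercept). R² is SS_fit/SS_total;
adjusted R² uses Ezekiel's formula. Axis significance is a sequential
pseudo-F permutation test with free row permutation of the (residualized)
response, stopping at the first non-significant axis (α = 0.05); squared
SNP loadings on retained axes are exported as scan statistics. Backward
selection removes the predictor with the largest drop-one marginal
pseudo-F permutation p while it exceeds `p_stay` (default 0.1), permuting
reduced-model residuals. Variance partitioning computes adjusted R² for
the seven set unions and solves the inclusion-exclusion system; the seven
signed components sum to the full-model adjusted R² by construction and
this identity is asserted at 1e-10. Negative unique fractions are possible
and reported as computed, as is standard for adjusted-R² partitioning.

The univariate GEA statistic is the absolute Spearman correlation between
population frequencies and each variable. It is a deliberately simple,
clearly labelled (`bf_analog`) per-SNP association score: the aggregation
and consensus machinery is agnostic to the statistic's source, and external
per-SNP tables (e.g., Bayesian association scores) can be supplied in the
same `ScanStats` form. The count writer rounds `p·n` and `(1-p)·n`
half-to-even (documented because rounding convention affects counts by ±1).

## Weighted-Z aggregation and consensus

Genes come from BED intervals (0-based half-open); a SNP at 1-based
position P belongs to [start, end) iff start ≤ P-1 < end, and genes with
fewer than 5 assigned SNPs are excluded from both testing and the
background. Higher-is-more-extreme statistics are converted to empirical
p-values by descending rank/(n+1) with average ties (making the aggregation
invariant to monotone transforms); p-value statistics are used directly.
Gene Z = Σ w_i z_i / sqrt(Σ w_i²) with w_i = p̄(1-p̄): under independent
null SNPs Z is standard normal regardless of SNP count, which is the
"correction for the number of SNPs". The gene p is the normal upper tail by
default; an empirical mode (descending rank of Z across genes) is provided
since published analyses often report empirical p-values — the choice is a
flag because either reading is defensible.

Top candidates use a strict p < 0.001. Pairwise overlap percentages use the
pairwise union as the denominator (the convention is ambiguous in the
literature this emulates, where reported percentages are internally
inconsistent at the ±0.2% level; the set arithmetic here is exact and the
convention documented). The consensus list is genes flagged by ≥ 2 methods.
Region enrichment is a 2×2 Pearson χ² (df = 1, no Yates correction —
immaterial at realistic background sizes, flag provided) with BH correction
across the whole (method, region-class) family; zero-margin tables are
reported NA. QTL proximity expands gene intervals by 100 kb on both sides
with half-open arithmetic. Term enrichment is a one-sided hypergeometric
tail with BH across terms; ontology parsing/propagation is out of scope —
the input is a flat gene→term map.

## Orchestration, formats, determinism

Internally intervals are 0-based half-open and SNP positions 1-based
(VCF convention); conversions happen in one function. TSV is the canonical
tabular format; VCF v4.2 (GT only, `./.` missing) for genotypes; Newick for
trees. Filters follow strict `>` for MAF and `≥` for the coverage fraction
(default 0.75). Every stochastic stage derives its seed from the config
seed, so a fixed config reproduces byte-identical outputs; disabled stages
make dependents fail fast with a named-dependency error.

## Problem sizes

The default simulated scenario is 30 populations × 20,000 SNPs, 1,000 genes
(20 adaptive), 20 individuals per population — chosen so the full pipeline,
the calibration studies (1,000 null Mantel replicates, 100 scan seeds) and
the recovery experiments (200 planted replicates) all run comfortably on a
single CPU while leaving every estimator in its well-behaved regime
(hundreds of pairs, thousands of SNPs per test). Calibration and recovery
claims are statements about this generator; transfer to real data depends
on features the generator omits (LD within genes, structured missingness,
estimation noise in frequencies).

## Known limitations

* Frequencies are true post-drift values, not resampled estimates; see above.
* No linkage is simulated within or between genes, so WZA operates in its
  independent-SNP regime; with real LD the effective SNP count per gene is
  lower and gene p-values are anti-conservative unless an effective-count
  correction is applied.
* The residual-substitution decomposition is least-squares and
  intercept-only per category; strong ancestry×category interactions would
  leak into residuals (the interaction variant is available).
* Mode clustering uses exact pairwise alignment (optimal assignment), which
  is O(runs² · K³); fine for tens of replicates, not thousands.
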