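# Methods

This note documents the models and procedures implemented in
`intertissue`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducibility.

## Study design and preprocessing

The package targets matched multi-tissue cohort designs: the same
individuals profiled in several tissues (the default emulation uses
liver, skeletal muscle, SAT and VAT in 60 severely obese individuals
split 28/32 into metabolically healthy/unhealthy groups). Raw
expression is quantile normalized per tissue (columns = samples) and
log2 transformed; the quantile-normalization tie rule assigns tied
entries the mean of the reference values at their tied ranks, and a rank
whose values already agree across all columns keeps that value
bit-identically, which makes the transform exactly idempotent. The log2
offset defaults to 1.0 and is configurable.

Individuals are aligned to one canonical column ordering across tissues.
Individuals missing from a tissue become NaN columns, and every pairwise
operation (per-gene cross-tissue correlations, correlation blocks) uses
the pairwise-complete individuals of its tissue pair within the group —
listwise deletion would discard usable samples. A configurable minimum
(default 10) of shared individuals per tissue pair per group is
enforced at alignment time.

Cohort summaries use Welch's unequal-variance t-test for numeric
phenotypes and the chi-square test without continuity correction for
categorical ones; constant phenotypes are reported with p = 1 and a
flag. The chi-square variant is a documented choice: several
chi-square-family tests give values in the 0.43–0.44 range on a typical
21/7 vs 21/11 sex split, and the implementation does not attempt to
match any particular published rounding.

## Differential inter-tissue connectivity

For each gene present in all tissues, the Pearson correlation of its
expression between every unordered tissue pair is computed separately
per group; the score is the sum over pairs of the absolute between-group
difference. Undefined correlations (constant vectors) are excluded from
the sum and flagged rather than imputed as zero, which would silently
shrink scores. P-values for single correlations use the
t-approximation t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.

Because no fixed threshold defines an "altered" gene, the package
exposes both the ranking and a group-label permutation test: labels are
permuted within the matched individual set and the empirical p is
(1 + #{permuted ≥ observed}) / (n_perm + 1). Note a caveat inherent to
this null: for a gene with genuine group-specific coupling, permuted
groups mix individuals from both phenotypes, so partial coupling
survives in both permuted groups; the permutation p is conservative in
small cohorts. With ~28–32 individuals per group the sampling noise of
a single correlation is large (sd ≈ 0.19 under the null), so scores of
null genes spread widely; rankings among a few hundred genes should be
read together with the permutation p, not alone.

## Inter-tissue network construction

Per group, all (gene, tissue) nodes are stacked in tissue-major order
and the full correlation matrix is assembled blockwise: diagonal blocks
are within-tissue gene-gene correlations, off-diagonal blocks the
correlations of every gene in one tissue with every gene in another.
The matrix is exactly symmetrized and given a unit diagonal. A
diagnostic compares within- vs inter-tissue entry distributions (Welch
t on Fisher-z transformed entries) and flags imbalance at α = 0.05.

Soft thresholding defaults to the unsigned network a = |r|^β with β = 6:
modules of interest mix strong positive and negative correlations, which
only an unsigned network groups together. A scale-free-fit power picker
(R² of log frequency vs log connectivity over log-spaced bins; smallest
β reaching R² ≥ 0.8 with negative slope, else the default with a
warning) is provided for data-driven choices, including β = 1 (no
thresholding). The adjacency diagonal is zero; the TOM formula

TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  l_ij = Σ_u a_iu a_uj

then excludes self-terms naturally, and 1 − TOM (zero diagonal) is the
clustering dissimilarity. Clustering is average-linkage agglomeration;
ties merge in nearest-neighbour-chain order, which joins the
lowest-index pair among equidistant points.

### Dynamic tree cut

The module cut is dendrogram-only (no dissimilarity-based PAM stage).
Two adaptive thresholds, both expressed as fractions of the maximum
merge height, drive it:

* a **core** is a minimal branch with ≥ `min_module_size` leaves whose
  top merge lies below `cut_height_fraction · max_height`;
* each core then absorbs stragglers: any subtree joining a single core's
  branch below `absorb_height_fraction · max_height` (and containing no
  other core) is assigned to that core's module.

Leaves outside every such branch stay grey; modules are named by
descending size with the standard WGCNA color sequence (turquoise, blue,
brown, …). Both fractions default to 0.95. The rationale: on dense TOM
dissimilarities most entries concentrate near 1, and the merge heights
form bands — planted-module branches complete by roughly 0.93·max,
while spuriously correlated and plain noise leaves attach between about
0.975·max and the maximum. A cut anywhere in the gap separates them; a
cut at the 99th percentile of merge heights (or 0.99·max) sits inside
the noise band and either absorbs noise into giant modules or fragments
real branches. The 0.94–0.97 range behaves equivalently on planted
data, so 0.95 is not a knife-edge setting.

Module eigengenes are the first right-singular vector of the
row-standardized member × individual matrix, sign-aligned so the
correlation with the mean member profile is nonnegative (first member
when the mean vanishes, as with two antipodal members); the proportion
of variance explained is reported. Module membership (kME) is the
correlation of a node's expression with a module eigengene, with
configurable reporting cutoffs (0.6 and 0.9 are conventional).
Eigengene-covariate association uses Pearson correlation (point-biserial
via 0/1 coding for binary covariates).

## Module edge comparison

For a module's tight core (own-module kME above a cutoff, default 0.6),
all node-pair correlations are computed per group over the appropriate
matched individuals, giving per-edge |Δr| tables sorted by difference.
Edge lists are exported as Cytoscape-importable TSVs (per group plus
combined), with endpoint tissue as attribute columns; edges below
|r| = 0.1 in both groups are omitted by default purely to limit visual
clutter.

## cis-eQTL stage

Genotypes are 0/1/2 dosages (read from GT-only VCF via cyvcf2, or a
dosage TSV). QC applies the conventional strict thresholds — call rate
> 0.95, Hardy-Weinberg exact p > 1e-4, MAF > 0.05 — with failing SNPs
retained in the QC report with reasons. The HWE test is the exact
conditional test: the summed probability of heterozygote counts no more
probable than the observed one given the allele counts, computed in log
space and verified against exact-rational enumeration.

cis pairs are same-chromosome SNP-probe pairs within 1 Mb of the probe
position (inclusive at exactly 1 Mb; probe intervals reduce to their
midpoint). Association defaults to Spearman rank correlation with the
t-approximate p (a linear additive regression is available via
configuration). FDR control permutes expression sample labels against
fixed genotypes (default 10 rounds, preserving the correlation structure
across probes), takes the best p per probe, and estimates
FDR(x) = mean permuted count of best-p ≤ x over the observed count,
clipped to [0,1] and made monotone non-decreasing; SNP-level granularity
is available via configuration. Ten permutations bound the resolution
of the null: the FDR estimate is coarse but unbiased in expectation, and
calibration is checked under a global null in the benchmark suite.
Missing dosages are excluded pairwise, never imputed. Mapping runs per
tissue independently.

## Synthetic-data generator

The generator emulates the matched two-group, four-tissue design with
known planted structure:

* **Modules**: member = sqrt(ρ)·factor + sqrt(1−ρ)·noise per individual,
  so the expected pairwise correlation is analytically ρ (default
  experiments use ρ = 0.7–0.8 and module sizes 60–80, with minimum
  module size 50 in detection).
* **Crosstalk**: the *same* gene in the tissues of a pair set shares one
  per-individual latent factor only in the specified group, with target
  correlation r per coupled pair (the liver/SAT/VAT clique at r = 0.6
  mirrors the cytokine pattern the method is built to find). The factor
  acts on the union of the named tissues, so a non-clique pair set also
  induces correlation on its omitted pairs — a documented approximation.
  A negative target flips the loading of the first tissue.
* **Covariates**: age/sex/glucose/HbA1c/BMI drawn to resemble a severely
  obese surgical cohort, with the unhealthy group older and more
  hyperglycemic on average.
* **Genotypes**: per-SNP binomial(2, MAF) dosages (random mating), with
  optional missingness; planted cis effects add effect·SD-of-residual
  per alternate allele to the designated probe, on the
  normalization-scale data. Probe coordinates are spaced 2.5 Mb apart
  on one chromosome so each probe's 1 Mb cis window is private.
* Conflicting assignments (one gene-tissue slot claimed by both a module
  and a crosstalk spec) raise an error naming the gene. One global seed
  expands into independent per-component child seeds
  (`SeedSequence.spawn`, order: expression, phenotypes, genotypes,
  missingness), so stages regenerate independently.

What it does **not** emulate: probe-level intensity distributions, batch
effects, imputation uncertainty, linkage disequilibrium between SNPs,
population structure, or realistic gene-gene correlation beyond the
planted factors. Benchmarks passing on this generator show the
pipeline's operations recover the structures they are defined to
recover at realistic sample sizes; they do not certify performance on
real arrays with those additional complications.

A note on scale: the generator emits data already on the
quantile-normalized log2 scale, and the pipeline's quantile step is
therefore a config flag. Re-normalizing a small synthetic matrix (a few
hundred genes of which a planted module is a large fraction) visibly
attenuates the module's correlations, because quantile normalization
removes column-level shifts and a module that dominates the column
distribution *is* such a shift. On genome-scale matrices (tens of
thousands of rows) the effect is negligible.

## Benchmark experiment sizes

The benchmark suite (`intertissue.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) uses 20 seeds or
replicates per experiment at the design's own dimensions — 4 tissues ×
200 genes × 60 individuals for recovery experiments, 50-node matrices
for the TOM oracle, 20-leaf dendrograms for the linkage oracle, 200
random genotype tables (n ≤ 200) for the HWE oracle, and 50 probes ×
~150 SNPs for the eQTL calibration — completing in about a minute on a
single CPU.

At these sample sizes the differential-connectivity experiment is
informative about limits as well as strengths: with 28/32 individuals
per group a planted liver/SAT/VAT coupling at r = 0.6 yields scores
(~2.5) of the same order as the maximum over ~200 null genes (~2.5), so
both planted genes top the ranking in only a minority of runs, and the
(conservative, see above) permutation test clears p < 0.05 for both in
roughly two thirds. Detecting such genes reliably at desk scale
requires either stronger coupling, fewer candidate genes, or larger
groups; the benchmark reports the measured rates rather than asserting
otherwise.

## Known limitations

* Correlation-based throughout; no covariate adjustment inside the
  network or eQTL models (age/sex checks are post-hoc on eigengenes).
* The dynamic cut is the dendrogram-only variant; very close or nested
  modules that a PAM-based hybrid cut could separate may merge or leave
  stragglers grey.
* Permutation FDR with 10 rounds has coarse resolution at small pair
  counts; raise `n_perm` when precision near the 0.05 boundary matters.
* The per-gene connectivity score treats tissue pairs symmetrically; it
  does not localize which pair drives a difference (the per-pair columns
  in the output table do).
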