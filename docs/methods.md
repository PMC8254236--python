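# Methods

This note documents the statistical models, parameter choices and known
limitations of the `serous` pipeline, in the order data flows through it.

## Differential expression

Genes are first restricted to those quantified in every sample (the
intersection filter); missing cells are explicit NaN and are never
zero-filled, so a gene absent from one sample's quantification drops out
rather than biasing the test.

The two-group test is the pooled-variance two-sample Student's *t* with
df = n₁+n₂−2, computable identically from raw vectors or from per-group
(mean, SD, n) triples (sample SD, denominator n−1).  The pooled form was
chosen over Welch because the published per-gene p-values of the discovery
cohort are consistent with pooled degrees of freedom: recomputing all 28 of
them from the printed summary triples reproduces every printed p-value
within a factor of 1.02.  Welch remains available behind a flag.  Zero
pooled variance is degenerate: equal means give (t=0, p=1), unequal means
(t=±inf, p=0) with a degeneracy flag.

Fold changes are signed: r = m₁/m₂ is reported as r when r ≥ 1 and as −1/r
otherwise, so magnitude is always ≥ 1 and sign encodes direction.  Zero
denominators are an error by default; an optional pseudocount (0.01 FPKM)
can be enabled explicitly, but is off so that worked examples on published
means are not silently distorted.  Selection uses the nominal p < α with no
multiple-testing correction — the discovery groups have 3–7 samples, where
FDR control would have no power — but Benjamini–Hochberg q-values are
reported alongside for the reader.  Ties in the |FC|-descending output
order break lexicographically by gene id for determinism.

Stage-wise validation comparisons use the two-sided Mann–Whitney U: exact
null distribution when the combined n ≤ 20 and there are no ties, the
tie-corrected normal approximation otherwise; fully tied input returns
p = 1.

## Unsupervised structure

PCA is an eigendecomposition of the sample covariance matrix (samples are
observations, genes variables); no correlation scaling is applied, matching
the covariance-PCA convention, with an optional log2(x+1) transform.  The
sign convention makes each component's largest-magnitude loading positive.
Score-plot confidence ellipses use the bivariate-*t* radius
r² = 2·F⁻¹(level; 2, n−2) on the group's sample mean and covariance —
the classical form of the "within 80% confidence interval" ellipse; the
robust scale variant (cov.trob-style iterative reweighting) is not
reproduced.

Hierarchical clustering is agglomerative with Euclidean distances and
complete linkage by default (single/average/ward selectable), serialized to
Newick with branch lengths derived from merge heights.  One empirical
caveat discovered during validation: on raw FPKM the discovery cohort's
ribosomal genes (SDs in the hundreds to thousands) dominate the metric and
the top split tends to isolate outlier samples; on log2(x+1) values the top
split separates SBT from HGSOC in every tested seed.  Clustering of
expression matrices should therefore use the log2 transform; the raw scale
remains the PCA default.

Methylation-style site selection ranks sites by beta-value range (max −
min across samples) and keeps the top k, ties broken by site id.

## GO enrichment (tree-travel / transform / t-test)

Annotations are propagated to all ancestors over is_a edges (transitive
closure; cycles are a hard error naming an offending edge).  The expression
universe is the expressed genes (mean FPKM > 0 within the queried sample
group).  "Transform" is interpreted as log2(x+1) applied to the per-gene
mean within that group — the reference describing the method names the
step but not the function, so the choice is recorded here and exposed as a
flag.  Per term, the in-group gene values are compared with all remaining
expressed genes by the same pooled *t* as the DEG module; n therefore
counts genes, not samples.  Terms with fewer than 2 expressed in-group
genes or fewer than 2 out-group genes are skipped.  No multiple-testing
correction is applied (BH q reported).

## Nested cross-validation

Stratified 3-fold outer/inner nested CV: the inner grid search maximizes
accuracy over min_samples_split ∈ {2,4,8,16} × max_depth ∈ {2,4,8,None}
(the grid spans the bias/variance range for cohorts under ~300 samples and
is configurable), the refit model is scored once on the held-out outer
fold, which the search never sees (asserted by fold-index bookkeeping).
Stratification keeps the rare class present in every fold; random forests
default to 500 trees; all randomness derives from one seed.

## Promoter motif pipeline

Promoters are the 2000 bp upstream of the TSS, strand-aware (minus-strand
promoters are reverse-complemented downstream sequence), truncated and
flagged at contig edges.

Scanning scores every window on both strands with log2 odds against a
0-order background estimated from the scanned set.  Scores are discretized
onto an integer grid of ~1000 steps and the exact null distribution of the
window score under the background model is computed by dynamic programming
(per-column convolution); a hit is any window whose exact null tail
probability is below the threshold.  The default threshold is 1e-4 (the
FIMO convention).  Note the expected number of null hits per 2-kb promoter
at p = 1e-4 is ≈ 0.8 across both strands, which inflates background
coverage of *every* motif by ~0.3; pipeline runs that feed the coverage
filter therefore scan at p = 1e-5 (≈ 0.04 expected null hits per
promoter), which the experiment drivers set explicitly.  Windows containing
N are skipped; a zero-probability PWM cell with no pseudocount is an error
(infinite log-odds).

Ranking fits two 500-tree random forests on the binary promoter × motif
occurrence matrix — one per split criterion (Gini impurity; entropy, i.e.
information gain) — and ranks motifs by mean decrease in impurity,
retaining the union of the top 20 under each criterion.  Coverage
(fraction of promoters of a class containing ≥1 hit) is the class-wise
column mean of the occurrence matrix.  Filter regime A keeps motifs with
c_fg ≥ 0.50 and c_bg ≤ 0.35; regime B keeps c_fg ≥ 0.80 and c_bg ≤ 0.35
(non-strict inequalities on the keep side).  Near-duplicate survivors
(pairwise match p < 0.001) are deduplicated keeping the higher foreground
coverage.  Single-motif accuracy is the fraction of all promoters
correctly classified by the presence rule "foreground iff the motif
occurs"; with a 1:4 foreground:background design its floor is the majority
class fraction 0.8.

Motif matching uses the mean per-column Euclidean distance over the best
ungapped alignment (both orientations, overlap ≥ 4 columns).  The
empirical null is n = 10⁴ column-shuffled database motifs (shuffling
preserves per-column sharpness), with the add-one p-value
(1 + #{null ≤ observed}) / (n + 1); matches at p < 0.001 are significant.
Because exactly repeated columns can tie a shuffled null at distance 0,
synthetic PWMs are generated with Dirichlet-jittered columns, as in
empirical frequency matrices where no two columns are identical.

TF binding evidence counts, per TF, the promoters overlapped (half-open
interval intersection) by at least one ChIP-seq site interval, ranked by
count with name tie-breaks.  K-mer seed discovery ranks k-mers by a
two-proportion z-score of per-sequence presence (either strand) in
foreground vs background and extends top seeds to PWMs by averaging all
foreground windows within Hamming distance 1 (reverse-strand occurrences
complemented into motif orientation) — a deliberately simple stand-in for
external de-novo discovery ensembles; any candidate PWM list can be
supplied instead.

## Survival association

Per gene, each patient's expression is z-scored against the diploid
reference: z = (x − median of diploid values) / SD of diploid values.  The
median center with SD denominator follows the portal convention the
z-threshold phrasing comes from; mean-centering is a flag.  Patients with
|z| ≥ 2 in either direction form the altered group.  Survival curves are
Kaplan–Meier product-limit estimates (right-censoring handled) and group
comparison is the standard two-group logrank test with hypergeometric
variance, p from chi-square with df = 1; a comparison with no events at
all is degenerate and returns p = 1.

## Synthetic data: what it emulates, and what it does not

The expression generator draws truncated-at-zero normals per gene and
group.  With moment matching enabled, draws are affinely rescaled so the
realized group mean and SD equal the targets exactly (to 1e-9); for
strongly skewed targets where a rescaled normal sample cannot stay
non-negative (e.g. mean 0.24, SD 0.53 — a nearly silent gene with
bursts), the base draw switches to a right-skewed gamma and retries until
feasible, so such genes are skewed rather than normal, as real FPKM of
low-abundance genes is.  The defaults replay the published study design:
4 SBTs vs 3+4 HGSOCs, per-gene moments from the published tables, and a
validation-shaped cohort of 18 vs 267.

Planted promoter sets place one PWM-sampled site (uniform strand, uniform
position, overwriting the background sequence) in exactly round(f·n)
sequences of each set; background sequences are i.i.d. from a configurable
base composition (uniform by default — the real promoter GC landscape is
not modeled), and the background set is 4× the foreground size.  Synthetic
"known TF" PWMs use length 10–16 with per-column dominant-base frequency
~0.95 under Dirichlet jitter (≈ 1.6 bits/column), matching curated-database
sharpness.  Survival times are exponential with hazard
baseline · exp(Σ β_g z_g) and independent exponential censoring scaled to
the requested expected censoring fraction.  GO plants multiply member-gene
expression by 2^δ (a δ shift in log2 units) on a random-tree DAG.

What passing tests on these inputs do **not** show: robustness to
library-size artifacts, batch effects, dependent genes (all genes are
drawn independently), non-exponential hazards, promoter GC/CpG structure,
or overlapping/nested real GO terms.  The external validation datasets and
their published accuracies and survival p-values are not reproduced — the
synthetic cohorts only mirror their shapes and the published effect sizes.

## Problem sizes and numerical choices

Simulation experiments run at desk scale, chosen once: the classification
property uses 20 cohort draws of 285 samples with a reduced inner grid
({2,8} × {4,None}) and 100-tree forests (the property concerns class
separability, which is insensitive to forest size); the motif-recovery
property uses 40 seeds of 20 foreground + 80 background full-length 2-kb
promoters, 1 planted + 49 decoy candidates, and a 10-motif database with
10⁴-shuffle match nulls; null calibrations use 500 replicates per
statistic and compare the false-positive rate at α = 0.05 against the 99%
binomial band.  The reproduction script (`scripts/acceptance.py`) uses the
same drivers with 10–12 seeds per simulation family.  Score discretization
uses ~1000 bins over the motif's log-odds range; all tie-breaks
(ranking, sorting, dedup) are lexicographic for bit-reproducibility; every
stochastic component takes an explicit integer seed.
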