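# Methods

`coexffl` re-implements, as a tested pipeline, a network-inference workflow
for paired tumor/normal expression studies (the motivating use case is
non-small cell lung cancer, NSCLC): meta-differential expression across two
microarray cohorts, weighted gene co-expression network analysis, dense
protein-interaction cluster detection, enrichment-based hub-gene calling,
miRNA–TF–gene feed-forward-loop (FFL) assembly, and median-split survival
analysis. Every stage operates on plain-text inputs; a simulator generates all
of them with planted ground truth so the whole chain is testable offline.

## Meta-differential expression

Each dataset is a log2 genes-by-samples matrix in which every subject
contributes one tumor and one normal column. Per dataset, each gene gets a
classic paired t-test p-value on the tumor-minus-normal differences
(t = mean(d)/(sd(d)/sqrt(n)), df = n−1, two-sided). p-values are combined
across the k datasets with Fisher's statistic X = −2·Σ ln p ~ χ²(2k) and
adjusted with Benjamini–Hochberg (step-up, via statsmodels). A gene is called
up (down) when the adjusted p is strictly below `alpha = 1e-4` and the pooled
log2 fold change — mean over all tumor samples minus mean over all normal
samples, pooled across datasets — is strictly above 1.5 (below −1.5).

Numerical choices: p-values of exactly 0 are clamped to the smallest positive
normal float before the logarithm so X stays finite; genes with zero-variance
differences get a missing p (logged) and are excluded from the BH test count
m; matrices whose maximum exceeds 30 are assumed unlogged and are
log2(x+1)-transformed with a warning. Probe-level matrices are collapsed to
symbols by averaging duplicate-symbol probes per dataset before the
cross-dataset intersection; per-dataset fold changes are emitted alongside the
pooled value for audit.

## Co-expression network and modules

The network is unsigned: similarity s_ij = |cor(x_i, x_j)| (Pearson), raised
elementwise to a soft power β (a_ij = s_ij^β). β is the smallest integer in
1..20 whose connectivity distribution satisfies the scale-free criterion at
signed R² ≥ 0.80, where the fit regresses log10(bin frequency) on
log10(mean k) over 10 equal-width bins of k and the R² is signed by the
negated slope so only decaying distributions score positively. When no power
reaches the target, the fallback is the argmax power if any candidate shows a
decaying distribution, otherwise the standard unsigned-network default power
by sample count (6 for more than 40 samples) — small block-structured
networks are never scale-free, and maximizing a negative fit index would
systematically select the weakest network.

Adjacency is converted to the standard unsigned topological overlap
ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with ℓ_ij = Σ_u a_iu·a_uj,
and 1 − ω feeds average-linkage hierarchical clustering. Module detection uses
an adaptive height cut — a deliberately simplified variant of dynamic tree
cut: candidate cut heights (midpoints between consecutive merge heights in the
upper dendrogram tail; `deep_split` 0–4 maps to the 0.90/0.75/0.50/0.25/0.10
height quantile that bounds the searched tail) are scanned and the cut kept
that maximizes the number of clusters with at least `min_module_size = 30`
genes, breaking ties toward fewer unassigned genes, then the coarser cut.
Branches below the size floor become the grey (unassigned) module. Over-split
halves of one true module are re-joined by the eigengene-merging step below,
which is why the scan can afford to favor more clusters.

Module eigengenes are the first principal component of the row-standardized
module submatrix, unit variance, sign-oriented to correlate non-negatively
with the module mean profile. Modules whose eigengene dissimilarity
1 − cor(ME_i, ME_j) falls below `merge_height = 0.2` (correlation above 0.8)
are merged iteratively, closest pair first, recomputing eigengenes after each
merge; the larger module's label survives. Connectivity statistics follow the
intramodular definitions (k.in and ω.in sum adjacency/TOM weights over
same-module partners, kTotal over all genes, kOut = kTotal − k.in,
kDiff = k.in − kOut; diagonals excluded). kME is the correlation of a gene
with each eigengene; genes whose best |kME| is below 0.7 are reassigned to
grey once, after merging. Representative genes have module membership
(own-module kME) strictly above 0.9.

## Dense PPI clusters (MCODE)

The interaction network keeps edges with combined score strictly above 0.9
(scores on a 0–1000 scale are auto-detected and rescaled). The cluster
detector follows the seed-and-expand MCODE scheme: each vertex with degree
≥ 2 is weighted by the density of the highest k-core of its closed
neighborhood times that core number; seeds are taken in decreasing weight
order and expanded breadth-first, admitting unassigned neighbors whose weight
is at least seed weight × (1 − 0.2); the haircut step iteratively removes
vertices with fewer than two connections inside the cluster; clusters smaller
than 3 vertices are discarded and vertices belong to at most one cluster.
Cluster score = density × vertex count = (2E/(n(n−1)))·n, reported to three
decimals. Ranking ties break by node count, then lexicographically smallest
member; the procedure is fully deterministic. The fluff stage is not
implemented (the configured cut style is haircut).

## Enrichment and hub genes

Query genes (the top cluster) are tested against GMT libraries with the
upper-tail hypergeometric probability P(X ≥ overlap); the population defaults
to the union of the library's term genes and can be overridden — p-values
depend strongly on this background, so the pipeline exposes it explicitly.
BH adjustment is applied within each library (a global-BH switch exists).
Hub genes are the intersection, over every term significant at BH-p < 0.001
across all libraries, of the term's overlap with the query; an empty
intersection is a reported outcome, not an error.

## FFL assembly and motif

miRNA target edges survive when score > 0.95 (strict) and the binding region
normalizes to 3'UTR; TF-binding edges when p < 0.001 (strict). A two-tier
screen then keeps regulators on the tier-1 (literature) list, and miRNAs only
if additionally present in mouse target tables filtered with the same
thresholds (conservation screen; applied to both miRNA→gene and miRNA→TF
edges by default, switchable to genes only — the stricter reading is the
default because conservation evidence for a regulator should not depend on
which edge cites it). Species prefixes (hsa-/mmu-) are stripped and names
lower-cased before cross-species matching. Surviving typed edges merge into a
simple digraph. A closed FFL is a (miRNA, TF, gene) triple with edges
miRNA→TF, TF→gene and miRNA→gene; triples sharing miRNA and gene merge into
composite instances, and the highest-order motif maximizes the summed degree
of its constituent nodes in the merged network ("order"), ties broken toward
more TFs and then lexicographic names. The alternative reading of
highest-order (maximum single-node degree) was rejected because a composite
instance is characterized by all of its nodes.

## Survival

Cohorts are split at the median expression of the queried gene, ties to low
(equivalent to a 50:50 percentile split on distinct values). Kaplan–Meier
curves use the product-limit estimator (lifelines; deaths processed before
censorings at ties); the median is the smallest time with S(t) ≤ 0.5 and is
flagged undefined when never reached. The log-rank statistic and the hazard
ratio share one observed/expected table over the distinct event times; the
HR is Mantel–Haenszel, (O_h/E_h)/(O_l/E_l), with Var(log HR) ≈ 1/E_h + 1/E_l
and a 95% Wald interval. A Cox fit would add nothing to this univariate
contract but can diverge from MH in small samples; the MH choice matches how
univariate web survival tools report HRs.

## Synthetic data: what it emulates, and what it does not

One integer seed fans out to fixed per-generator substreams, so every
generator is byte-reproducible and independently seeded. Defaults are the
study conditions used throughout the tests: 300 genes, two cohorts of 50
tumor/normal pairs, half the genes differentially expressed with mean
|log2FC| 2.0 (log2 units), three latent-factor modules of 60/50/40 genes at
loading 0.9 and residual SD 0.5, a planted 12-gene clique containing the 5
differentially expressed hub genes, one composite FFL (1 miRNA, 2 TFs, 1 hub
gene), and a hub-gene log-hazard of ln 2.

Expression is simulated directly on the log2 scale: gene g in sample s is
baseline_g + dataset offset + loading·f_{m,s} + shift_g·1[tumor] + noise, with
one latent factor f per module and sample. Intra-module correlation is
analytically loading²/(loading² + noise²) ≈ 0.76 at the defaults, before the
condition contrast. Whole modules share a direction of regulation
(alternating up/down), as disease modules do; this means genes responding in
the same direction are correlated across module boundaries through the shared
tumor/normal contrast — a realistic feature that the module detector must
overcome. The PPI generator plants a fully connected clique with
supra-threshold scores inside an Erdős–Rényi background with mixed scores.
The gene-set generator writes two libraries in which at least two planted
terms contain the whole hub set padded with non-clique genes (so the
significant-term intersection pins down exactly the hubs) plus random decoy
terms. The regulatory generator emits the planted FFL with passing scores and
screen membership, and decoys that each fail exactly one filter or screen
tier. The survival generator drives all prognostic genes with one latent
aggressiveness factor (they are one tight module) plus N(0, 0.1) measurement
noise, and multiplies the exponential baseline hazard (scale 60 months) by
exp(coeff · 1[factor above its median]) — so the true high/low cohort hazard
ratio is exp(coeff) by construction and a median split on any hub gene
recovers it. Censoring is independent of the covariates: a subject is
censored with probability `censor_rate` at a uniform fraction of its event
time.

Not emulated: probe-level (CEL) intensities, batch effects beyond
dataset-specific per-gene baselines, non-proportional hazards, dependent
censoring, and the long-tailed degree structure of genome-scale co-expression
networks (the 150-gene module fixture is deliberately small and block
structured, which is why the scale-free target is typically not reached and
the documented fallback power engages). Passing tests therefore demonstrate
correctness of the statistics and recoverability of planted structure at
realistic effect sizes — not performance on genome-scale microarray data,
where probe collapse and annotation versions also perturb counts.

## Degenerate inputs and tie rules

Zero-variance genes abort similarity construction; an all-equal dissimilarity
yields a single module; fewer genes than the module size floor yields all
grey with a warning. MCODE on a path graph emits nothing (all weights fall
below the seed rule or haircut empties the candidate). Median splits on
constant expression are errors, as are log-rank tests with an eventless
cohort. All ranking ties (cluster order, motif choice, color assignment) have
explicit deterministic tie-breaks described above.

## Problem sizes used by the test suite

The default fixture (300 genes × 200 samples, two cohorts) runs the full
pipeline in a few seconds. Calibration tests use 100 null replicates of the
meta-analysis (200 genes, 20 pairs × 2 datasets) and 500 null replicates of
the log-rank test (100 subjects); oracle-equivalence tests use 100 random
instances per operation at sizes where exhaustive brute force is feasible
(≤ 12 nodes for topological overlap, ≤ 8 for the MCODE weight enumeration,
≤ 50 p-values, ≤ 30-gene universes, ≤ 20 subjects, ≤ 30-node regulatory
networks). Hazard-ratio recovery uses 1000 subjects.
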