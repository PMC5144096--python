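# Methods

## Copy-number classification

Calls operate on COSMIC-style tumor exports: one row per aberrant segment
per sample, with the segment's total (both-allele) copy number and the
sample's genome-wide average ploidy. The classifier is a pure function of
(total_cn, avg_ploidy) with the thresholds as configuration
(`CnvThresholds`; defaults 2.7 / 0 / 5 / 9):

* loss: (ploidy ≤ 2.7 and total_cn = 0) or (ploidy > 2.7 and
  total_cn < ploidy − 2.7)
* gain: total_cn ≥ 5 (ploidy ≤ 2.7) or total_cn ≥ 9 (ploidy > 2.7)

Inequalities are applied exactly as stated (≤ 2.7 belongs to the
near-diploid regime; loss at low ploidy requires total_cn exactly 0). Loss
and gain are mutually exclusive for all valid inputs, which the classifier
asserts and the test suite verifies on a 200 × 200 grid.

Aggregation to a (gene, sample) call is needed because the source data are
segment-level and a gene may be covered by several segments. We classify
per segment, then aggregate: any loss and no gain → loss; any gain and no
loss → gain; both → *ambiguous*, excluded from loss and gain counts (a
conservative choice for a genuinely underdetermined case). A pair with no
overlapping segment is copy-neutral by the export convention and counts as
diploid; a pair covered only by neutral segments is diploid only when every
covering segment has total copy number exactly 2. The frequent-loss filter
keeps genes with n_loss ≥ ratio × n_gain (default ratio 2) **and**
n_loss ≥ 1 — the floor prevents genes with no CNV at all from passing
vacuously when n_gain = 0.

## Genomic intersection

Coordinates are 0-based half-open throughout (BED convention); a gene
partially covered by a segment inherits the segment's call (any-overlap,
≥ 1 bp), strand is ignored, and chromosome names are compared as exact
strings with an optional strip-`chr` normalisation flag. The join is a
per-chromosome sort-then-sweep with a min-heap of active genes keyed by end
coordinate — O((n + m) log n + k) — validated against a quadratic
all-pairs oracle on random instances.

## Diploid-baseline Z-scores and concordance

Per gene, μ and σ (sample SD, n − 1 denominator) are computed over the
samples flagged diploid at that gene; expression columns absent from the
CNV table are treated as diploid, consistent with the aberrant-only export
convention. Baselines with fewer than two diploid samples or σ = 0 are
flagged unusable and reported in a side table; their Z-scores are NaN,
never a silent 0. A sample is concordant for a gene iff it has a loss call
and Z **strictly** below −2. No transform is applied to the expression
values by default (Z-scores are location/scale-free, so a positive linear
rescaling of any gene's row leaves them unchanged — a property test). The
over-expression call (Z > 2) exists in the API but plays no role in the
concordance path. "Top" genes are those concordant in strictly more than
`top_gene_min_samples` (default 50) samples.

## Enrichment

Standard over-representation: p = P(X ≥ k) for X hypergeometric over the
background N, term size K, query size n, computed via the scipy survival
function; Benjamini–Hochberg step-up across tested terms. The background is
the intersection of the annotation's gene universe with the analysis
universe (configurable). Terms with zero query overlap are not tested —
they are uninformative and only inflate the BH denominator (configurable
`min_overlap`). A DAVID-style EASE variant (discounting one overlapping
gene) is available but off by default. Specificity follows the permutation
recipe: R (default 100) query sets of the observed size drawn uniformly
without replacement from a configurable gene pool, each run through the
full enrichment; we report per-term re-enrichment frequency and the add-one
empirical p (count + 1)/(R + 1), leaving any thresholding to the user.

## Sub-network extraction (Klein–Ravi)

Node-weighted Steiner tree approximation by greedy spider merging:

* one singleton tree per terminal (seed gene) present in the graph;
  terminals missing from the graph are reported, not fatal — partial seed
  coverage is normal for pathway-derived networks;
* nodes already bought by any tree have residual weight 0; distances are
  node-weighted shortest paths (unit weights by default) computed with
  `scipy.sparse.csgraph.dijkstra` on a directed matrix in which edge u→v
  costs the residual weight of v, multi-sourced from each tree;
* each round selects the centre v and the prefix S of trees (sorted by
  distance from v) minimising (w(v) + Σ_{t∈S} dist(v, t))/|S| with |S| ≥ 2,
  merges S along the predecessor paths, and repeats until one tree remains
  per connected component of the terminal-reachability relation.

The solution cost (total linker weight) is within 2·ln(k) of the optimum
for k terminals; the suite checks this bound, and feasibility, against an
exhaustive subset-enumeration oracle on small random graphs. Determinism:
graph nodes are indexed in lexicographic order and ties broken by (ratio,
node symbol, larger merged subset), so results are independent of edge
input order.

Topology of the extracted sub-network: degree histogram, power-law exponent
b fit by least squares of log10(count) on log10(degree) over observed
degrees ≥ 1 (NetworkAnalyzer-era practice: no xmin selection, no MLE; b is
NaN with fewer than two distinct degrees), and the shortest-path-length
histogram over reachable node pairs (BFS; unreachable pairs counted
separately). Modularity uses the single-community Newman form
Q = e_S/m − (d_S/2m)² measured **against the full graph**, so the whole
graph and the empty set both score 0. The permutation test draws R random
seed sets of the same size from a pool, runs the full extraction on each
and compares observed Q to the null with the add-one empirical p. Published
modularity values from other snapshots of curated interaction databases are
not comparable across network versions and modularity definitions, and are
not targets here.

## Survival

Median expression split (ties and the odd-n median go to "low"), since a
fixed, reproducible cutoff policy is preferable to best-cutoff scanning.
Kaplan–Meier product-limit curves with simultaneous-tie handling; two-group
log-rank with hypergeometric variance summed over distinct event times
(skipping times with one subject at risk); HR via the closed-form O/E
(Mantel–Haenszel-type) estimator with CI exp(ln HR ± 1.96·√(1/E₁ + 1/E₂)).
This is an approximation to the Cox partial-likelihood HR — adequate for
screening, not for multivariable modelling. The implementation is
cross-checked against lifelines in the test suite. The pipeline's survival
stage analyses one deterministic marker: the lexicographically first top
gene (any gene can be analysed through the CLI).

## Synthetic cohort: what it emulates, and what it does not

Defaults describe the study conditions: 1000 genes on 22 chromosomes,
300 samples, per-sample ploidy drawn from {2.0, 3.2}, 5% of genes planted
with recurrent losses in 30% of samples and gains in 5% (so the 2× filter
is recoverable by construction), expression Normal(μ_g, σ_g) truncated at
0 with μ_g ~ U(200, 1000) and σ_g ~ U(20, 60) — chosen so μ/σ > 2
everywhere and zero-truncation cannot mask the planted effect — and a
dosage effect of 4 baseline SDs in loss-carrying samples, the scale of a
homozygous deletion. All planted loss genes carry the dosage effect by
default (`concordant_frac = 1`), which makes funnel precision measurable
against the truth manifest. Annotation: 50 random terms of 10–40 genes,
one containing ≥ 80% of the planted concordant genes. Network:
Barabási–Albert preferential attachment (3 edges per node) over all genes,
with 30 planted-module genes additionally wired into a connected subgraph
plus one extra internal edge per module node. Survival: exponential event
times, baseline hazard 0.1 per time unit for the "high" group and 0.1 × HR
(default 2) for "low", with an independent exponential censoring clock
calibrated to a 20% expected censored fraction; groups are tied to the
median split of the marker gene's expression.

One integer seed drives everything through deterministically spawned
substreams, so identical configurations give byte-identical files.

Deliberately not modelled: chromosome-arm structure, segment breakpoints
inside genes, subclonality and tumor purity, GC bias, allele-specific copy
number, correlated expression programs, log-normal expression heavy tails,
and annotation term overlap structure (a GO DAG). Passing the recovery
tests therefore demonstrates that the pipeline's logic is correct under its
own assumptions — clean dosage effects, independent genes, exponential
hazards — not that real TCGA-scale data would yield comparable precision.

## Numerical and operational choices

* Hypergeometric tails via scipy's `hypergeom.sf` (log-space internally);
  verified to 1e-12 against exhaustive draw enumeration for all N ≤ 12.
* BH adjustment as a vectorised step-up (reverse cumulative minimum),
  cross-checked against statsmodels.
* Degenerate inputs fail loudly: reversed intervals, negative copy numbers,
  duplicated symbols/calls, empty terminal sets, zero-event survival tables
  and single-group splits all raise with the offending record named.
* Re-running any stage with unchanged inputs rewrites byte-identical
  outputs; stage wall-times are logged but kept out of the written report
  for exactly that reason.
* Problem sizes: unit tests run on small instances (≤ 200 genes); the
  end-to-end recovery check uses ten cohorts at the full default conditions
  (1000 × 300, 100 permutations); calibration checks use 200 replicates.

## Known limitations

* The O/E hazard ratio is biased away from 1 relative to Cox for strong
  effects; confidence intervals use the standard log-HR approximation.
* The power-law exponent from a least-squares fit on a small sub-network's
  degree histogram is a descriptive statistic, not a rigorous tail-index
  estimate.
* Klein–Ravi is a 2·ln(k) approximation; for large seed sets the extracted
  sub-network is not guaranteed minimal, and permutation nulls inherit the
  same heuristic.
* The pipeline assumes sample identifiers agree across CNV, expression and
  survival tables; no fuzzy matching is attempted.
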