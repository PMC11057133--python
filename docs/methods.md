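# Methods

This note records the exact computational definitions used by `coexage`.
Parameters given are defaults; all are configurable through `RunConfig`.

## Gene age

Genes carry an integer phylostratum in 1–16. Strata 1–3 are classed
unicellular (UC), strata 4–16 multicellular (MC). Genes absent from the
phylostratum table are "unknown" and are ignored by all age-composition
counts (they still participate in network construction).

## Preprocessing

Starting from a raw count matrix (genes × samples) and a sample manifest
(`sample`, `condition` ∈ {tumor, normal}, `pair_id`, `stage`):

1. **Expression filter.** Counts are converted to CPM; a gene is kept when
   CPM > 1 in *all* tumor samples or in *all* normal samples.
2. **Transform.** log2(CPM + 1) (configurable off).
3. **Outlier samples.** Samples are clustered by average linkage on
   Euclidean distance; the dendrogram is cut at mean + 2.5 sd of the merge
   heights and only the largest cluster is kept. When a sample is dropped,
   its `pair_id` partner is dropped too, preserving the paired design.
4. **Bad genes.** Genes with zero variance or missing in more than half the
   samples are removed before correlation.

## Network and modules

- **Adjacency.** Unsigned: a_ij = |pearson(x_i, x_j)|^β with β = 6.
- **Topological overlap.** TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
  where l_ij = Σ_u a_iu a_uj over u ∉ {i, j} and k_i = Σ_{u≠i} a_iu.
  TOM_ii = 1.
- **Clustering.** Average linkage on the dissimilarity 1 − TOM.
- **Tree cut.** A deterministic recursive cut: a dendrogram branch is split
  when its merge height exceeds 0.99 × the tallest merge, or when both
  children hold ≥ `min_size` genes and sit at least 0.1 below the merge
  height. Surviving branches with ≥ `min_size` (default 30) genes become
  modules; all other genes go to the grey pool. A plain static height cut
  is available as a fallback (`method="static"`). Labels are M1, M2, … by
  decreasing size, ties broken by smallest member gene id, so output is
  order-invariant.
- Tumor and normal networks are built independently from the same filtered
  gene set, using each condition's samples.

## Module age classification

For each module with UC/MC counts (u, m) against background totals (U, M):

- UC direction: one-sided Fisher exact test (alternative "greater") on
  [[u, m], [U−u, M−m]]; MC direction likewise with columns swapped.
- Each direction forms its own Benjamini–Hochberg family across the
  condition's modules (pooling both directions into one family is a flag).
- Category: UC-enriched if adjusted UC p < 0.05, else MC-enriched if
  adjusted MC p < 0.05, else **mixed**.
- Reported odds ratios are cross-product estimates ad/bc. When a single
  cell is zero the Haldane–Anscombe 0.5 correction is applied and flagged;
  a zero marginal leaves the odds ratio undefined (NaN, flagged). A
  conditional-MLE estimate is available behind a flag.

## Novelty

For a tumor module of size S, the raw novelty N is the minimum number of
normal-tissue modules whose union covers ≥ 0.5 S of its genes. Because
reference modules are disjoint, the greedy count (accumulate reference
modules by decreasing overlap; ties by larger module, then label) is exactly
the optimum. When half-coverage is unreachable — genes absent from every
reference module — N is the number of overlapping reference modules plus
one, flagged `reached=False`. The novelty score is N/S; scores are binned
into low/medium/high at the 1/3 and 2/3 quantiles (linear interpolation)
within each comparison.

## Per-sample module activity (ssGSEA)

Within a sample, genes are ordered by decreasing expression (ties broken by
gene id). The gene at ascending rank r (top gene has r = n) contributes
weight r^α (α = 0.25) when in the module; the enrichment score is
Σ_positions (P_in − P_out) where P_in is the cumulative normalized in-set
weight and P_out the cumulative out-of-set fraction. Scores depend only on
within-sample ranks, hence are invariant to monotone transforms. Matrix
scores are optionally normalized by the global max − min span.

## Mutation overlay

- **Recurrent point mutation:** missense/LoF hits in ≥ 3 distinct patients
  and a nonsynonymous-to-synonymous ratio < 1 (zero synonymous counts as an
  infinite ratio, failing the filter). "Other" consequences count toward
  neither side.
- **Focal CNA:** a gene's per-patient call is the state of the segment
  overlapping the gene midpoint; the call is focal when the segment spans
  ≤ 25 % of its chromosome (chromosome lengths default to the maximum
  observed end coordinate). Recurrent = focally altered in ≥ 10 % of
  patients.
- **Module CNA flag:** ≥ 10 % of a module's genes recurrently altered.
  Tumor-vs-normal flag enrichment is a one-sided Fisher test on
  [[normal flagged, normal not], [tumor flagged, tumor not]] with the
  alternative that normals are flagged less often.
- **Centrality:** within a module's TOM subnetwork, a gene's degree is its
  summed edge weight to the other members; genes are ranked ascending
  (average ties), and centrality = rank/S − 1 ∈ (−1, 0], the hub at 0.
  Centrality shift of a gene is its tumor-module centrality minus its
  normal-module centrality; the gene must be placed in exactly one module
  per condition.

## Robustness filter

Within a module, edges below the median off-diagonal weight are removed
(ties at the median survive), then genes whose retained degree falls below
⌈S/2⌉ (S = original module size) are dropped. Age enrichment and novelty
re-run on the surviving genes check classifications against weak-edge
artifacts.

## Progression and grade classifier

A stage chain (e.g. normal → low → high) builds modules independently per
stage and novelty-scores each stage against the previous one. The grade
classifier draws 100 stratified 70/30 splits; each split fits a
500-tree random forest on per-sample ssGSEA module scores and records the
held-out ROC AUC. Variable importance is mean decrease in Gini on the
R `randomForest` scale — the raw impurity decrease summed over nodes and
averaged over trees (scikit-learn's normalized importances are not
comparable across forests) — with modules above Gini 5 called
grade-discriminating. All per-iteration seeds derive from one master seed
via `numpy.random.SeedSequence`, making reports byte-identical across runs.

## Synthetic cohorts

Counts are drawn from a negative binomial (dispersion 0.2) around
log-normal means: per-gene base level Uniform(log 5, log 400) in log-CPM,
plus loading × module factor (factor ~ N(0,1) on the samples where the
module is active), plus N(0, 0.4) noise, scaled by Uniform(0.8M, 1.2M)
library sizes. Six planted modules cover preserved (both-condition)
UC-rich/MC-rich/balanced programs, two tumor-only balanced programs, and
one high-grade-only program; module age compositions are exact by
construction. Five driver genes are ordinary members of a preserved module
in normal samples but load strongly (loading 2.0) on a tumor-only factor in
tumors, becoming its hub; 30 % of patients additionally carry a focal
amplification (log2 fold change 2) over the driver locus, alongside a
whole-chromosome gain decoy that exercises the focality rule. Planted point
mutations include three genes passing the recurrence filter and three
designed to fail it. `truth_recovery` scores detected modules against the
planted partition by adjusted Rand index over non-grey genes.
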