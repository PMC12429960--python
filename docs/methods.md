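# Methods

## The screen

`anchorscreen` implements a multi-dataset screening procedure for genes whose
developmental expression trajectory tracks, or mirrors, a single *anchor*
gene — the motivating case being Mkrn3, the hypothalamic "pubertal brake"
whose expression drops sharply before puberty, screened against candidate
regulators such as Acvr1c. The procedure has four bulk stages and one
single-cell stage:

1. **Normalization.** Raw counts are scaled to counts per million (CPM) and
   transformed to `log2(CPM + 4)`. The offset of 4 bounds the scale below at
   exactly 2 and stabilizes the variance of low counts; all downstream
   statistics operate on this scale.

2. **Drop-point detection.** For each dataset, the anchor's replicate values
   are compared across timepoints by one-way ANOVA, then each consecutive
   timepoint pair is tested with a two-sided Wilcoxon test: `signed_rank`
   pairs replicates by label, `rank_sum` treats the groups as independent.
   The *drop index* is the earliest transition with p ≤ α and a mean decrease
   (an `--increase` direction flag covers anchors that rise). Replicate
   numbers in these datasets are tiny, so for groups of ≤ 25 the null
   distribution is enumerated exactly by dynamic programming over doubled
   mid-ranks, which is correct in the presence of ties (the test conditions
   on the observed values); the normal approximation is used only beyond
   that. A consequence the pipeline reports rather than hides: with n = 4
   pairs, the exact signed-rank test's smallest attainable two-sided p is
   2/2⁴ = 0.125, so no transition can be significant at α = 0.05 from four
   pairs — each transition therefore carries a `min_p` field, and at such
   designs only `rank_sum` (smallest p = 2/70 ≈ 0.029 at 4 vs 4) can call a
   drop.

3. **Transition differential expression.** Between the drop timepoint and
   the one before it, each gene is tested with a negative-binomial Wald
   test: median-of-ratios size factors, per-gene method-of-moments
   dispersion pooled across the two groups (floored at 1e-8), log2 fold
   change with a pseudo-quantity of 0.5 normalized counts when a group mean
   is zero, standard error from the observed Fisher information, and
   Benjamini–Hochberg adjustment over the tested genes (all-zero genes are
   excluded from testing and from the BH denominator). The Wald statistic is
   referred to a **t distribution with n₁ + n₂ − 2 degrees of freedom**
   rather than a normal: with four replicates per group the plug-in
   dispersion makes the statistic t-like, and a normal reference roughly
   doubles the nominal type-I error (simulation: ~0.10 instead of 0.05; the
   t reference gives ~0.053). The two references coincide as group sizes
   grow. This stage is intentionally simpler than shrinkage-based DE
   packages: no dispersion shrinkage, no fold-change moderation, no
   independent filtering, no covariates and no outlier handling — the
   consensus only consumes the adjusted p-value and the sign of the change.

4. **Correlation consensus.** Per dataset, each gene's Pearson correlation
   with the anchor is computed over the timepoint means of `log2(CPM + 4)`
   (≥ 3 timepoints required; zero-variance genes are flagged undefined and
   excluded from thresholding). The consensus keeps genes with |r| ≥ `r_min`
   (default 0.6) in at least `min_datasets_r` (default 3) datasets AND
   significant transition DE (padj ≤ 0.05) under a configurable rule:
   `all_datasets` (the default) or `min_datasets` (≥ `min_datasets_r`).
   Both rules are exposed because the two are defensible readings of the
   published screen this design follows; note that under `all_datasets` a
   single dataset with an undetectable or misplaced drop vetoes every gene.
   A dataset in which no drop is detectable still contributes correlation
   evidence — correlation does not depend on the transition — and simply
   counts as a DE failure everywhere. Candidates are finally intersected
   with a signaling gene set and a merged puberty gene set (GMT inputs;
   `and` by default, `or` available), sorted by |mean r| with ties broken by
   symbol — the ordering rule is this package's own convention.

5. **Single-cell co-expression.** On a normalized cell × gene matrix with
   cell-type and stage annotations (annotations are inputs; no clustering or
   embedding is computed), the pipeline filters to the postnatal stages of
   interest, computes dot-plot statistics per cell type (percentage of cells
   with value > τ and mean normalized expression over *all* cells of the
   type), and classifies every cell of one type by joint expression of the
   anchor and a candidate, overall and per stage. "Expressing" means
   normalized value strictly above τ = 0 by default; τ is configurable
   because published filters of this kind rarely state a threshold. The
   permutation mutual-exclusivity test (hold the anchor's expressing set
   fixed, redraw the candidate's expressing set uniformly at the observed
   size, p = (k+1)/(n_perm+1) for permutations with overlap ≤ observed) is
   an extension beyond descriptive overlap counting and is labelled as such
   in outputs; its null agrees with the hypergeometric tail.

## Synthetic data

The generators provide planted ground truth so every stage is testable
without downloads; their defaults are the package's reference study
conditions.

**Bulk.** Gene mean trajectories are specified on the `log2(CPM + 4)` scale
and inverted to count space (`CPM = max(2^m − 4, 0.1)`), so planted
correlations are controlled on the scale the screen uses. Defaults: 2000
genes, 4 timepoints (P0/P7/P14/P28) × 4 replicates, anchor at level 10
dropping 4-fold at index 2, 50 positively and 50 negatively tracking genes
(slope ±1), NB dispersion φ = 0.1, lognormal library sizes with median 1e7
and 0.2 log-sd — magnitudes typical of bulk brain RNA-seq. Planted genes
deviate from the scaled anchor by stationary AR(1) noise (lag-1 correlation
0.7): biological drift across adjacent developmental ages is smooth, and
independent per-timepoint jitter would make transition fold changes far
noisier than the trajectories themselves. The noise sd is derived from the
target planted correlation (default |r| ≈ 0.9) through the centered AR
covariance — centering matters because the smooth component partly acts as a
constant offset that Pearson correlation ignores. Null genes are flat levels
(N(6, 2), floored at the scale minimum) plus their own smooth AR(1) wander
(sd 0.3). `simulate_multidataset` shares gene roles, signs and the drop
index across datasets while drawing independent noise, offsets and library
sizes per dataset (sub-streams via `SeedSequence` spawn keys, stable across
platforms), plus a per-gene constant baseline shift (sd 0.25) so datasets
are not replicates; constant shifts leave correlations and fold changes
untouched.

What this emulates and what it does not: NB counts with library-size
variation, a stepped anchor, correlated trajectories and cross-dataset
heterogeneity are represented; batch structure, cross-species ortholog
divergence, heavy-tailed outlier samples and realistic gene–gene correlation
beyond the anchor are not. Passing recovery tests therefore demonstrates
that the pipeline's statistics behave as designed under the stated model,
not that the published gene lists would be reproduced from the public
datasets.

**Single cell.** Cells receive a type (neuron / oligodendrocyte / tanycyte /
astrocyte / microglia-like census) and a postnatal stage by stated
proportions. Gene A is expressed probabilistically in its types, gene B in
its own, with neurons the single shared type; within it, an A-expressing
cell expresses B with probability ε (0 = perfect mutual exclusivity).
Expressed entries get lognormal positive values. The generator returns the
realized co-expression counts as exact truth, so the analyzer must match it
identically — the round-trip is asserted over random configurations
including both ε edges.

## Calibration and measured behaviour

Quantities below are recomputed by the test suite and
`scripts/acceptance.py`; problem sizes are the package's reference
conditions.

- Exact rank-sum at 6 vs 6 with complete separation: p = 2/924 ≈ 0.0022;
  drop detection at 6 replicates × 5 timepoints, 4-fold drop, φ = 0.05 is
  correct in ≈ 96–99% of simulations.
- NB-Wald null calibration (n = 4 vs 4, μ = 100, φ = 0.1): empirical type-I
  error ≈ 0.05 at nominal 0.05; a simulated 2-fold change (μ = 500, φ = 0.05,
  n = 6/6) is recovered with median log2 fold change ≈ 1.0.
- Full-screen recovery (5 datasets at the bulk defaults, thresholds 0.6 /
  3-of-5 / 0.05, DE rule `min_datasets`, rank-sum drop detection): ≈ 83–92%
  of planted genes pass the consensus and essentially no null genes do.
  The limiting factor is per-dataset DE power: holding planted |r| at 0.9
  over only four timepoints forces trajectory noise of ~0.66 log2 units on
  the transition change, and occasionally (≈ 3% of datasets) the 4-replicate
  exact test calls a wrong or no transition.

## Numerical and degenerate-input conventions

- Two-sided exact p-values are twice the smaller tail, capped at 1; zero
  differences in the signed-rank test are dropped; all-zero difference sets
  give p = 1.
- Pearson r is clipped to [−1, 1] against rounding; the anchor self-reports
  r = 1; a constant anchor makes every correlation undefined.
- A constant anchor yields an undefined ANOVA and no drop rather than an
  error; an all-zero sample is a hard error naming the sample.
- Consensus direction is `negative`/`positive` when all threshold-passing
  correlations share that sign, `mixed` otherwise, `none` when no dataset
  passes the threshold.
- Size factors require at least one gene with nonzero counts in every
  sample; `pseudo_reference=True` switches to positive-count geometric means
  for very sparse designs.
- Timepoints are 0-based contiguous indices per dataset, assigned from the
  sample sheet's label order of first appearance; original labels are kept
  for reporting.

## Known limitations

- The DE stage is a transparent surrogate, not a reimplementation of
  shrinkage-based tools; on real data with few replicates its ranking will
  be noisier than theirs.
- Cross-species gene matching is case-insensitive symbol identity plus an
  optional alias-mapping file; no ortholog inference is performed.
- The single-cell stage takes normalization and cell-type annotations as
  given; results are sensitive to the "expressing" threshold convention,
  which published analyses often leave unstated.
- With four replicates the signed-rank test cannot reach significance at
  α = 0.05; this is a property of the exact test, reported via `min_p`, not
  a software limitation.
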