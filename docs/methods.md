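# Methods

## Model and procedure

`pvpred` classifies proteins into virion (positive) and non-virion
(negative) classes from sequence alone. The pipeline has four parts:

1. **g-gap dipeptide encoding.** For gap `g`, a sequence of length `L`
   contributes `L − g − 1` ordered residue pairs `(p, p + g + 1)`; the
   feature vector is the 400 pair frequencies `n_i / (L − g − 1)`.
   The 400 pairs are indexed row-major by alphabetical residue rank
   (AA = 0, AC = 1, …, YY = 399). Nothing in the statistics depends on this
   ordering; it is fixed so ranked-index outputs are reproducible.
2. **ANOVA-F filter with incremental feature selection (IFS), per gap.**
   One-way ANOVA F per feature (implemented for general K ≥ 2 groups,
   used with K = 2), descending ranking, then an SVM-evaluated sweep of
   nested ranking prefixes; the smallest prefix size attaining the maximum
   pooled CV accuracy is kept as that gap's optimal subset.
3. **Fusion and mRMR re-ranking.** The per-gap optimal subsets are
   concatenated (ascending g, each block in its ANOVA-ranked order — mRMR
   is order-insensitive for selection, so intra-fusion order matters only
   for reporting), discretized, and re-ordered by incremental greedy mRMR;
   a second IFS sweep locates the final subset.
4. **RBF-SVM classification.** Soft-margin SVM with the Gaussian kernel;
   `(C, γ)` tuned by exhaustive grid search on pooled CV accuracy. The
   deployment model is refit on all data at the final peak.

## Assumptions

- Two classes; sequences restricted to the 20 standard residues. Records
  with ambiguous letters are rejected at load, not masked, so every
  feature vector is computed on fully specified residues.
- Input FASTA files are assumed pre-deduplicated (e.g. by identity
  clustering upstream); class membership is given by supplying one FASTA
  per class rather than parsed from headers, since header conventions for
  labels are not standardized.
- Every sequence must satisfy `L ≥ g + 2` for each requested gap. A
  violation aborts the run listing the offending ids — silently skipping
  records would desynchronize rows and labels.
- Class imbalance is not reweighted in the SVM; with imbalanced data the
  accuracy-maximizing grid search will favour majority-respecting models
  (see *Limitations*).

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `g_values` | 0…9 | gap range; g = 0 is adjacent dipeptides |
| `n_folds` | 5 | stratified CV folds; per-class fold counts differ by ≤ 1 |
| `grid_c` | 2⁻⁵…2¹⁵ (odd powers) | libsvm-practice C grid |
| `grid_gamma` | 2⁻¹⁵…2³ (odd powers) | libsvm-practice γ grid |
| `criterion` | `mid` | mRMR difference form; `miq` (quotient) selectable. MIQ falls back to relevance alone when mean redundancy < 1e-12 |
| `n_bins`, `bin_multiplier` | 3, 1.0 | μ ± aσ three-bin discretization (population σ); an equal-frequency quantile scheme supports other bin counts |
| `tune` | `per_k` | re-run the grid search at every prefix (honest nested tuning); `once` tunes at the first evaluated prefix and reuses `(C, γ)` |
| `seed` | 0 | drives fold assignment and the data generator; identical inputs + seed ⇒ bit-identical outputs |

Mutual information is the plug-in estimate in bits with no pseudocounts;
the log base uniformly rescales mRMR scores and cannot change the greedy
order. ANOVA ranking uses raw F with no p-value conversion and no
multiple-testing correction — it is a relevance filter, not a test.

## Numerical choices and degenerate inputs

- **ANOVA sentinels.** Zero within-class variance with non-zero
  between-class variance ⇒ F = +inf (a perfectly separating feature must
  rank first); a feature constant across all samples (0/0) ⇒ F = 0.
  "Zero" means an SS term below 1e-12 of the feature's total SS, since the
  frequencies are small rationals and float round-off leaves dust.
- **Ranking ties** break toward the lower original feature index (stable
  sort); **grid ties** toward smaller C, then smaller γ (the least complex
  model); **mRMR ties** toward the lower feature index.
- **IFS peak** is the *smallest* evaluated prefix achieving the maximum
  accuracy. All prefixes up to the requested maximum are evaluated rather
  than stopping at the first decrease, which would halt at local plateaus.
- **ROC** thresholds descend through unique scores with tied samples moved
  as a block, preventing optimistic stair-casing; trapezoidal auROC then
  equals Mann–Whitney pair counting with ties at ½ (asserted exactly in
  tests). **Mcc** with any zero denominator factor is defined as 0.
- **Z-scores** of mRMR criterion values use the population standard
  deviation; constant score vectors are an error.
- g-gap frequencies already lie in [0, 1], so no feature rescaling is
  applied before the SVM.

## Synthetic benchmark generator

The generator (`pvpred.synth`) emulates a curated two-class benchmark:
99 positives vs 208 negatives by default (the class imbalance of typical
curated virion sets), lengths uniform on 80–200, uniform residue background
(a Swiss-Prot-like preset is provided). Negatives are i.i.d. background;
positives plant signal by *biased sequential sampling*: when emitting
position `t`, the probability of residue `b` is multiplied by the
enrichment factor for every planted pair `(g, a, b)` whose conditioning
position `t − g − 1` holds `a`, then renormalized. This keeps sequences
compositionally natural and makes the enrichment factor an interpretable
conditional-odds multiplier; enrichments implying a conditional frequency
above 1 are rejected. Generation is a deterministic function of the spec
seed.

What passing tests on this generator do **not** show: robustness to domain
architecture, homology clusters, phylogenetic correlation between samples,
or realistic length/composition confounds between classes. They show the
pipeline's machinery — encoding, ranking, fusion, redundancy removal,
tuning, evaluation — recovers known signal and stays calibrated under a
known null.

## Desk-scale problem sizes

The default configuration (full grids, per-prefix retuning, all 400
prefixes per gap) reflects the honest protocol. The test suite and
`scripts/acceptance.py` run a scaled-down version chosen as a sensible
desk-scale default: a 3×3 `(C, γ)` grid, tune-once mode, stage-1 prefixes
{1…6, 8, 10, 14, 18, 22, 26, 30}, and stage-2 prefixes dense to 10 then
every 4th size. On the planted benchmark (8 dipeptides, enrichment 8,
99/208 samples) this recovers all planted features in the top 5% of their
gap's ANOVA ranking and reaches pooled five-fold CV accuracy ≥ 0.99, so
the reduction does not mask the signal the experiments probe.

## Known limitations

- With imbalanced classes, a label-permuted control converges to the
  majority-class accuracy (208/307 ≈ 0.68 at the default shape), not to
  0.5; chance-level behaviour of a null run shows up instead in its auROC
  (≈ 0.5) and in the signal-vs-control accuracy margin, which the test
  suite asserts at ≥ 0.25.
- Greedy mRMR optimizes the incremental criterion, not the set-level
  objective (NP-hard); different discretizations or the quotient variant
  can reorder features.
- Pooled CV metrics are reported from a single assembly of out-of-fold
  predictions; per-fold averaging would give slightly different variance
  properties.
- Tune-once mode reuses `(C, γ)` across prefix sizes and can understate
  small-prefix accuracy relative to per-prefix retuning.
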