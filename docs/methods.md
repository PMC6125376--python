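# Methods

## Pipeline model and assumptions

The package implements a phenotype-signature pipeline for bulk expression
matrices: probe collapsing → quantile normalization → per-gene mean±SD
discretization → greedy mRMR ranking by mutual information → incremental
feature selection (IFS) with an RBF-SVM under leave-one-out cross-validation
(LOOCV) → smallest-k MCC-maximizing signature → overlap/direction
statistics.

Key assumptions:

* Labels are binary (case/control) with the case class as positive; both
  classes must be present (and ≥ 2 per class for LOOCV).
* Expression values are used as read — no log transform, background or batch
  correction. Quantile normalization is applied jointly across **all**
  samples of the gene-level matrix (after probe collapsing), not per group.
* Discretization statistics (mean, SD) are computed per gene over all
  samples **before** cross-validation, and the mRMR ranking is likewise
  computed once on the full cohort; only the SVM is refit inside each LOOCV
  fold. This mirrors the classical construction of such pipelines but means
  the feature-selection step sees the held-out sample: the reported LOOCV
  metrics are optimistically biased relative to fully nested
  cross-validation, and should be read as model-selection scores, not
  unbiased generalization estimates.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_n` | 300 (clamped to #genes) | mRMR ranking depth |
| `max_k` | `top_n` | IFS search depth (k = 1..K prefixes) |
| `SVMParams.C` | 1 | SVM cost |
| `SVMParams.gamma` | `"auto"` = 1/#features | RBF width |
| `SVMParams.standardize` | on | per-feature centering/scaling from training-fold statistics (SD with n−1) |
| discretization `ddof` | 1 | sample SD in the mean±SD thresholds |

The SVM defaults replicate the classical R `e1071::svm` defaults (radial
kernel, C = 1, gamma = 1/#features, internal scaling), pinned explicitly so
"default parameters" is reproducible. No class weights are used; with
unbalanced cohorts the Matthews correlation coefficient (MCC) is therefore
the model-selection metric.

## Numerical choices

* **Mutual information** is the plug-in estimate in **bits** (log₂). The
  mRMR ranking is invariant to the log base since relevance and redundancy
  scale together; scores are labelled with their unit. Terms are accumulated
  with exact float summation (`math.fsum`), which makes I(x,y) = I(y,x) hold
  exactly, and the result is clamped at 0 against rounding.
* **mRMR tie-breaking** is by input gene order (first wins). Scores within
  1e-9 bits are treated as tied so that mathematically equal scores reached
  through different summation orders still resolve to the earlier gene.
  Pairwise gene–gene MIs are computed once (when a gene is selected) and
  accumulated into running redundancy sums; this is arithmetically identical
  to naive recomputation, which the tests verify against an independent
  brute-force implementation.
* **Rank-1 score convention:** the first selected gene's score is its pure
  relevance (empty-set redundancy ≡ 0).
* **Quantile normalization** replaces each sample's rank-r value by the
  across-sample mean of rank-r sorted values. Tied values within a sample
  receive the mean of the reference values at their tied ranks (the standard
  convention); for tie-free input the operation is idempotent and makes all
  per-sample value distributions identical. With ties, the tie groups are
  averaged per sample, so the postcondition holds up to that averaging.
* **Discretization boundaries** (exactly mean ± SD) are assigned to the
  middle bin; a constant gene (SD 0) is all-mid and carries no information.
* **MCC zero-denominator convention:** 0. Sensitivity/specificity are
  reported as missing when the corresponding actual class is absent.
* **IFS tie-breaking:** the smallest k attaining the maximal MCC is chosen,
  favouring compact signatures.
* **Overlap test:** one-sided upper tail P(X ≥ k) (the enrichment
  convention) with the sample (unconditional) odds ratio and no continuity
  correction; zero overlap gives odds ratio 0, a zero-cell denominator gives
  infinity. The universe size defaults to the number of genes in the
  analyzed matrix and is overridable. On the reference 23-vs-27 comparison
  with 4 shared genes in a 25,159-gene universe this yields odds ratio
  229.87 and p = 9.18e-09.

## Synthetic cohorts

`SyntheticSpec`/`generate_cohort` emulate exactly the structure the pipeline
assumes: a two-class Gaussian cohort (defaults 106 cases vs 33 controls, on
a log-intensity-like scale with `base_mean` 8, `base_sd` 1), `n_informative`
genes whose case mean is shifted by `effect_size`·SD (default δ = 3, a
strong, clearly detectable signal), one or more redundant copies per
informative gene (parent values plus independent noise, default SD 0.1),
and `n_null` background genes (default 200) drawn identically for both
classes. A single RNG stream is consumed gene-by-gene — informative genes,
then redundant copies, then nulls — so enlarging the null background never
reshuffles the signal genes, and identical spec+seed is bit-identical.

What the generator does **not** emulate: probe-level (beadchip) noise,
batch/array effects, heavy-tailed intensity distributions, and realistic
co-expression networks beyond the planted parent–copy blocks. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
idealized planted signals, not performance on real cohorts.

Two deliberate fixture choices in the tests: the "fully separable" IFS-curve
fixture uses δ = 5 (per-gene class separation of 5 SD, i.e. essentially
non-overlapping classes) so that the premise of full separability actually
holds; and the empirical-null LOOCV check uses 50+50 samples × 10 pure-noise
features, where the LOOCV MCC fluctuation (≈ n^−1/2) keeps |MCC| well below
0.3.

## Behaviour of smallest-k selection on strong planted signals

With δ = 3 and 30+30 samples, two to three planted genes already separate
the classes almost perfectly, so the IFS curve typically reaches MCC 1.0 at
k ≈ 3 and the smallest-maximizer rule stops there. Consequently the optimal
signature usually contains only 3 of the 5 planted signals — recovering
more would require either a weaker per-gene effect or a tie-break that
prefers larger k. Likewise, a redundant copy differs from its parent only
through noise at the discretization boundaries, so which of the pair ranks
first in the mRMR list is essentially a coin flip per pair (the loser of the
pair is pushed far down by its redundancy penalty either way). Stronger
statements — that the signature always contains ≥ 4/5 parents, or that every
parent always outranks its copy — are not stable properties of the method at
these settings; the robust guarantees, asserted in the tests, are that the
signature reaches MCC ≥ 0.9, contains no null genes, and that a
representative of every planted signal (parent or copy) appears in the top
10 of the ranking.

## Problem sizes

Test and acceptance runs use desk-scale cohorts chosen to exercise every
code path: 60–139 samples, 210 genes (5 informative + 5 redundant + 200
null), mRMR ranking over all 210 genes, IFS depth K = 30–40. Oracle
equivalence is checked on 100 random mRMR instances (≤ 8 genes, ≤ 20
samples), 1,000 random MI contingency tables, and exhaustive hypergeometric
enumeration for universes up to 30.

## Known limitations

* LOOCV is O(n) SVM fits per curve point; cohorts beyond a few hundred
  samples or IFS depths beyond a few hundred make the curve expensive.
* The plug-in MI estimator is biased upward for small n; this bias is shared
  by relevance and redundancy and by all genes, so the ranking is affected
  far less than the absolute scores.
* No nested cross-validation, hyperparameter tuning, alternative mRMR
  variants (e.g. quotient form), or continuous-variable MI estimators.
* Pathway/network enrichment of a discovered signature is out of scope; only
  set-overlap and direction summaries are provided.
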