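# Methods

## Model

The package treats a binary data stream as a sequence of fixed-size
chunks `W(0), W(1), …` of `d`-dimensional numeric feature vectors with a
declared rare positive class. Two oversampling models share a two-stage
structure per chunk:

1. **Selection.** The positives of the current chunk form a virtual
   cluster `VC(T)`; its centroid `CW(T)` is their coordinate-wise mean
   and its distortion is the sum (SSE) / mean (MSE) of squared
   *Euclidean* distances to the centroid. A positive instance `x`
   carried in the previous adapted window is admitted as a synthesis
   source iff adding it would not raise the cluster's MSE. The centroid
   is not recomputed while candidates are examined, and every candidate
   is judged against the same baseline MSE rather than cumulatively.
   Under those two conventions the test reduces exactly to
   `‖x − CW(T)‖² ≤ MSE`, which is how it is implemented; the test suite
   keeps the definitional recomputation as an independent oracle.
   - *Model A* filters every previous positive.
   - *Model B* partitions the previous window's positives by their
     provenance tag: items that originated in the immediately preceding
     chunk bypass the filter and are folded into `VC(T)` before the
     centroid and MSE are computed; strictly older items are then
     filtered. The bypass prevents the circularity of re-judging items
     against a centroid they anchored one step earlier.
2. **Synthesis.** Exactly one synthetic positive per admitted item:
   `x̂ = x + (CW(T) − x) ⊙ RV` with `RV` uniform per coordinate on a
   configurable sub-range of `[0, 1]`. With the default range the point
   is a per-coordinate convex combination of the item and the centroid.
   Only the synthetic offspring are merged into the training window;
   original previous items are not copied forward, and negatives pass
   through untouched. Synthetic instances inherit the provenance tag
   (`time_moment`) of their source, which is what allows items whose
   lineage began many chunks ago to remain in play and is the signal
   model B's bypass/filter split keys on.

The controller that orchestrates the two stages takes no window-size or
age parameter; the itemset size is fully determined by the data through
the distortion criterion. It never undersamples negatives and places no
cap on positive accumulation — it records the positive fraction in
telemetry and logs a warning past 50%, but does not intervene, because
capping would reintroduce a tuning parameter and change the method.

### Degenerate inputs and tie-breaks

- Empty positive sets: with no previous positives, or (model A) no
  current positives, selection is skipped and the adapted window equals
  the raw chunk. In model B, bypass items alone may seed the cluster
  when the current chunk has no positives.
- A cluster whose points are all identical has MSE 0 and accepts only
  candidates exactly at the centroid; no special-casing.
- The acceptance boundary is inclusive: distance² exactly equal to MSE
  is admitted.
- Duplicate candidates are evaluated and admitted independently (no
  deduplication).
- The last, possibly short, chunk of a stream is processed like any
  other chunk.
- Missing feature values are rejected at ingest rather than imputed;
  the distance computations are undefined on incomplete vectors.

### Random-vector sub-ranges

The synthesis equation places small `RV` values near the *source item*
and values near 1 at the *centroid*; the `[0, 0.5]` range therefore
yields points in the half-segment adjacent to the source and `[0.5, 1]`
in the half adjacent to the centroid. The equation is implemented
literally and both sub-ranges are exposed; the geometry is asserted in
the test suite.

## Evaluation protocol

Prequential test-then-train: each chunk is scored with the model as
trained on earlier chunks, then used for training (after adaptation, if
an oversampling controller is attached). The first chunk is train-only
because an untrained incremental model has no defined predictions.
Confusion counts accumulate per chunk and cumulatively; the six derived
metrics are sensitivity, specificity, accuracy, precision, F1 and the
Matthews correlation coefficient, with every zero-denominator case
mapped to 0. Repetitions are averaged with an unweighted mean across a
seed list, keeping per-run reports for dispersion.

**Synthetic instances are never scored by default.** Testing points the
sampler itself created would inflate sensitivity, so confusion counts
cover real instances only; a `score_synthetic` option exists for
compatibility with protocols that test every element of the adapted
window. This is a deliberate, documented divergence from evaluation
schemes that score the full window.

The built-in reference classifier is an incremental nearest-centroid
model (running per-class means, Euclidean prediction, unseen class →
majority prediction). It was chosen because its adaptation speed after
drift is directly proportional to the number of positive training
instances it receives, making the effect of oversampling transparent;
adapters over scikit-learn's `partial_fit` estimators (Gaussian naive
Bayes, SGD logistic regression) are provided for comparison with
established incremental learners.

## Synthetic stream generator

The generator emulates the statistical shape of a feature-extracted
biomedical monitoring stream: per-instance labels are
Bernoulli(positive_rate), features are isotropic Gaussians conditioned
on the label, and a drift event abruptly replaces the positive-class
mean from a given chunk onward. Defaults: 100 chunks × 1600 instances,
35 features, 2% positive rate, negative mean at the origin and positive
mean at Euclidean distance 3 (unit variances) — separable but noisy.
Isotropic Gaussians were chosen for analytic transparency: the method
only requires numeric features and a coherent positive cluster.

What the generator does **not** emulate: spectral structure and
autocorrelation of real EEG features, temporal clustering of seizure
events, gradual drift, and heavy-tailed feature marginals. Passing tests
on this generator therefore demonstrate the mechanics and the drift
response of the method, not clinical-grade performance on real signals.

### Desk-scale drift fixture

Tests and the acceptance script use a scaled-down fixture: 50 chunks ×
200 instances at 2% positive rate (≈4 positives per chunk), with one
abrupt drift at chunk 25 that mirrors the positive mean through the
origin (6σ displacement, landing the new positives closer to the
negative mean than to the stale positive mean, so an unaided classifier
genuinely suffers until it re-adapts).

The fixture's feature count is 5, not the full-scale 35. This is an
operating-point argument, not a convenience: for i.i.d. Gaussian
positives the filter admits a fresh same-distribution candidate with
probability `P((1 + 1/n)·χ²_d ≤ χ²_{d(n−1)}/n)`, which is ≈0.44 at the
full scale (n ≈ 32 positives per 1600-instance chunk, d = 35) but
≈0.04 at n ≈ 4 with d = 35 — a 4-point sample cannot calibrate the
spread of a 35-dimensional cluster, so the window would be inert and
the fixture would exercise nothing. At d = 5 the 4-positive chunks
admit at ≈0.3, preserving the accumulate-then-collapse dynamics the
fixture exists to probe.

Even at this operating point the desk-scale window sizes are
intrinsically noisy: the per-chunk positive count is Binomial(200, 0.02)
(about one chunk in four has ≤2 positives), so model B's itemset —
whose bypass component is exactly the previous chunk's raw positive
count — grows on average but not monotonically chunk-to-chunk, and a
chunk with one or two tightly spaced positives yields a near-zero MSE
that can reject the whole accumulated pool at once. These collapse
events are faithful behaviour of the selection rule at small positive
counts, not artifacts; at the full scale (≈32 positives per chunk)
relative fluctuations are an order of magnitude smaller and the growth
is far smoother.

## Numerical choices

- Acceptance uses the closed form `d² ≤ MSE` (exact algebraic
  equivalence to the definitional included-MSE comparison with a fixed
  centroid); floating-point disagreement is possible only exactly at
  the boundary and is not observed on random inputs.
- Round-trip CSV I/O writes floats with 17 significant digits so
  feature values survive to 1e-12.
- One RNG stream per run (NumPy `default_rng(seed)`), consumed in
  itemset order (previous-window order), makes adapted windows and all
  outputs byte-reproducible for a given seed and configuration.

## Problem sizes used by the test and acceptance runs

Oracle equivalence: 1,000 cluster/candidate pairs over d ∈ {1, 2, 5,
35}; distortion non-increase: 500 random clusters; synthesis geometry:
1,000 triples per random-vector range; conservation and relaxation:
seeded 20-chunk streams and 40 fixture windows; drift response and
classifier comparison: the desk-scale fixture over 5 seeds. These sizes
were chosen as the smallest that make the binomial/χ² margins in the
assertions comfortable.

## Known limitations

- No guard against rare-class dominance after long drift-free runs
  (reported in telemetry, warned past 50%, by design not intervened).
- Binary labels only; multi-class selection would need per-class
  clusters.
- Labels are assumed available immediately after testing each chunk
  (no delayed or partial labeling).
- The distortion criterion is blind to cluster *shape*: it is isotropic
  around the centroid, so elongated positive clusters admit candidates
  along all axes equally.
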