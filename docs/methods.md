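# Methods

## Problem setting

Spatially resolved transcriptomics (SRT) measures a cell × gene count
matrix together with each cell's physical position (µm).  Cell-type
annotation transfers labels from a dissociated scRNA-seq reference whose
taxonomy is curated, but reference and target differ in capture
efficiency — spot-based platforms in particular suffer heavy gene dropout
— and dissociated references carry no spatial information.  The package
addresses both: a transfer classifier carries the taxonomy over, and a
graph model over the spatial neighbour graph regularizes per-cell calls
with neighbourhood context.

## The three-stage model

**Stage 1 — transfer.**  Both datasets are restricted to their common gene
set (optionally intersected with a marker list), optionally
log1p-transformed, and each cell vector is scaled to unit L2 norm.  A
feed-forward network (four hidden blocks of affine → GELU → dropout, then
an affine head) is trained on the labelled reference with focal loss

    FL(p_t) = −α (1 − p_t)^γ log p_t ,   defaults γ = 2, α = 1,

which damps the contribution of easy examples and so tempers cell-type
class imbalance without resampling.  Applied to the spatial data the
network yields logits `Y` and a distribution `D` per cell.  Pseudo-labels
are the temperature-softened softmax

    l_i = exp(y_i / T) / Σ_j exp(y_j / T),

with `L = D` exactly at `T = 1`.  The default `T = 2` keeps inter-class
similarity structure in the soft targets.

**Stage 2 — spatial embedding.**  The spatial neighbour graph links each
cell to its `N = 30` nearest neighbours with Gaussian weights
`ω(u,v) = exp(−d(u,v)² / 2θ²)`.  The decay coefficient θ defaults to half
the mean distance to the N-th neighbour, so the kernel resolves structure
at the neighbourhood scale; it is exposed as a parameter for datasets
with known interaction ranges.  The directed kNN graph is symmetrized by
elementwise max and given unit self-loops — the graph convolution assumes
an undirected graph with self-connections.

A two-layer autoencoder (affine → batch-norm → ELU → dropout, twice)
encodes expression into `X`; a variational graph autoencoder applies two
graph convolutions `H' = Â H W` with `Â = D^{−1/2}(A)D^{−1/2}`, the second
layer splitting into `μ` and `log σ²` heads, and samples the spatial
embedding by the reparameterization trick `S = μ + σ·τ`, `τ ~ N(0,1)`.
The combined latent is `Z = X + S` (all three share one width).  Four
signals are optimized jointly with Adam on the full graph:

* `w_ae · MSE(I, I′)` — expression reconstruction (decoder reads `Z`
  during joint training; the standalone autoencoder op decodes `X`);
* `w_graph · BCE(binarize(A), logistic(Z Zᵀ))` — adjacency
  reconstruction, with the positive class re-weighted by
  #non-edges / #edges so the sparse edge set is not swamped;
* `w_kl · (−0.5/n) Σ(1 + log σ² − μ² − σ²)` — KL pull of `q(S|X,A)`
  toward the `N(0,1)` prior;
* `w_cls · (−1/n) Σ_i Σ_c L_ic log Q_ic` — soft-target cross-entropy of a
  one-layer softmax classifier on `Z` against the stage-1 pseudo-labels
  (frozen after stage 1; no iterative refresh).

Default weights are (1, 1, 1, 1).  The parameter snapshot with minimum
total loss is kept.

**Stage 3 — inference.**  The optimal checkpoint is reloaded and run with
`τ = 0` (so `S = μ`), making annotation deterministic.  The predicted type
is the classifier argmax; the maximum probability `c_s` is recorded per
cell.

## New-type discovery

Cells with `c_s` below a confidence threshold (sensible range 0.5–0.9;
0.7 and 0.9 are the demonstration settings) are tagged unassigned and
clustered by k-means in the combined latent `Z` with
`k = ceil(#types / 2)`.  For each predicted type, the centroid is the mean
latent vector of its assigned cells and its radius the 0.95 quantile of
member distances (robust to outliers; the radius has no canonical
definition, so the quantile is exposed).  A cluster centroid inside at
least one radius is folded into the nearest such type; otherwise the
cluster becomes `new_type:<k>`.  Radii are computed from assigned cells
only, and assigned cells are never relabelled.

## Domain-shift augmentation

A reference-trained classifier systematically misassigns whole types when
the target carries gene dropout the reference lacks (in development this
appeared as several types collapsing onto one sink class).  Training
therefore augments each batch with the exact target-domain transform:
a random fraction of features (uniform in [0, 2·`input_dropout`], default
centre 0.3) is zeroed and each row re-normalized to unit L2.  This is the
package's own robustness measure; `input_dropout = 0` disables it.

## Synthetic data generator

The generator emulates a paired annotation problem: gene baselines
`log b_g ~ N(log 3, 0.8)`, per-type profiles
`m_tg = b_g · exp(separation · N(0,1))` so `separation` directly scales
between-type log-expression distance (≈1 is a moderately separable
mixture; ≥3 makes expression-only transfer near-perfect).  Counts are
negative-binomial via the gamma–Poisson mixture with dispersion 0.3
(`var = m + 0.3 m²`, a typical single-cell overdispersion).  Spatial cells
occupy a 1000 × 1000 µm field, laid out either as one horizontal band per
type (cortical-lamination-like; 5% of cells swap into a neighbouring band
to create realistic boundary mixing) or as Gaussian blobs.  Gene dropout
zeroes each matrix entry independently with the given rate.  Withholding
a type removes it from the reference and its taxonomy while its cells
remain in the spatial data.

What the generator does *not* model: platform-specific noise (segmentation
error, optical crowding, bead mixing), batch effects between reference and
target beyond dropout, continuous gradients or rare types.  Passing the
fixture suite therefore demonstrates that the machinery is correct and
that spatial context is exploited when type layouts are coherent — not
performance on any real tissue.

## Numerical choices

* All randomness flows through explicit `numpy.random.Generator` seeds;
  training is bit-reproducible per seed.
* Softmax and BCE-with-logits use max-subtraction / softplus forms;
  `p_t` and probabilities are clamped at 1e-12 before logs.
* The dense part of the adjacency-reconstruction loss is evaluated in
  float32 with a sparse correction on the edge set (the n² logistic terms
  dominate stage-2 cost); parameters and gradients stay float64.
* Neighbour ties in graph construction are broken by cell index (stable
  argsort); an exact quadratic search is used up to 5000 cells, a k-d
  tree beyond.
* All-zero cells pass through normalization unchanged; QC is expected to
  remove them upstream.
* Zero-support types contribute zero weight to weighted F1 rather than
  NaN; neighbourhood metrics include the focal cell so isolated cells are
  well-defined (complexity 1, purity 1).
* The quantile rule in QC makes refiltering non-idempotent in general; on
  an already-filtered set with the same parameters it removes nothing.

## Fixture-scale settings

End-to-end runs in the test suite, the examples and
`scripts/acceptance.py` use the fixture-scale configuration: 10 types,
100 genes, 2000 reference cells, 3000 spatial cells; DNN hidden widths
(256, 128, 64, 32) for 100 epochs; joint model for 150 epochs; dropout
sweep at rates {0, 0.4, 0.8}.  These sizes were chosen so a complete
multi-condition evaluation runs on a laptop-class single core; the
library defaults (hidden (1024, 512, 256, 128), 200 joint epochs) target
real panels with hundreds of genes and tens of thousands of cells.

## Known limitations

* Stage 2 trains on the full graph; memory grows with n² in the
  adjacency-reconstruction term.  Datasets beyond a few tens of thousands
  of cells need the graph loss subsampled or tiled (not implemented).
* `Z = X + S` requires the autoencoder latent width and the VGAE output
  width to match; the config enforces one shared width (default 64, with
  a 32-wide first graph-convolution layer).
* Gene matching is exact-string and case-sensitive; alias resolution is
  an external concern.
* Pseudo-labels are generated once; no self-training iterations.
* Discovery is a single pass; no re-discovery after relabelling.
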