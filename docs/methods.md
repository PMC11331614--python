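# Methods

## Problem and model

`her2mil` predicts a breast-cancer slide's HER2 group — negative (IHC 0),
low (IHC 1+, or 2+ without ISH amplification), or high (2+ with
amplification, or 3+) — from an H&E whole-slide image, with supervision only
at the slide level. A slide is represented as a *bag* of tile embeddings
X = {x_1 … x_n}, x_k ∈ R^d, and classified by a clustering-constrained
attention MIL model:

* shared projection h_k = relu(W1 x_k + b1), width `d_proj`;
* per-class gated attention
  a_{c,k} = softmax_k( w_c · (tanh(V h_k) ⊙ σ(U h_k)) + b_c ),
  with the tanh branch scoring a tile and the sigmoid branch gating it;
* per-class slide vector M_c = Σ_k a_{c,k} h_k, linear bag classifiers,
  and a softmax over the per-class activations;
* per-class 2-way linear *instance* heads on h_k, trained on pseudo-labels
  from the attention ranking (top-k attended tiles of the true class → 1,
  bottom-k → 0; top-k tiles of other classes → 0). During training they
  regularize the representation; afterwards they act as tile-level
  detectors, which is what the actionable-tile analysis uses.

The training objective is 0.7·(bag cross-entropy) + 0.3·(mean smooth-SVM
instance loss), where the smooth multiclass SVM loss is
L(s, y) = τ·log Σ_j exp((s_j + Δ·1[j≠y] − s_y)/τ) with Δ = 1, τ = 1. It is
an upper bound on the hard hinge for every τ > 0, converges to it as τ→0,
and reduces to cross-entropy at Δ = 0, τ = 1; the suite checks all three
identities. Optimization is Adam (lr 1e-4, weight decay 1e-4), one bag per
step, at most 200 epochs with early stopping on validation loss.

With the default widths (d_in = 1024, d_proj = 1024, d_attn = 512, three
classes) the model has exactly 2,109,964 trainable parameters; these widths
are the unique common configuration consistent with a ≈2.1 M parameter
budget and are exposed as configuration keys. The model, losses, and the
Adam optimizer are implemented directly in NumPy with analytically derived
gradients; the test suite validates every gradient against central finite
differences, and pseudo-label selection is treated as non-differentiable
(the attention ranking is a constant of the backward pass), the standard
practice for this architecture family.

## Labels, partitions, and splits

The five legal assay cells {0, 1+, 2+/ISH−, 2+/ISH+, 3+} map to groups by a
fixed truth table; IHC 2+ without ISH raises an equivocal-case error. Six
partitions probe different clinical contrasts:

| model | cells → classes | n_classes |
|---|---|---|
| M1 | 2+/ISH− → low; 2+/ISH+, 3+ → high | 2 |
| M2 | 0 → neg; 2+/ISH+, 3+ → high | 2 |
| M3 | 1+, 2+/ISH− → low; 2+/ISH+, 3+ → high | 2 |
| M4 | 0 → neg; 1+, 2+/ISH− → low; 3+ → high | 3 |
| M5 | 0 → neg; 1+, 2+/ISH− → low | 2 |
| M6 | all five cells | 3 |

The M4 cell set is genuinely ambiguous in its source material; the default
above (3-class, excluding the amplified 2+ cell) was chosen because M4 is
reported as non-binary elsewhere in the same analysis, and it is exposed as
an override (`build_partition(..., class_map=...)`).

Splits are patient-level (all slides of a patient share one role) and
stratified on (partition label, cohort). A 15% hold-out is drawn once
(round-half-up per stratum, remainder absorbed by the largest stratum);
each of the 10 folds then independently re-draws a 15% validation set from
the remainder — repeated stratified splits, not a disjoint k-fold
partition, matching the "randomly assigned per fold" protocol. Strata with
fewer than two patients are merged into the nearest stratum with the same
label, with a warning. Cohorts flagged external are excluded from all
training roles.

## Imaging stages

Tiles are 256 px at 0.5 µm/px with 50% overlap (stride 128); finer scans
(0.25 µm/px) are read through a 512 px level-0 window and reduced by exact
area averaging (non-integer factors: anti-aliased resampling of the nearest
integer window). Coordinates are 0-based, half-open, level-0; edge strips
narrower than one tile are discarded. Slides with fewer than 1000 tumor
tiles (strict inequality) are excluded; the count is always taken at the
TUMO level regardless of the downstream filtering strategy.

Stain normalization is Macenko-style: OD = −log10((I+1)/256) (the +1 offset
avoids log 0), background pixels excluded below a max-channel OD of 0.15,
stain directions at the 1st/99th percentile angles in the top-2 OD singular
plane, hematoxylin identified as the column with the larger red-channel OD.
Concentrations are solved by an exact vectorized 2-column active-set NNLS
(all four sign supports enumerated per pixel; verified against
`scipy.optimize.nnls`), rescaled by the ratio of 99th-percentile
concentration maxima, and re-rendered with the reference matrix. The method
is behind a small strategy surface so a sparse-NMF variant could be swapped
in. Profiles are intended to be estimated per slide from a sample of tumor
tiles and applied to all of that slide's tiles.

The region classifier (tumor / non-tumor / background) is pluggable; the
bundled default is a multinomial logistic model on per-channel color and OD
summary statistics, trained on generated fixtures. It stands where a large
CNN patch classifier would be used on real slides, and any 3-class
probabilistic patch model can be substituted. Tile region calls use the
argmax probability.

Feature encoders are likewise pluggable (`dim` + `encode`); the default is a
seeded random projection of 3×16-bin channel histograms, a deterministic
stand-in occupying the interface where a pathology foundation model's
1024-d embedding would enter. Embeddings are not L2-normalized. Bags are
materialized once into an HDF5 store (per-slide `features`/`coords`
datasets) and training reads from the store.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes.
Defaults: 10 slides per latent class per cohort over two synthetic sites
(60 slides), 50–200 tiles per slide, d = 32, 10 shared background Gaussian
clusters (unit σ), witness mean shift δ = 5σ along orthogonal
class-specific directions, witness prevalence 0.10 (low) / 0.20 (high)
drawn per slide from a Beta with concentration 20 (tumor heterogeneity),
assay model P(3+|high) = 0.7 else 2+/ISH+, P(1+|low) = 0.6 else 2+/ISH−,
neg → 0, and interobserver noise ε swapping observed 0↔1+ only (2+/3+
calls stay clean). d = 32 at 60 slides keeps a full 10-fold experiment in
about a minute on one CPU; paper-scale dimensions (d = 1024, ≥1000 tiles)
are reachable through the same config. The generator does **not** model
spatial autocorrelation of tiles, scanner/site color variation, or
photorealistic texture — so passing tests demonstrate that the machinery
recovers planted bag-level structure under the stated label model, not
clinical-grade performance on real slides.

The ε mechanism reproduces the analysis's central qualitative finding: with
ε = 0.3, labels of the neg-vs-low contrast (M5) are corrupted in both
training and evaluation while neg-vs-high (M2) is untouched (a flipped
latent-low slide enters M2 as "neg" but carries no high-witness tiles, so
it still ranks correctly). The acceptance check pools fold AUROCs across
seeded replicates before comparing medians, because a single replicate's
M5 hold-out is only a handful of slides and its median is coarse-grained.

## Explainability

Actionable tiles: instance probability strictly > 0.5 for the class, then
the ≤15 highest-attention tiles per slide and class, regardless of the
slide's final classification. Attention heatmaps are per-slide min-max
normalized (a singleton normalizes to 1.0), painted on tile footprints with
overlaps averaged. The bin map fits one PCA on the pooled actionable-tile
embeddings across all models and folds (so panels share a comparable
plane), bins the first two components into a 30×30 equal-width grid over
the pooled ranges (max edge → last bin), and colors bins by majority class
(ties broken neg < low < high), by fold consistency (class present in
≥ 50% of folds, inclusive), or by cross-model agreement at levels ≥2/3/4.

## Numerical and degenerate-input choices

Softmax and log-sum-exp use max subtraction throughout. Attention/argsort
ties break by tile index (stable sort). k_sample defaults to 8 and shrinks
to ⌊n/2⌋ on small bags; bags of one tile contribute no instance loss.
Early stopping: best-validation-loss checkpoint; training stops after any
epoch ≥ min_epochs (default 50) with ≥ patience (default 20) epochs since
the last improvement, so patience 0 stops at the first eligible epoch.
3-class AUROC is macro one-vs-rest by default (micro available). All
randomness flows through per-fold generators derived from the experiment
seed; identical seeds reproduce histories bitwise.

## Known limitations

* The encoder and region classifier defaults are deliberately lightweight
  interface stand-ins; real-slide performance requires plugging in trained
  models.
* MIRAX and other proprietary WSI codecs are unsupported; input is plain or
  paged TIFF/PNG or in-memory arrays.
* Per-replicate M5/M2 medians on the 60-slide default cohort are
  coarse-grained (small hold-out); conclusions about the noise ordering are
  made on pooled replicates.
* The 2-column NNLS is exact for the H&E two-stain system but does not
  generalize to ≥3 stains.
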