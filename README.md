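# her2mil

Weakly supervised prediction of HER2-negative / HER2-low / HER2-high status
directly from H&E-stained breast-cancer whole-slide images.

HER2-low (IHC 1+, or IHC 2+ without ISH amplification) is a therapeutically
actionable category whose assessment normally requires immunohistochemistry
and, for equivocal 2+ cases, a slow and costly in-situ hybridization test.
`her2mil` implements the full computational pipeline for predicting the
HER2 group from routine H&E slides instead: tiling (256 px, 0.5 µm/px, 50%
overlap), tumor/non-tumor/background triage with NOBG/TUMO filtering and
the <1000-tumor-tile slide exclusion, Macenko stain normalization to a
reference profile, per-slide bags of tile embeddings behind a pluggable
encoder, a clustering-constrained attention MIL classifier

```
a_{c,k} = softmax_k( w_c · (tanh(V h_k) ⊙ σ(U h_k)) ),   M_c = Σ_k a_{c,k} h_k
```

trained with 0.7·CE(bag) + 0.3·smooth-SVM(instance) under Adam
(lr = wd = 1e-4, ≤200 epochs, early stopping on validation loss), six
IHC/ISH-derived training partitions M1–M6 with patient-level stratified
splits (15% hold-out + 10 repeated 85/15 folds), AUROC evaluation, and the
actionable-tile explainability analysis (instance probability > 0.5, top-15
by attention, 30×30 PCA bin maps with fold-consistency and model-agreement
coloring). The model and optimizer are pure NumPy with analytic gradients,
so everything runs on one CPU.

A synthetic-cohort generator emulates the assumed data structure — bags
drawn from shared background clusters plus class-specific witness clusters,
an IHC/ISH label model, and optional 0↔1+ interobserver noise — so the
entire pipeline is testable at desk scale without any slide downloads.
See `docs/methods.md` for the model and every default.

## Worked example

```python
from her2mil import (MILConfig, SynthConfig, TrainConfig, generate_cohort)
from her2mil.train_eval import run_experiment

cohort = generate_cohort(SynthConfig(seed=1))          # 60 slides, d=32
cfg = MILConfig(d_in=32, d_proj=64, d_attn=32, n_classes=2)
res = run_experiment(cohort.manifest, cohort.bags, ["M2"], cfg, TrainConfig(seed=1))
print(res.summary)
```

prints

```
  model_id  median_auroc  sd_auroc
0       M2           1.0       0.0
```

— the neg-vs-high model separates the clean synthetic cohort perfectly on
the hold-out set across all 10 folds, as it should: latent-high slides
carry a planted witness cluster 5σ from the background that the attention
mechanism learns to find. Adding interobserver label noise
(`SynthConfig(seed=11, label_noise=0.3)`) leaves M2 at median 1.0 but drops
the neg-vs-low model M5 (median 0.75 on the same run), reproducing the
ordering in which contrasts that depend on the subjective 0 vs 1+ IHC
distinction degrade while neg-vs-high stays intact.

The default full-scale model is `MILConfig()` (1024-d input, 3 classes):

```python
from her2mil import MILConfig, MILParams
MILParams.init(MILConfig(), seed=0).parameter_count()   # 2109964
```

A thin CLI covers the data-facing steps: `her2mil synth`, `her2mil split`,
`her2mil params` (see `--help`).

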