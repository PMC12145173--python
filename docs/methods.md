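# Methods

## Problem and data model

The package classifies a compound's mechanism of action (MoA) from two
modalities. A dataset couples each compound (ID, SMILES, class label, one
set of four binary fingerprints) with many five-channel cell images; the
compound is the atomic unit for splitting and voting because images of the
same compound are not independent. Matching attaches the compound's single
fingerprint set to each of its images, so a training sample is (image,
fingerprint quad, label). Channels are named and ordered
(DNA, Mito, AGP, RNA, ER); channel order is semantic, and single-organelle
experiments subset channels before the stem.

## Image branch

Backbone: the standard bottleneck residual topology with four stages. The
stem is replaced to honour the multi-scale, five-channel input: parallel
depthwise 3×3 convolutions at dilation rates {1, 2, 3} over the raw
channels, summed, then a pointwise convolution to `stem_width`, batch norm
+ ReLU, a stride-2 average pool and a 3×3/stride-2 max pool — total ×4
spatial reduction, matching the usual stage-0 contract so the four stages
are unmodified. The exact stem topology (branch count, fusion by sum,
pooling choice) is this package's design; the constraints honoured are
"dilated", "depthwise separable", and the stage-0 output shape.

Per-stage global average pooling + concatenation gives OS (width
Σ stage_widths = 3840 at full widths, 480 at the tiny preset). The
attention gate is an elementwise logistic sigmoid of an affine map of OS
(a per-feature score in (0,1)); a softmax-over-features gate is available
as a config variant. Because the gated vector's width differs from the
final feature width, a single affine projection maps it to `feature_dim`
(default 512); this projection is plumbing, not part of the attention
mechanism. Attention is purely per sample (no batch pooling of scores).
Batch normalisation follows every convolution; images are z-scored per
channel with statistics from the training fold only.

Presets: `full` = widths (256, 512, 1024, 2048), blocks (3, 4, 6, 3), stem
width 64 — the 50-layer configuration; `tiny` = widths (32, 64, 128, 256),
one block per stage, stem width 16, used for all desk-scale training.

## Fingerprint branch

Types and default lengths: RDK 2048, ECFP 2048 (radius 2; the usual
ECFP4-equivalent convention), PubChem 881, MACCS 167. Slot order R, E, P, M
is fixed everywhere. No open-source implementation of the PubChem/CACTVS
881-bit layout exists, so the package ships a documented approximation
(element-count thresholds, ring-size counts, a SMARTS bank, hashed atom
pairs); it is deterministic and binary but not the authoritative layout —
authoritative bits can be supplied via the override table, which always
wins. Fingerprint counts are clipped to presence/absence.

Architecture decisions where the design was open:

* The per-type embedder is a single affine map (reading the "linear"
  wrapper around the affine expression as one map, not two stacked ones).
* The shared common encoder (FPC) is Linear–ReLU–Linear, 4d → 1024 → d_c;
  the four independent specific encoders (FPS) are Linear–ReLU–Linear–ReLU,
  d → 512 → d_s, fed the *un-padded* embeddings. Hidden widths are package
  choices (the layer counts are fixed, the widths were not specified).
* `‖·‖²` in both losses is the squared Euclidean/Frobenius norm (standard
  loss convention; linear gradients). Lc and Ls are written per sample and
  averaged over the batch, keeping magnitudes batch-size invariant.
* Rows of H are not L2-normalised before the Gram product, so Ls also
  drives row norms toward 1; `normalize_rows=True` enables the normalised
  variant.
* The alignment target C̄ is recomputed each forward pass and gradients
  flow through it (no stop-gradient).
* Branch loss: CE + λ_c·Lc + λ_s·Ls with λ_c = λ_s = 1 by default.
* A useful identity (tested): Lc = (1/4)·Σ_{j<k}‖C_j − C_k‖², i.e. the
  alignment loss is exactly the mean pairwise squared distance rescaled.

Fusion layer: Linear–ReLU–Linear, (d_c + 4·d_s) → 256 → 64. Classifiers on
both branches are a single linear layer + softmax.

## Training and protocol

Optimizer: Adam (the adaptive-moment default) at lr 0.001 for the image
branch; the fingerprint branch's reference configuration is lr 1e-5 over
100 epochs. Plateau scheduling monitors validation loss (factor 0.1,
patience 10, min lr 1e-8). Cross-entropy clamps probabilities at 1e-12.

Split protocol: within each class, compounds are shuffled (seeded) and
dealt round-robin into 10 subsets, so per-class subset counts differ by at
most one. Subset 0 is the held-out test set; the nine others yield 5 folds
of 8 training + 1 validation subsets. β is selected on the validation
folds by grid search over {0.0, 0.1, …, 1.0} on mean validation accuracy
(the fusion weight's selection rule is a package decision; only its role
is prescribed). Test-time, fold models are ensembled by averaging their
score vectors (per-fold results are also reported, since whether to
ensemble was open), and results are reported both per sample and per
compound; the compound vote takes each sample's argmax, majority wins,
ties broken by highest mean fused score then lowest class index. Whether
reference results are sample-level or compound-level is ambiguous, so both
are always emitted.

Metrics: accuracy, macro-F1, weighted-F1 via scikit-learn with an explicit
label set; classes absent from the truth contribute F1 = 0 to the macro
average (conservative). Per-class accuracy (recall) supports per-MoA
reporting.

## NumPy engine

All networks run on `moafuse.nn`, a compact reverse-mode autodiff engine:
tensors over NumPy arrays, im2col convolution (stride/padding/dilation/
groups), fused batch norm, 3×3 max pooling, Adam, plateau scheduler. Every
operator's gradient is tested against finite differences or a naive-loop
oracle. Float32 is used for models, float64 for loss-identity and gradient
tests. He-normal initialisation from a caller-supplied generator makes
every model reproducible from one seed.

## Synthetic data

The generator emulates exactly the structure the model exploits and
nothing else. Fingerprints: compound latent z = class centroid +
N(0, 0.35²) perturbation in 32 dimensions; type t's bits are
1[P_t z > 0] for a fixed random projection P_t, then flipped independently
with p_flip = 0.05. The shared z induces cross-type commonality; the
distinct projections induce type specificity. Fingerprints are generated
directly as bits (not via synthetic SMILES) so the fingerprint branch is
testable without chemistry; a handful of real SMILES exercise the
featurization module separately.

Images (64×64, values quantized to integers so uint16 TIFFs round-trip
exactly): DNA = disks with class-linear radius 3–9 px; Mito = oriented
sinusoidal band-pass texture with class-linear frequency 0.12–0.45
cycles/px *and* class-permuted amplitude 0.5–3.0 — deliberately the
largest effect; AGP = rings and RNA = smoothed speckles with class-permuted
amplitudes 0.3–2.0 under different orderings; ER = smooth gradient with
amplitude 0.95–1.05, deliberately the weakest channel so the
single-channel ablation has non-trivial structure. Per-image jitter
(counts, positions, phases) is seeded per (dataset seed, compound, image).

Default conditions: 10 classes × 20 compounds × 4 images = 800 samples.
Presets: `smoke` (3 × 10 × 2, 32×32) and `hard` (p_flip = 0.25, wider
compound spread). What passing tests show: that the implementation can
recover strong class signal of the kinds the model targets
(channel-conditioned morphology, shared-latent fingerprints). What they do
not show: performance on real microscopy (no plate/batch effects,
illumination artefacts, dose-response, or realistic cell rendering here).

## Desk-scale configuration

Training runs in the tests and the acceptance script use the tiny backbone,
15 epochs (image branch), 20 epochs (fingerprint branch), 8 epochs for the
single-channel ablations, batch 32, and Adam lr 1e-3 for both branches —
the standard rate for this scaled-down setting (the 1e-5 reference rate
belongs with the 100-epoch real-data configuration and underfits a 20-epoch
budget by design). These sizes are the package's desk-scale choices; the
generator's defaults above are the study conditions and are never tuned
per run.

## Known limitations

* The PubChem fingerprint is an approximation unless override bits are
  supplied.
* The engine is CPU/NumPy; it is meant for desk-scale models, not the
  full-resolution assay.
* No image QC, illumination correction, or plate-metadata handling; the
  loader takes TIFF stacks at face value.
* Macro-F1's empty-class convention (F1 = 0) lowers scores on folds
  missing a class entirely; this is deliberate and documented.
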