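# Methods

## The model

The classifier decides whether a patient's chest radiograph study shows
pneumonia, using both the frontal (AP or PA) and the lateral (LA) projection.
Rather than classifying pixels directly, it fuses latent representations from
two generative branches, trained per view:

* **Image VAE** (encoder E2 / decoder D2). The normalized image x is mapped
  to a diagonal Gaussian posterior q(z₂|x) = N(μ, diag(σ²)) by a stack of
  three stride-2 convolutions (32-32-64 channels, 3×3 kernels), each followed
  by batch normalization and a leaky rectifier, then fully connected layers of
  128-128-128-64-64-32-32 units and two parallel linear heads for μ and
  log σ². The decoder mirrors the encoder with transposed convolutions. The
  latent is 32-dimensional.
* **Feature β-VAE** (E1 / D1). A backbone CNN reduces each image to a
  1024-dimensional feature vector; a fully connected encoder (256-256) maps
  it to a 32-dimensional posterior, and a mirrored decoder reconstructs the
  feature vector.

Both branches are trained with the reparameterization trick
z = μ + σ ⊙ ε, ε ~ N(0, I), minimising

    L = L_rec + β · KL[q(z|x) ‖ N(0, I)]

with β = 1 for the image VAE (the plain VAE objective) and a configurable
β ≥ 0 for the feature branch. The KL term has the closed form
½ Σᵢ (μᵢ² + σᵢ² − 1 − log σᵢ²). Larger β buys a posterior closer to the
prior — more disentangled latents — at the cost of reconstruction fidelity;
the β sweep in `run_beta_sweep` makes that trade-off measurable.

At classification time the four posterior **means** (feature-frontal,
feature-lateral, image-frontal, image-lateral; 4 × 32 = 128 dims) are
concatenated in a fixed order and fed to a single fully connected softmax
layer over the two classes. Single-view ablation modes fuse only that view's
two segments (64 dims). Using μ rather than a sampled z makes evaluation
deterministic; the branches are frozen while the head is trained (two-stage
protocol).

## Data handling

Manifests follow the CheXpert dialect (one row per image; labels coded
1.0 / 0.0 / −1.0 / blank for positive / negative / uncertain / missing).
The label policy is uncertain-to-positive for the target finding; rows with
missing target labels are dropped before pairing. Each patient contributes
one frontal/lateral pair; patients with a single surviving view are excluded,
and when several images exist per view the lexicographically smallest path is
used, which makes pairing independent of manifest row order. The pair label
is the frontal record's; a frontal/lateral disagreement logs a warning.
Splitting is at **patient** level (seeded shuffle, 80/20 cut) so no patient
leaks across train and test.

Images are decoded with Pillow, bilinearly resized to a square (224 by
default; tests and synthetic runs use 64 or smaller), replicated to three
identical channels, scaled to [0, 1], and standardised channel-wise with
mean/std fitted on the training split of each view. Train-set statistics
(persisted as JSON sidecars) were preferred over fixed external constants so
the pipeline has no dependency on a particular pretrained backbone;
`imageprep.IMAGENET_STATS` provides the fixed alternative.

## The backbone

The feature branch is backbone-agnostic behind `BackboneSpec`. The default
`toy_deterministic` backbone is a fixed-seed random convolutional feature
map: two strided random convolutions with rectification, average pooling
onto a 4×4 grid, and a fixed random projection to 1024 dimensions. Its
weights are a pure function of the spec, so features are bitwise
reproducible with no downloads. Random convolutional features are crude but
information-preserving enough for the synthetic studies here; a DenseNet-style
pretrained extractor can be plugged in through the same interface where its
weights are available (`weights_source="pretrained"` otherwise raises an
actionable error).

## Training defaults

| parameter | default | note |
|---|---|---|
| image-VAE batch size | 128 | full protocol |
| feature-β-VAE batch size | 256 | full protocol |
| branch epochs | 50 per view | Adam, lr 1e-3 (library default) |
| classifier | lr 0.001, 200 epochs | Adam, full-batch cross-entropy |
| split ratio | 0.80 train | patient-level |
| β grid | 0.001, 0.1, 1, 2, 5, 10, 100 | sweep default |
| latent dim | 32 per branch/view | |

All randomness derives from one run seed through per-stage hashed sub-seeds,
so any two runs with the same config produce byte-identical `metrics.json`.
Timing and environment details go to a separate `provenance.json` so they do
not break that determinism.

## Numerical core

No deep-learning framework is used: the layers run on a small reverse-mode
autodiff engine over float64 numpy arrays (`vaefusion.nn`). Convolution and
transposed convolution are implemented as the im2col/col2im adjoint pair;
batch normalization is composed from differentiable primitives (its gradient
is derived automatically) with running statistics for evaluation mode. Every
primitive and the full encoder–decoder graph are verified against central
finite differences in the test suite; `logsumexp` uses the constant-shift
trick for stable softmax cross-entropy. σ is parameterized as
exp(log σ² / 2), the numerically stable equivalent of predicting σ directly.
Weights are He-initialised; a non-finite loss aborts training with the epoch
and batch index.

## Evaluation statistics

AUC is the tie-aware Mann–Whitney statistic computed from midranks, together
with its placement components (per positive, the fraction of negatives it
outranks; per negative, one minus the symmetric quantity). The DeLong test
estimates the variance of the AUC difference between two score vectors on
the same labelled test set from the empirical covariances of those paired
placements; the p-value is two-sided normal. A variance below 1e−12 (e.g. a
model compared with itself) returns z = 0, p = 1 by convention. Both routes
are cross-checked in tests against scikit-learn's AUC, an exhaustive
pair-counting oracle, a stratified paired bootstrap, and a 500-replicate
null calibration.

## The synthetic generator

`synthetic_data.generate` emulates the study's data shape: per patient a
frontal and lateral grayscale image built from an elliptical thorax template
with Gaussian noise (default sd 0.05); positive patients get 1–3 bright
Gaussian opacity blobs, placed inside the lung fields on the frontal view
and in a posterior band on the lateral view, scaled by per-view signal
strengths (default 0.5 — clearly visible over the noise floor). The default
positive fraction, 4948/6226 ≈ 0.795, mirrors the pneumonia/healthy
imbalance of the filtered study population. Fractions of patients receive
uncertain or blank labels or a single view; these are assigned as "first
⌊f·n⌋ patients after a seeded shuffle", so counts are exact rather than
binomial, and uncertain labels go to positive patients so the
uncertain-to-positive policy stays consistent with the imagery.

To study the value of a second view, per-view **visibility** probabilities
(default 1.0) make the signal partial: each positive patient shows the
opacity in each view independently with the configured probability, and when
both draws fail the higher-visibility view is forced, so every positive
carries signal in at least one view. Under partial visibility a single-view
classifier is information-limited by construction while the multi-view
fusion is not — the mechanism behind the multi-view-dominance property.

What the generator does **not** model: anatomical realism, projection
physics, scanner/exposure variation, co-occurring findings, label noise
beyond the uncertain coding, or inter-patient anatomy correlation. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that fusion recovers complementary signal when it exists; they say nothing
about absolute performance on clinical radiographs.

`generate_latent_toy` provides a fast fixture: two unit-covariance Gaussian
classes separated by a chosen effect along a random direction, whose optimal
AUC is Φ(effect/√2) in closed form.

## Problem sizes used in checks

The end-to-end studies run at image size 64 with 100 synthetic patients
under the full training protocol, and at size 32 with 60–80 patients at
reduced epoch counts (15/30/150) for the multi-seed ablation and β-sweep
studies — sizes chosen so the whole suite runs comfortably on a single CPU
while leaving the qualitative orderings (multi-view ≥ single-view; recon ↑
and KL ↓ in β) clearly resolvable.

## Known limitations

* The toy backbone is untrained; its features are generic projections, so
  absolute AUCs on real radiographs would require a pretrained extractor.
* Full-batch classifier training assumes the fused training matrix fits in
  memory (it does at these scales by a wide margin).
* The DeLong normal reference is asymptotic; on very small test splits the
  report degrades the p-matrix entries to null rather than fabricating a
  value.
* Whether the feature β-VAE should be shared across views is an open design
  point; separate per-view instances were chosen, matching the image branch
  and the single-view ablation.
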