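# Methods

## The segmentation model

The network is a small encoder-decoder CNN classifying each pixel of a
single-channel T2WI-like slice into three tissue classes: surrounding tissue
(0), central gland (1), marginal gland (2). All layers are implemented
directly in NumPy, forward and backward:

- **Convolution** uses the cross-correlation convention (no kernel flip),
  the standard choice for learned kernels, where the symmetry of the learned
  filter bank makes the distinction immaterial. Output channel `p` sums the
  correlations of each input channel with its kernel slab plus a
  per-channel bias. Encoder convolutions are 3×3 with 'same' padding.
- **ReLU** `f(x) = max(0, x)` with derivative 1 for `x > 0`, 0 otherwise.
- **Batch normalization** standardizes each channel by the batch mean and
  population variance, with an epsilon (default 1e-5) under the square root
  for numerical stability, then applies a learnable scale and shift
  (initialized to 1 and 0). Statistics pool over batch *and* spatial
  positions, so even a single image provides H·W samples per channel; the
  functional `batch_norm` op, which operates on arbitrary feature stacks,
  still rejects single-sample training batches where the intent is
  ambiguous. Inference uses running statistics maintained by an exponential
  moving average (momentum 0.1). Choosing the scale as `sqrt(var + ε)` and
  the shift as the batch mean recovers the identity map exactly — a property
  the test suite verifies numerically.
- **Average pooling** is the non-overlapping window mean (equivalently,
  `1/k²` times correlation with an all-ones `k×k` matrix), `k = 2` by
  default. Non-divisible spatial dims raise rather than silently crop.
- **Transposed convolution** upsamples by its stride using stride×stride
  kernels, making windows non-overlapping and the output exactly
  stride-times larger. It is the exact adjoint of the corresponding strided
  valid convolution (`⟨conv(x), y⟩ = ⟨x, deconv(y)⟩`), which the tests check
  by inner product; the forward pass itself is an independent scatter, not a
  call into the convolution code.
- **Per-pixel softmax** with max-shift stabilization produces the 3-vector
  of class probabilities; prediction is the argmax with ties broken to the
  lowest class index. Training minimizes the mean per-pixel cross-entropy
  (probabilities floored at 1e-12 before the log). The `1/cd` normalizer is
  taken as image height × width — a mean over pixels — extended to a mean
  over the batch as well; any alternative reading only rescales the
  objective without moving its argmin.

**Architecture.** Encoder channels (16, 32, 64), pooling after the first two
blocks (64→32→16 px); decoder of two stride-2 deconv-BN-ReLU stages
restoring 64×64 exactly; final 1×1 convolution to 3 classes. This is the
smallest stack of this family that segments the phantoms essentially
perfectly while training on one CPU in under a minute. Inputs are divided by
255 so intensities sit near [0, 1].

**Optimization.** Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 8, 10 epochs
by default. Initialization is He-scaled Gaussian, seeded; shuffling derives
from the same config seed, so training is bit-reproducible. Optional
per-class loss weights exist for imbalance but are off by default — the
gland occupies ~15 % of the default frame and plain cross-entropy suffices.

## The phantom generator

The generator emulates an axial T2WI prostate slice: an elliptical gland of
40 mm (transverse) × 20 mm (antero-posterior) — textbook adult dimensions —
centred in a 64×64 image at 1 mm/pixel, with a concentric central zone
scaled by 0.55 so the marginal zone is a non-empty ring. Intensities follow
the T2WI pattern (marginal zone brightest): surrounding 90, central 140,
marginal 190, lesion 70 on an 8-bit-like scale, plus Gaussian noise of SD 10.
Cancer cases receive one low-signal lesion disc (radius uniform 3–8 px,
centre uniform over gland pixels, painted before noise) with probability 1
by default. Geometry is fixed across cases — variation comes from noise and
lesions — which keeps the rasterized gland area checkable against the
analytic ellipse area (within 5 % at 128×128, converging with resolution).

Clinical records are sampled from declared regimes: cancer Gleason scores
categorical over {6: 0.35, 7: 0.40, 8: 0.15, 9: 0.08, 10: 0.02} (pattern
split uniform over valid pairs), PSA log-normal (median 12 ng/mL, log-SD
0.6), stage categorical over T1…T4; hyperplasia sits at the benign floor
(Gleason 1+1, PSA median 4 ng/mL, stage T1, no risk group). These are
design choices producing a realistic mix across all three risk groups, not
inferences about any particular cohort; they are configurable.

**What the phantoms do not model:** anatomical shape variation between
patients, multi-sequence contrast (T1WI), bias fields, motion artifacts,
partial-volume effects, or 3D structure. Near-perfect Dice on phantoms
therefore demonstrates that the pipeline is implemented correctly and can
learn the class-intensity-geometry structure it is given — not that it would
reach the same accuracy on clinical MRI.

## Metrics

Dice operates on filled pixel regions; Hausdorff on boundary pixels (a
foreground pixel with at least one non-foreground 4-neighbour), the standard
surface-distance practice. Distances are Euclidean in pixel units with an
optional mm conversion via the pixel spacing. Degenerate inputs raise:
both-empty Dice (0/0), any empty set for Hausdorff, an empty reference
foreground. In foreground mode the gland is classes 1∪2 merged; per-class
mode reports a Dice per class plus the macro average, skipping classes
absent from both masks.

## Risk stratification

The three-axis rule (Gleason, PSA, clinical stage, ordered
T1 < T2a < T2b < T2c < T3 < T4) uses the canonical D'Amico-style thresholds,
applied with precedence high > medium > low, which makes the rule total,
mutually exclusive and monotone in each axis (verified by exhaustive
enumeration in the tests). All thresholds are configurable through
`RiskRule`, isolating this convention in one place.

## Concordance statistics

Positive rates are rounded half-up to integer percent, the convention
consistent with the bundled reference table (43.82→44, 33.71→34, 41.57→42).
Pearson chi-square tests use margin-derived expected counts, df (r−1)(k−1),
and no continuity correction by default (expected counts in cohorts of this
size are far above 5); Yates correction is available by flag. The bundled
reference tables for an 89-case cohort (39 cancer / 50 hyperplasia;
per-method strata) ship as CSV. Note the bundled strata table's
before-processing row sums to 39 although that method detected only 30
cancers — the transcribed counts are kept as printed rather than silently
corrected.

The demo pipeline's cancer call is an explicit heuristic, not a claim about
clinical reading: a case is positive when the gland segmentation contains a
low-signal defect of ≥ 10 pixels, recovered as background pixels inside the
morphological closing (disc radius 4) of the gland foreground — closing
bridges lesions that bite into the gland outline, hole-filling catches
enclosed ones. The "before processing" arm applies the same test to a
median-filtered intensity threshold (115) of the raw image, standing in for
segmentation without the network. Risk grading in the demo uses the true
clinical record of cases called and confirmed cancer.

## Reproducibility and problem sizes

All randomness flows through explicit seeds; per-case and per-stage seeds
are fanned out via `numpy.random.SeedSequence` (stage names hashed with
CRC-32), so every stage is independently reproducible and the demo pipeline
is byte-reproducible across runs. The benchmark configuration — 200
training phantoms, 10 epochs, 50 held-out phantoms at 64×64 — was chosen as
the smallest setting at which the learning curve has clearly converged
(final training loss below 0.06) while a full run stays in the minutes
range on a single CPU; the demo uses 32 training phantoms and 25 epochs,
enough for clean gland segmentation (mean Dice ≈ 0.95) without converging
fully.

## Known limitations

- Phantom geometry is fixed; the network never has to generalize across
  gland shapes or sizes.
- The deconvolution is restricted to stride-sized kernels (exact
  non-overlapping upsampling); overlapping transposed convolutions are not
  implemented.
- Hausdorff distances are exact but O(|M|·|N|) via a full distance matrix —
  fine for slice-sized boundaries, not for volumetric meshes.
- The risk rule's thresholds are the conventional ones; without per-case
  clinical data from a real cohort they cannot be validated against any
  particular stratification table.
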