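# prostseg

Semantic segmentation of prostate T2-weighted MRI slices with an
encoder-decoder convolutional network built from first principles, plus the
surrounding clinical workflow: segmentation-quality metrics (Dice, Hausdorff),
Gleason/PSA/stage risk stratification, and diagnostic-concordance statistics.
A seeded synthetic phantom generator makes the whole pipeline runnable and
testable end-to-end with no patient data.

## Who this is for

Researchers and students who want a transparent, dependency-light reference
implementation of the classic prostate-MRI segmentation workflow: every
network layer (convolution, ReLU, batch normalization, average pooling,
transposed convolution, per-pixel softmax) is written out in NumPy with
hand-derived backpropagation, so each operation can be checked against
brute-force oracles — and is, in the test suite.

## The model

The prostate comprises a central gland and a marginal (peripheral) gland that
must be distinguished from surrounding tissue, so segmentation is a per-pixel
classification into `U = 3` classes. For pixel `s_n` with class scores
`v(u_j)`, the network outputs

```
p(s_n = u_j) = exp(v(u_j)) / Σ_k exp(v(u_k)),     y_n = argmax_j p(s_n = u_j)
```

trained with the mean per-pixel cross-entropy over a `c × d` image,

```
L = −(1/cd) Σ_n Σ_j y_nj ln p(s_n = u_j).
```

The encoder stacks conv(3×3, same) → batch-norm → ReLU blocks with 2×2
average pooling (channels 16, 32, 64); the decoder mirrors the poolings with
stride-2 transposed convolutions and ends in a 1×1 convolution to 3 classes.
Optimization is Adam at desk scale (64×64 slices, CPU, seconds to minutes).

Segmentation quality is scored with the Dice similarity coefficient
`DSC = 2|M∩N| / (|M|+|N|)` on filled regions and the symmetric Hausdorff
distance `HD(M,N) = max(h(M,N), h(N,M))`, `h(M,N) = max_m min_n ‖m−n‖`, on
boundary pixels. Cancer cases are stratified into low/medium/high risk with
the standard D'Amico-style rule over Gleason score, PSA and clinical T-stage
(high: Gleason ≥ 8 or PSA > 20 or ≥ T2c; medium: Gleason 7 or PSA 10–20 or
T2b; low otherwise), and detection methods are compared against pathology by
positive rates and Pearson chi-square tests.

## Worked example

```sh
prostseg demo --out demo_run --seed 7
```

trains the network on 32 lesion-free phantoms, simulates a 22-case cohort
(10 cancer with low-signal lesions, 12 hyperplasia), segments every case,
calls cancer by a lesion-defect heuristic on the segmentation (and, for the
"routine reading" arm, on a plain intensity threshold), and writes the
concordance report. With seed 7 it prints a held-out-style mean Dice of
0.9463 and the report contains:

| method      | n_cancer | n_hyperplasia | positive_rate_pct | rate_diff_pct |
|-------------|----------|---------------|-------------------|---------------|
| pathology   | 10       | 12            | 45                | 0             |
| mri_before  | 4        | 18            | 18                | 27            |
| mri_after   | 9        | 13            | 41                | 4             |

`pathology` is the simulated ground truth; `mri_before` is the naive
threshold reading and `mri_after` the CNN-assisted reading. The CNN arm's
positive rate sits 4 points from pathology versus 27 for the naive arm —
the CNN-processed reading is the more concordant one, which is the workflow's
point. The same library calls are available in Python:

```python
from prostseg import pipeline
result = pipeline.segmentation_benchmark(seed=42)   # train 200, evaluate 50
print(round(result["mean_dsc"], 4))                 # 1.0 (phantoms are easy)
```

Other subcommands: `simulate`, `train`, `segment`, `evaluate`, `stratify`,
`concordance` (see `prostseg --help`).

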