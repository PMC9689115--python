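# wavemri

Wavelet-texture classification of brain-MRI-like grayscale images.

Clinical brain MRI archives span dozens of conditions — stroke, glioma,
dementias, encephalitides — and a recurring engineering question is how far
a *classical* pipeline (contrast normalization, hand-crafted texture
features, linear dimensionality reduction, a convex classifier) can go on a
many-class recognition problem before reaching for deep networks.
`wavemri` implements that pipeline end to end as a tested, reusable library
plus CLI, and ships a seeded synthetic phantom generator so every stage is
benchmarkable without access to any clinical archive.

## The pipeline

1. **Global histogram equalization (GHE).** Each gray level g_k is remapped
   through the normalized cumulative histogram,
   G_k = Σ_{i≤k} n_i / n, output level = ⌊G_k · (N−1)⌋,
   which cancels per-image brightness/contrast (monotone intensity)
   nuisances.
2. **Symlet wavelet features.** A j-level 2-D discrete wavelet transform
   (default `sym4`, j = 4, periodized boundaries — orthonormal, hence
   energy-conserving and exactly invertible) splits the image into a rough
   (approximation) grid R_j and detail triples (P_h, P_v, P_d) per level.
   The feature vector is the flattened R_j concatenated with one
   dominant-frequency estimate per subband and their average
   f_avg = (f_1 + … + f_K)/K, using the scale-to-frequency relation
   f = f_c / (a·δ) with f_c the wavelet center frequency. Mutual-information
   diagnostics between coefficient grids are included.
3. **LDA reduction.** Between-class scatter VAR_B = Σ_i V_i (m̄_i−m̿)(m̄_i−m̿)ᵀ
   and within-class scatter VAR_W = Σ_i Σ_{x∈C_i} (x−m̄_i)(x−m̄_i)ᵀ define the
   generalized eigenproblem VAR_B d = ω VAR_W d; the top t ≤ c−1
   eigenvectors form the projection (ridge-regularized when VAR_W is
   singular).
4. **Regularized logistic regression.** One-vs-rest (default) or
   multinomial, minimizing, for y ∈ {−1, +1},
   ½wᵀw (ℓ2), ‖w‖₁ (ℓ1) or (1−∂)/2·wᵀw + ∂‖w‖₁ (Elastic-Net), each plus
   C·Σ log(1 + exp(−y_i(X_iᵀw + c))), via an in-package monotone proximal
   gradient solver (soft-thresholding gives exact zeros under ℓ1).
5. **Evaluation.** Stratified n-fold cross-validation; confusion matrices;
   per-class one-vs-rest counts (Tp, Tn, Fp, Fn) and two metric variants —
   `paper` (sensitivity = Tp/(Tp+Fp)) and `standard`
   (sensitivity = Tp/(Tp+Fn)) — plus the average recognition rate (mean of
   the row-normalized confusion diagonal).

## Worked example

```python
from wavemri import (PipelineConfig, run_cross_validation, MetricsReport,
                     average_recognition_rate)
from wavemri.phantoms import default_spec, generate_phantom_arrays

spec = default_spec()                     # 5 classes x 20 images, 128x128
images, labels = generate_phantom_arrays(spec)
cfg = PipelineConfig(resize_h=0, resize_w=0, n_folds=5, seed=0)
cm = run_cross_validation(images, labels, cfg)
report = MetricsReport.from_confusion(cm, variant="paper")

print("classes:", cm.class_order)
print(cm.counts)
print(f"average recognition rate: {average_recognition_rate(cm):.2f}%")
print(f"macro sensitivity={report.macro_sensitivity:.4f} "
      f"accuracy={report.macro_accuracy:.4f} "
      f"specificity={report.macro_specificity:.4f}")
```

prints

```
classes: ['CA', 'FS', 'GL', 'MN', 'VD']
[[20  0  0  0  0]
 [ 0 20  0  0  0]
 [ 0  0 20  0  0]
 [ 0  0  0 20  0]
 [ 0  0  0  0 20]]
average recognition rate: 100.00%
macro sensitivity=1.0000 accuracy=1.0000 specificity=1.0000
```

The diagonal confusion matrix says every one of the 100 phantom images
(Gaussian noise σ = 10, illumination amplitude 0.3) was assigned to its true
class when held out; the default phantom benchmark is separable by design,
so deviations from 100% flag pipeline regressions rather than hard data.
The same run is available from the shell:

```sh
wavemri --seed 0 generate data/ --classes 5 --images-per-class 20
printf 'resize_h = 0\nresize_w = 0\nn_folds = 5\n' > cfg.txt
wavemri --config cfg.txt crossval data/ out/
wavemri report out/
```

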