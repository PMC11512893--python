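# spinalzfnet

A tested re-implementation of a hybrid deep-learning pipeline for 4-class
kidney-CT classification — **normal / cyst / tumor / stone** — exercised end
to end on synthetic CT-like phantoms.

The pipeline is aimed at researchers studying classical+learned hybrid
designs for medical image classification: every stage is an explicit,
individually testable library component rather than a monolithic script.

## The method

1. **Median filter** — each pixel is replaced by the middle value of the
   sorted neighbourhood window (default 3×3, edge-replicated), removing
   salt-and-pepper acquisition noise without blurring edges.
2. **ENet segmentation** — a lightweight bottleneck encoder–decoder
   (1×1 projection → main convolution → 1×1 expansion; downsampling
   bottlenecks pool the identity branch and zero-pad its channels; the
   decoder max-*unpools* with the indices saved by the paired encoder pool;
   a final full convolution emits the C=2 class maps) separates the kidney
   from the background.
3. **Augmentation** — padding, rotation (1°–359°, about the centre) and
   integer translation with black-or-white fill expand the training folds.
4. **Feature bank** — per image, a fixed 1652-vector with named blocks:
   - *SURF* (320): up to 5 interest points from an integral-image box-filter
     Hessian detector, det H = Dxx·Dyy − (0.9·Dxy)², each described by 4×4
     subregion sums (Σdx, Σdy, Σ|dx|, Σ|dy|) of Haar responses, L2-normalised;
   - *texture* (1323): one-level Haar DWT → LL/LH/HH subbands → Weber local
     descriptor differential excitation arctan[Σ(fᵢ−f₀)/f₀] → HOG
     (64×64 window, 16×16 cells at stride 8, 9 unsigned bins ⇒ 7·7·9 = 441
     per subband);
   - *shape* (5): area, perimeter, major/minor axis lengths, solidity of the
     segmentation mask;
   - *statistics* (4): masked mean and GLCM entropy, correlation, contrast
     (8 grey levels, distance 1, angle 0°, symmetric).
5. **Hybrid classifier** — a SpinalNet branch over the flattened masked
   image (sub-layer k sees [segmentₖ ‖ outputₖ₋₁]; per-layer projections sum
   to C1), a fusion layer

   `C2 = U·p + ½·U·p1 + ⅙·(1−U)·p2 + 1/24·(1−U)(2−U)·C1`

   with learned projections p (all features), p1 (statistics), p2 (shape)
   and a logistic gate U, and a five-convolution ZFNet head (response
   normalisation after conv1/conv2, pooling after conv1/conv2/conv5, FC
   stack to 4 logits).
6. **Evaluation** — one-vs-rest accuracy/sensitivity/specificity/precision/
   F1 (macro-averaged, in %), per-class + micro/macro ROC with AUC, under
   stratified K-fold and learning-set protocols; training uses softmax
   cross-entropy, batch 32, plateau LR halving (patience 5, min delta 1e-4),
   early stopping and best-checkpoint restore.

All networks run on a small reverse-mode autodiff engine
(`spinalzfnet.autodiff`) written on numpy, verified against
finite-difference gradients in the test suite.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from spinalzfnet import cli_io, phantom

seed = 1
spec = phantom.PhantomSpec(image_size=64, n_per_class=40,
                           seed=cli_io.stage_seed(seed, "phantom"))
samples = phantom.generate(spec)            # 160 labelled phantoms + masks
labels = [s.label for s in samples]
train_idx, test_idx = train_test_split(
    np.arange(len(samples)), test_size=0.2,
    random_state=cli_io.stage_seed(seed, "split"), stratify=labels)
result = cli_io.fit_and_predict([samples[i] for i in train_idx],
                                [samples[i] for i in test_idx], seed=seed)
print(f"ENet train IoU      {result['mean_train_iou']:.3f}")
print(f"held-out accuracy   {(result['y_pred'] == result['y_true']).mean():.3f}")
```

Output:

```
ENet train IoU      0.965
held-out accuracy   0.875
```

The IoU says the segmenter recovers 96.5 % overlap with the true kidney
masks; the classifier then labels 87.5 % of the 32 never-seen phantoms
correctly after at most 30 training epochs.

The same experiment is available from the shell:

```bash
spinalzfnet run --seed 1 --out runs/demo      # writes summary.json + CSVs
spinalzfnet phantom --out data --n-per-class 10 --seed 0 --size 64
spinalzfnet extract --in data --out features.csv
```

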