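# particleprint

Classification and population "fingerprinting" of subvisible-particle
microscopy images.

Biopharmaceutical products must be monitored for subvisible particles
(roughly 2–100 µm): protein aggregates, fatty-acid precipitates from
polysorbate degradation, and process contaminants all show up as small
grayscale particle crops in plate-based brightfield (backgrounded membrane)
imaging. `particleprint` provides a complete, tested pipeline for asking
two questions of such image collections:

1. **What kind of particle is this?** A small convolutional network
   classifies individual crops, with class-imbalance-aware training and
   forced out-of-sample assignment for particle types absent from training.
2. **Are these two particle *populations* the same?** A sibling network
   with the same trunk embeds each crop into 2D via a metric (triplet)
   loss; the population's embedding scatter is summarized as a
   nonparametric density — its *fingerprint* — and two populations are
   compared by a goodness-of-fit test on that density.

Because instrument particle crops are typically proprietary, the package
ships a first-class synthetic particle-image generator whose classes
control size distribution, boundary roughness, interior darkness, edge
contrast and texture. It generates both gross class differences and
subtle brightness-only differences, and is the basis of every test.

## Method

- **Pre-processing.** Variable-size crops are standardized to 32×32 (no
  rescaling: smaller crops are centered in a constant border at the
  training-set mean intensity, larger crops center-cropped), then z-scored
  with frozen training-set statistics.
- **Classifier.** Trunk 2×[3×3 conv, ReLU, 2×2 max-pool] (16, 32
  channels) → 32-unit feature layer → K logits; weighted cross entropy
  with w_k ∝ 1/n_k (Σw_k = K); Adam + AMSgrad, minibatch 256, 15 epochs,
  80/20 train/test split. Results are reported as row-normalized confusion
  matrices (rows = ground truth, rows sum to 1).
- **Embedder.** Same trunk, 2-unit linear head; "batch-all non-zero"
  triplet loss with squared Euclidean distances and margin 1.0, over
  minibatches holding 32 images of every class; early stopping on a
  validation split (patience 5), returning the validation-minimum snapshot.
  loss = mean over active triplets of max(0, d²(a,p) − d²(a,n) + m).
- **Fingerprint.** Gaussian KDE of a population's N embedded points with a
  full 2×2 plug-in bandwidth matrix H (two-stage selector, normal-reference
  pilot): f(x) = N⁻¹ Σᵢ φ_H(x − xᵢ). Utilities: highest-density-region
  levels λ(p), global pdf mode, and the ~50 nearest embeddings to the mode
  for image-gallery curation.
- **Goodness of fit.** The Rosenblatt transform of the null fingerprint,
  (x₁, x₂) ↦ (F₁(x₁), F₂|₁(x₂|x₁)) in closed form for the Gaussian
  mixture, maps null-distributed points to independent uniforms; a
  one-sample Kolmogorov–Smirnov test is applied to disjoint subsets of
  N_test = 100 points and the *fraction of rejected subsets* reported.

## Worked example

```python
import numpy as np
from particleprint import (TrainConfig, confusion_matrix, predict,
                           render_class, train_classifier)
from particleprint.synthetic import default_study_specs

# four synthetic classes, 500 crops each, stratified 80/20 split
rng = np.random.default_rng(42)
data = {"train": [], "test": []}
for ci, spec in enumerate(default_study_specs()):
    imgs = render_class(spec, 500, seed=42, class_idx=ci)
    order = rng.permutation(500)
    data["train"] += [imgs[i] for i in order[:400]]
    data["test"] += [imgs[i] for i in order[400:]]

model, log = train_classifier(data, TrainConfig(seed=3))
pred = predict(model, data["test"])
truth = np.array([im.label for im in data["test"]])
print(confusion_matrix(pred, truth, model.labels).to_frame().round(3))
```

prints the held-out confusion matrix (rows = true class, row sums = 1):

```
           etfe  fa_pal  protein_a  protein_b
etfe        1.0    0.00        0.0       0.00
fa_pal      0.0    1.00        0.0       0.00
protein_a   0.0    0.00        1.0       0.00
protein_b   0.0    0.01        0.0       0.99
```

i.e. the four morphologically distinct classes are recovered essentially
perfectly, while a brightness-only "subtle pair"
(`particleprint.synthetic.subtle_pair_specs()`) trains to an accuracy
clearly above the 0.5 chance level but below the separable case.

The same study shapes are available from the command line:

```bash
particleprint simulate specs.yaml --n-per-class 200 --out data/
particleprint classify run.yaml      # or: fingerprint / temporal / gof
particleprint report runs/classify/  # verify a run's artifact contract
```

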