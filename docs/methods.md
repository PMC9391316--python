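# Methods

This note records the models, numerical choices and open design decisions
behind `particleprint`, and what the synthetic test bed does and does not
establish about real instrument data.

## Synthetic particle images

Plate-based brightfield imaging of particles isolated on a membrane yields
small grayscale crops: dark particles on a near-white background. The
generator (`particleprint.synthetic`) emulates this with star-shaped
blobs: the boundary radius is

    R(θ) = r · (1 + ρ · Σ_{k=1..K} a_k cos(kθ + φ_k)),

with per-image radius r drawn as mean_radius·(1 + cv·z), z standard
normal (floored at 2 px), amplitudes a_k ~ U(−1, 1)/k and phases
φ_k ~ U(0, 2π) from the image's seeded generator. ρ (`boundary_roughness`)
scales lobedness; the 1/k decay keeps low harmonics dominant, as for
gently lobed precipitates. The interior is filled at `interior_level`
plus speckle (`texture_sd`), ringed by an `edge_width_px` band at
`edge_level`, on a `background_level` background with global additive
noise; intensities are clipped to [0, 1]. The radial-Fourier model was
chosen over thresholded filtered noise because a disc (ρ = 0) has an
analytic pixel area, which anchors the generator's unit tests.

Crop side length is round(2r) + 12, clipped to [8, 64] px, so a class with
mean radius 14 px and cv ≥ 0.3 produces crops on both sides of 32 px and
exercises both the padding and the cropping branch downstream. Pixel
scale is treated as arbitrary (no µm/px calibration is modeled).

Three preset class collections define the canonical study conditions:
`default_study_specs()` (four well-separated classes: a large dark rough
polymer-surrogate, two protein-like classes, one small bright fatty-acid
class), `fa_panel_specs()` (six classes with graded size/darkness/
roughness, a chain-length panel analogue), and `subtle_pair_specs()`
(identical geometry, ±0.08 brightness shift — the mix-versus-mix hard
case). Default per-class sample sizes in the tests are 500 (separable
study), 300 (six-class panel) and 2000 (subtle pair); these were fixed
once as desk-scale study sizes at which training is stable.

What the generator does **not** emulate: optical point-spread and
defocus, vacuum/drying artefacts, membrane texture, well-level
illumination gradients, overlapping/touching particles, and the long-tail
size distributions of real products. Passing tests therefore demonstrate
that the *pipeline* recovers known structure under controlled morphology
differences — not that any particular real particle chemistry is
classifiable at a given accuracy.

## Pre-processing

Crops are standardized to a fixed `target` (default 32, 24 supported)
without interpolation: pad with a constant fill (by convention the
training-set mean intensity; a black border behaves nearly identically)
centering the content, or center-crop, independently per axis. When the
centering offset is fractional the extra row/column goes to the
bottom/right — an arbitrary convention fixed so geometry tests can be
bit-exact. Normalization subtracts the pooled training-set pixel mean and
divides by the pooled *population* standard deviation (the sample/
population distinction is immaterial at ~10⁵ pixels but must be fixed);
statistics are computed on raw intensities, frozen after training, and
reused for validation/test data. A constant training set raises rather
than silently producing NaNs.

## Networks and training

Both networks share one trunk: 2 × [3×3 same-padding conv, ReLU, 2×2
max-pool] with 16 then 32 channels, flatten, fully connected ReLU layer
of exactly 32 features. The classifier head is a K-logit linear layer;
the embedder differs only in the last layer (2-unit linear). This is the
smallest standard trunk consistent with the 32-dimensional feature layer;
the architecture is recorded in each checkpoint's metadata so variants
are drop-in. No dropout, batch norm, augmentation or pretraining is used.

Implementation is plain numpy in float32: convolutions are single GEMMs
on concatenated shifted-patch (im2col) matrices with hand-derived
backward passes (verified against finite differences), max-pool ties
break to the first element in row-major order, and the optimizer is Adam
with the AMSgrad maximum-of-second-moment correction. With fixed seeds
and fixed BLAS threading, training is bit-reproducible.

Classifier: weighted cross entropy with w_k ∝ 1/n_k normalized to
Σw_k = K; the loss uses the *weighted-mean* convention (divide by Σᵢ w_{yᵢ})
so its scale is comparable across imbalance levels — with plain-mean
normalization, duplicating a class would change the loss of a fixed
model. Training runs exactly 15 epochs (no early stopping), minibatch
256, lr 1e-3, shuffled each epoch; the test split never touches a
gradient, and evaluation uses the final-epoch model.

Embedder: batch-all non-zero triplet loss — over all valid (anchor,
positive, negative) triplets in the batch, hinge terms
max(0, d²(a,p) − d²(a,n) + margin) with squared Euclidean distances and
margin 1.0, averaged over *strictly positive* terms only; a batch with no
active triplet contributes zero loss and no gradient. Minibatches hold
`per_class_batch` = 32 images of every class; one epoch runs
ceil(min_k n_k / 32) batches with each class cycling through a reshuffled
permutation (so an image of class k appears at most ceil(n_k/32) times
per epoch); classes smaller than 32 fall back to sampling with
replacement, with a warning. Early stopping monitors the batch-all loss
on the validation split and stops once it has failed to improve below its
running minimum for max(patience, 1) consecutive epochs (patience 5 by
default, hard cap 200 epochs); the returned parameters are the
validation-minimum snapshot. The embedder's Adam step is 3e-4 rather than
the classifier's 1e-3: with an unbounded 2D output and hinge gradients
proportional to embedding distances, the default step makes the
validation loss oscillate strongly enough that early stopping can fire on
the first epoch; 3e-4 trains stably across the test fixtures.

Splits are stratified per class (seeded shuffle within each class, exact
largest-remainder counts). This guarantees every class appears in every
nonempty split — a precondition of embedder training and of per-class
confusion rows — at the cost of not being a plain image-level shuffle.

The PCA baseline flattens standardized pixels, centers, and projects onto
the top principal axes (full SVD; the largest-magnitude loading of each
axis is made positive so signs are deterministic).

## Fingerprints

A population fingerprint is the Gaussian-mixture KDE over all of its
embedded points (no train/test split of the embedding scatter — particle
counts per population are low) with one full 2×2 bandwidth matrix H from
a two-stage plug-in selector:

1. **Pre-sphering** by the symmetric square root of the sample
   covariance. This makes the final estimate exactly scale- and
   rotation-equivariant (H ↦ c²H, H ↦ RHRᵀ to floating-point noise) and
   lets the pilot stage assume unit covariance.
2. **Pilot bandwidth.** The five fourth-order integrated density
   derivative functionals ψ_r (|r| = 4) are estimated by the double sum
   ψ̂_r = n⁻² Σᵢⱼ D^r φ_{g²I}(zᵢ − zⱼ) with diagonal terms included. The
   common isotropic pilot g minimizes the summed squared asymptotic bias
   of the five estimators under a standard-normal reference (sixth-order
   functionals in closed form). A single scalar pilot — rather than
   per-functional pilots — is what preserves exact rotation equivariance.
3. **AMISE minimization.** AMISE(H) = (4πn)⁻¹|H|^(−1/2) + ¼·Q_ψ̂(H), with
   Q a quadratic form in (h₁₁, h₁₂, h₂₂), is minimized by BFGS on a
   log-Cholesky parametrization (SPD by construction, analytic gradient)
   followed by a Newton polish directly in (h₁₁, h₁₂, h₂₂); the Newton
   map is covariant under rotations acting linearly on that triple, which
   pins equivariance to machine precision. The result is symmetrized and
   its eigenvalues floored at 10⁻¹²·tr(H).

On truly Gaussian data the AMISE optimum is n^(−1/3)·Σ at d = 2; the
selector lands within ~2% of it at n = 20,000 (the acceptance oracle
allows 20%). At least 8 non-collinear points are required.

HDR levels use the density-quantile estimator: λ(p) is the (1−p) quantile
of f evaluated at points distributed per the fingerprint — by default its
own support points, which at small N carries a modest upward smoothing
bias (each point sits on its own kernel bump); passing a fresh
Monte-Carlo sample (`points=fp.sample(...)`) gives calibrated levels, and
`hdr_mass` verifies enclosed mass by simulation. The global mode is found
by multi-start (top-5 density support points) shrinking-grid pattern
search to 1e-6; an exact two-maximizer tie returns the first-encountered
maximizer and sets a tie flag. Nearest-to-mode curation sorts by
Euclidean distance with ties broken by lower index. Embeddings enter the
KDE in raw network output units; no rescaling is applied before density
estimation.

## Goodness of fit

The Rosenblatt transform of the Gaussian-mixture null is closed-form:
u₁ = F₁(x₁) = N⁻¹ Σ Φ((x₁−pᵢ₁)/√H₁₁) and u₂ = F₂|₁(x₂|x₁) =
Σ wᵢ(x₁) Φ((x₂−μᵢ(x₁))/σ_c) with responsibilities wᵢ ∝ N(x₁; pᵢ₁, H₁₁),
μᵢ(x₁) = pᵢ₂ + (H₂₁/H₁₁)(x₁−pᵢ₁), σ_c² = H₂₂ − H₂₁²/H₁₁. The
factorization order follows the embedding axes (x₁ first); the transform
is order-dependent and the order is recorded in every result. Outputs are
clipped to [0, 1] against rounding just past the ends.

Subset testing: the test population is shuffled without replacement
(seeded), cut into floor(M/N_test) disjoint subsets (remainder dropped;
the reference example divides evenly), and each subset's 2·N_test
transformed coordinates are *pooled* into one one-sample KS test against
U(0, 1) — valid because the two coordinates are independent uniforms
under the null. How a 1D KS test should consume the 2D transform is
genuinely open; a per-coordinate Bonferroni variant (reject if
min(p₁, p₂) < α/2) is provided behind `variant="bonferroni"` and is
conservative, as expected. α defaults to 0.05 (configurable; no value is
canonical). The KS statistic and p-value come from `scipy.stats.kstest`
(exact sup-difference at jump points; standard exact/asymptotic p-value).
Under the null the subset rejection fraction is binomial(α) to within the
3σ band at 300 subsets; power is monotone in population shift and reaches
1.0 at 10 null-SDs.

## Pipeline

One master seed fans out to fixed per-stage seeds through
`numpy.random.SeedSequence(master, spawn_key=(stage,))`, so stages are
reproducible in isolation and no seed is reused. Every run directory
contains a config snapshot, seed record, timing log and a declared
artifact list checked by `check_run_dir`. The temporal study trains the
embedder only on in-training time points and embeds held-out time points
with the frozen network before fingerprint comparison.

## Problem sizes and limitations

Test and acceptance runs use desk-scale sizes chosen once: 500/class
(separable), 300/class (six-class), 2000/class (subtle pair), 250/class
(embedder), 20,000 samples for the bandwidth oracle, 30,000 points / 300
subsets for calibration, 3 × 2,000-point vials. Known limitations: the
classifier is evaluated only at the final epoch (no epoch selection); the
KDE is fixed-bandwidth (no adaptive/balloon estimators, no
cross-validation selectors); the GOF suite offers only the KS statistic;
and the forced out-of-sample assignment row quantifies resemblance among
trained classes, not identity — a foreign class always lands somewhere.
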