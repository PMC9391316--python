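"""Convolutional networks for particle-crop classification and 2D embedding.

Two closely related models share one small convolutional trunk:

* the **classifier**: trunk -> 32-unit feature layer -> K logits, trained
  with class-weighted cross entropy (weights inversely proportional to
  class counts) for a fixed number of epochs;
* the **embedder**: the same trunk and 32-unit feature layer, but the head
  is a 2-unit linear layer, trained with the batch-all non-zero triplet
  loss (squared Euclidean distances, margin 1.0) on minibatches holding a
  fixed number of images of every class, with early stopping on a
  validation split.

Trunk architecture: 2 x [3x3 conv (same padding), ReLU, 2x2 max-pool] with
16 then 32 channels, flatten, fully connected ReLU layer of 32 features.
This is the smallest standard trunk consistent with a 32-dimensional
penultimate feature layer; it is recorded in the model metadata so
alternatives are drop-in.

Everything is plain numpy: convolutions are im2col matrix products with
hand-derived backward passes, and the optimizer is Adam with the AMSgrad
correction.  Runs are deterministic for a fixed seed and fixed BLAS
threading.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preproc import NormalizationStats, compute_normalization, prepare_batch
from .synthetic import DatasetManifest, ParticleImage

__all__ = [
    "TrainConfig",
    "ClassifierModel",
    "EmbeddingModel",
    "ConfusionMatrix",
    "EmbeddingSet",
    "class_weights",
    "weighted_cross_entropy",
    "batch_all_triplet_loss",
    "make_pk_batches",
    "train_classifier",
    "train_embedder",
    "predict",
    "confusion_matrix",
    "classify_out_of_sample",
    "pca_embed",
    "embed_images",
]


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the reference protocol: 15 epochs / minibatch 256 /
    Adam with AMSgrad for the classifier; margin-1.0 batch-all triplet loss
    with 32 images of each class per minibatch and patience-5 early
    stopping (max 200 epochs) for the embedder; 80/20 splits throughout.
    The embedder uses a smaller Adam step (``embed_lr``) than the
    classifier: the unbounded 2D triplet output oscillates at 1e-3.
    """

    epochs: int = 15
    minibatch: int = 256
    lr: float = 1e-3
    embed_lr: float = 3e-4
    margin: float = 1.0
    per_class_batch: int = 32
    patience: int = 5
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("epochs", "minibatch", "per_class_batch", "max_epochs"):
            if int(getattr(self, attr)) < 1:
                raise ValueError(f"{attr} must be positive")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion fractions: row = truth, column = prediction."""

    matrix: np.ndarray
    labels: list[str]
    row_counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.row_counts):
            raise ValueError("confusion matrix shape mismatch")
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-15):
            raise ValueError("confusion entries must lie in [0, 1]")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("every confusion-matrix row must sum to 1")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels[: self.matrix.shape[0]],
                            columns=self.labels)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


@dataclass
class EmbeddingSet:
    """N points in 2D with class labels."""

    coords: np.ndarray
    labels: np.ndarray
    source: str = ""
    image_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[0] != self.labels.shape[0]:
            raise ValueError("coords and labels must agree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    def filter(self, labels: str | Sequence[str]) -> "EmbeddingSet":
        wanted = {labels} if isinstance(labels, str) else set(labels)
        mask = np.isin(self.labels, list(wanted))
        ids = self.image_ids[mask] if self.image_ids is not None else None
        return EmbeddingSet(self.coords[mask], self.labels[mask],
                            source=self.source, image_ids=ids)

    def to_csv(self, path: Path | str) -> None:
        df = pd.DataFrame({"x": self.coords[:, 0], "y": self.coords[:, 1],
                           "label": self.labels})
        if self.image_ids is not None:
            df["image_id"] = self.image_ids
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "EmbeddingSet":
        df = pd.read_csv(path)
        ids = df["image_id"].to_numpy() if "image_id" in df else None
        return cls(df[["x", "y"]].to_numpy(), df["label"].to_numpy(), image_ids=ids)


# ---------------------------------------------------------------------------
# Layers (im2col convolutions, max-pool, dense) with manual gradients
# ---------------------------------------------------------------------------

# Internal layout is channels-last (B, H, W, C) in float32: a 3x3
# same-padding conv is a single GEMM on a concatenated shifted-patch
# matrix, which keeps the arithmetic in BLAS.

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, 9*C) shifted-patch matrix (zero padding)."""
    bsz, h, w, c = x.shape
    xp = np.zeros((bsz, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    cols = np.empty((bsz * h * w, 9 * c), dtype=x.dtype)
    for k, (di, dj) in enumerate((i, j) for i in range(3) for j in range(3)):
        cols[:, k * c:(k + 1) * c] = xp[:, di:di + h, dj:dj + w, :].reshape(-1, c)
    return cols


def _wmat(W: np.ndarray) -> np.ndarray:
    """(F, C, 3, 3) kernel -> (9*C, F) matrix matching _im2col's layout."""
    return W.transpose(2, 3, 1, 0).reshape(-1, W.shape[0])


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    bsz, h, w, c = x.shape
    cols = _im2col(x)
    out = cols @ _wmat(W) + b
    return out.reshape(bsz, h, w, W.shape[0]), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray):
    bsz, h, w, f = dout.shape
    c = W.shape[1]
    dflat = dout.reshape(-1, f)
    dWmat = cols.T @ dflat                                   # (9C, F)
    dW = dWmat.reshape(3, 3, c, f).transpose(3, 2, 0, 1)
    db = dflat.sum(axis=0)
    dcols = dflat @ _wmat(W).T                               # (BHW, 9C)
    dxp = np.zeros((bsz, h + 2, w + 2, c), dtype=dout.dtype)
    for k, (di, dj) in enumerate((i, j) for i in range(3) for j in range(3)):
        dxp[:, di:di + h, dj:dj + w, :] += dcols[:, k * c:(k + 1) * c].reshape(
            bsz, h, w, c)
    return dxp[:, 1:-1, 1:-1, :], dW, db


def _pool_forward(x: np.ndarray):
    """2x2 max-pool, stride 2, channels-last. Assumes even H, W.

    Ties go to the first element in row-major order (fixed convention for
    deterministic gradients).
    """
    a, b = x[:, 0::2], x[:, 1::2]
    v_first = a >= b
    m1 = np.where(v_first, a, b)
    cc, d = m1[:, :, 0::2], m1[:, :, 1::2]
    h_first = cc >= d
    out = np.where(h_first, cc, d)
    return out, (v_first, h_first)


def _pool_backward(dout: np.ndarray, masks, x_shape: tuple) -> np.ndarray:
    bsz, h, w, c = x_shape
    v_first, h_first = masks
    vf_even = v_first[:, :, 0::2]
    vf_odd = v_first[:, :, 1::2]
    dx = np.zeros((bsz, h, w, c), dtype=dout.dtype)
    dx[:, 0::2, 0::2] = dout * (h_first & vf_even)
    dx[:, 1::2, 0::2] = dout * (h_first & ~vf_even)
    dx[:, 0::2, 1::2] = dout * (~h_first & vf_odd)
    dx[:, 1::2, 1::2] = dout * (~h_first & ~vf_odd)
    return dx


_ARCH = {"conv_channels": [16, 32], "kernel": 3, "pool": 2, "feature_dim": 32}


def _init_params(in_side: int, n_out: int, rng: np.random.Generator) -> dict:
    """He-initialized parameters for the trunk plus an ``n_out``-unit head."""
    c1, c2 = _ARCH["conv_channels"]
    flat = c2 * (in_side // 4) * (in_side // 4)
    fd = _ARCH["feature_dim"]

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    return {
        "W1": he((c1, 1, 3, 3), 9), "b1": np.zeros(c1, dtype=np.float32),
        "W2": he((c2, c1, 3, 3), 9 * c1), "b2": np.zeros(c2, dtype=np.float32),
        "W3": he((fd, flat), flat), "b3": np.zeros(fd, dtype=np.float32),
        "W4": he((n_out, fd), fd), "b4": np.zeros(n_out, dtype=np.float32),
    }


def _forward(params: dict, x: np.ndarray, want_grad_cache: bool = False):
    """Trunk + head forward pass.

    Returns (head_output, features, cache); features are the 32-unit
    post-ReLU penultimate activations.
    """
    dtype = params["W1"].dtype
    x = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=dtype)  # channels-last
    h1, cols1 = _conv_forward(x, params["W1"], params["b1"])
    a1 = np.maximum(h1, 0.0)
    p1, masks1 = _pool_forward(a1)
    h2, cols2 = _conv_forward(p1, params["W2"], params["b2"])
    a2 = np.maximum(h2, 0.0)
    p2, masks2 = _pool_forward(a2)
    flat = p2.reshape(p2.shape[0], -1)
    f = flat @ params["W3"].T + params["b3"]
    feat = np.maximum(f, 0.0)
    out = feat @ params["W4"].T + params["b4"]
    cache = None
    if want_grad_cache:
        cache = (cols1, h1, a1.shape, masks1, cols2, h2, a2.shape, masks2,
                 p2.shape, flat, f, feat)
    return out, feat, cache


def _backward(params: dict, cache, dout: np.ndarray) -> dict:
    (cols1, h1, a1_shape, masks1, cols2, h2, a2_shape, masks2, p2_shape,
     flat, f, feat) = cache
    grads = {}
    grads["W4"] = dout.T @ feat
    grads["b4"] = dout.sum(axis=0)
    dfeat = dout @ params["W4"]
    df = dfeat * (f > 0)
    grads["W3"] = df.T @ flat
    grads["b3"] = df.sum(axis=0)
    dflat = df @ params["W3"]
    dp2 = dflat.reshape(p2_shape)
    da2 = _pool_backward(dp2, masks2, a2_shape)
    dh2 = da2 * (h2 > 0)
    dp1, grads["W2"], grads["b2"] = _conv_backward(dh2, cols2, params["W2"])
    da1 = _pool_backward(dp1, masks1, a1_shape)
    dh1 = da1 * (h1 > 0)
    _, grads["W1"], grads["b1"] = _conv_backward(dh1, cols1, params["W1"])
    return grads


class AdamAMSGrad:
    """Adam optimizer with the AMSgrad maximum-of-second-moment correction."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.vhat = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            np.maximum(self.vhat[k], self.v[k], out=self.vhat[k])
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.vhat[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def class_weights(counts: Sequence[int]) -> np.ndarray:
    """Per-class weights w_k proportional to 1/n_k, normalized to sum to K."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 1):
        raise ValueError("every class count must be >= 1")
    inv = 1.0 / c
    return inv * (len(c) / inv.sum())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray, return_grad: bool = False):
    """Class-weighted cross entropy with the weighted-mean convention.

    loss = sum_i w_{y_i} * (-log softmax(logits_i)[y_i]) / sum_i w_{y_i}.
    The weighted-mean denominator keeps the loss scale comparable across
    imbalance levels (a plain mean would shrink as rare classes get heavy
    weights).
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=float)
    n, k = logits.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError("label out of range for the given logits")
    p = _softmax(logits)
    wi = weights[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    denom = wi.sum()
    loss = float((wi * nll).sum() / denom)
    if not return_grad:
        return loss
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (wi / denom)[:, None]
    return loss, grad


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    sq = (x * x).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d, 0.0, out=d)
    return d


def batch_all_triplet_loss(embeddings: np.ndarray, labels: np.ndarray,
                           margin: float = 1.0, return_grad: bool = False):
    """Batch-all non-zero triplet loss with squared Euclidean distances.

    Every valid (anchor, positive, negative) triplet in the batch
    contributes ``max(0, d2(a,p) - d2(a,n) + margin)``; the loss is the
    mean over the *strictly positive* terms only ("non-zero" convention).
    A batch in which no triplet is active has loss 0 and no gradient.
    """
    x = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("triplet loss needs at least 2 classes in the batch")
    same = y[:, None] == y[None, :]
    if not np.any(same & ~np.eye(len(y), dtype=bool)):
        raise ValueError("triplet loss needs a class with >= 2 samples")

    d = _pairwise_sq_dists(x)
    n = len(y)
    total = 0.0
    n_active = 0
    coef = np.zeros((n, n)) if return_grad else None
    eye = np.eye(n, dtype=bool)
    for a in range(n):
        pos = same[a] & ~eye[a]
        neg = ~same[a]
        if not pos.any() or not neg.any():
            continue
        terms = d[a, pos][:, None] - d[a, neg][None, :] + margin
        active = terms > 0
        total += terms[active].sum()
        n_active += int(active.sum())
        if return_grad:
            pi = np.flatnonzero(pos)
            ni = np.flatnonzero(neg)
            coef[a, pi] += active.sum(axis=1)          # d term / d d2(a,p) = +1
            coef[a, ni] -= active.sum(axis=0)          # d term / d d2(a,n) = -1
    if n_active == 0:
        loss = 0.0
        grad = np.zeros_like(x)
    else:
        loss = total / n_active
        grad = None
        if return_grad:
            c = (coef + coef.T) / n_active
            # d d2(i,j)/d x_i = 2 (x_i - x_j); accumulate over the row of c
            grad = 2.0 * (c.sum(axis=1)[:, None] * x - c @ x)
    if return_grad:
        return float(loss), grad
    return float(loss)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def make_pk_batches(labels: np.ndarray, per_class: int = 32,
                    seed: int = 0) -> Iterator[np.ndarray]:
    """One epoch of P·K minibatch index arrays: ``per_class`` images of
    every class per batch.

    The number of batches is ``ceil(min_k n_k / per_class)``; each class's
    images are used in a seeded shuffled order, wrapping around (reuse only
    after exhaustion), so over one epoch an image of class k appears at
    most ``ceil(n_k / per_class)`` times.  Classes smaller than
    ``per_class`` fall back to sampling with replacement (with a warning).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("PK batching needs at least 2 classes")
    rng = np.random.default_rng(seed)
    index_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    n_min = min(len(v) for v in index_by_class.values())
    n_batches = max(1, -(-n_min // per_class))
    pools = {}
    for c in classes:
        idx = index_by_class[c]
        need = n_batches * per_class
        if len(idx) < per_class:
            warnings.warn(
                f"class {c!r} has {len(idx)} < per_class={per_class} images; "
                "sampling with replacement", stacklevel=2)
            pools[c] = rng.choice(idx, size=need, replace=True)
        else:
            reps = []
            while sum(len(r) for r in reps) < need:
                reps.append(rng.permutation(idx))
            pools[c] = np.concatenate(reps)[:need]
    for b in range(n_batches):
        batch = np.concatenate([pools[c][b * per_class:(b + 1) * per_class]
                                for c in classes])
        yield batch


# ---------------------------------------------------------------------------
# Models and training
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


@dataclass
class _BaseModel:
    params: dict
    labels: list[str]
    stats: NormalizationStats
    input_side: int = 32
    arch: dict = field(default_factory=lambda: dict(_ARCH))

    def features(self, x: np.ndarray) -> np.ndarray:
        _, feat, _ = _forward(self.params, x)
        return feat

    def save(self, path: Path | str) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {"format_version": FORMAT_VERSION, "kind": type(self).__name__,
                "labels": list(self.labels), "stats": self.stats.to_dict(),
                "input_side": self.input_side, "arch": self.arch}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "_BaseModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        with np.load(path.with_suffix(".npz")) as z:
            params = {k: z[k].copy() for k in z.files}
        return cls(params=params, labels=list(meta["labels"]),
                   stats=NormalizationStats.from_dict(meta["stats"]),
                   input_side=int(meta["input_side"]), arch=meta["arch"])


class ClassifierModel(_BaseModel):
    """Trunk + K-logit head; penultimate feature layer has 32 units."""

    def logits(self, x: np.ndarray) -> np.ndarray:
        out, _, _ = _forward(self.params, x)
        return out


class EmbeddingModel(_BaseModel):
    """Trunk + 2-unit linear head producing 2D embedding coordinates."""

    def embed(self, x: np.ndarray) -> np.ndarray:
        out, _, _ = _forward(self.params, x)
        return out


def _resolve_dataset(data, split: str):
    """Accept a DatasetManifest or a (images, labels)-style in-memory list."""
    if isinstance(data, DatasetManifest):
        images = data.load_images(split)
    elif isinstance(data, dict):
        images = data.get(split, [])
    else:
        raise TypeError("expected DatasetManifest or {split: [ParticleImage]} dict")
    labels = np.array([im.label for im in images])
    return images, labels


def train_classifier(data, config: TrainConfig | None = None,
                     target: int = 32):
    """Train the classification network for exactly ``config.epochs`` epochs.

    ``data`` is a :class:`DatasetManifest` (or an in-memory
    ``{"train": [...], "test": [...]}`` dict).  Normalization statistics
    are computed on the train split only; the test split never touches a
    gradient.  Returns ``(ClassifierModel, log)`` where ``log`` is a
    per-epoch DataFrame with the mean training loss and step count.
    """
    config = config or TrainConfig()
    train_images, train_labels = _resolve_dataset(data, "train")
    if len(train_images) == 0:
        raise ValueError("empty train split")
    label_names = sorted(set(train_labels))
    if len(label_names) < 2:
        raise ValueError("need >= 2 classes to train a classifier")
    label_to_idx = {c: i for i, c in enumerate(label_names)}
    y = np.array([label_to_idx[l] for l in train_labels])

    stats = compute_normalization(train_images)
    x = prepare_batch(train_images, stats, target=target)
    counts = np.bincount(y, minlength=len(label_names))
    w = class_weights(counts)

    rng = np.random.default_rng(config.seed)
    params = _init_params(target, len(label_names), rng)
    opt = AdamAMSGrad(params, lr=config.lr)

    n = len(y)
    log_rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses, steps = [], 0
        for start in range(0, n, config.minibatch):
            idx = order[start:start + config.minibatch]
            out, _, cache = _forward(params, x[idx], want_grad_cache=True)
            loss, dlogits = weighted_cross_entropy(out, y[idx], w, return_grad=True)
            grads = _backward(params, cache, dlogits.astype(np.float32))
            opt.step(params, grads)
            losses.append(loss)
            steps += 1
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "steps": steps})
    model = ClassifierModel(params=params, labels=label_names, stats=stats,
                            input_side=target)
    return model, pd.DataFrame(log_rows)


def _full_triplet_loss(model_params: dict, x: np.ndarray, y: np.ndarray,
                       margin: float) -> float:
    emb, _, _ = _forward(model_params, x)
    return batch_all_triplet_loss(emb, y, margin=margin)


def train_embedder(data, config: TrainConfig | None = None, target: int = 32):
    """Train the embedding network with batch-all triplet loss + early stop.

    Stops once the validation triplet loss has failed to improve below its
    running minimum for ``max(patience, 1)`` consecutive epochs, or at
    ``config.max_epochs``; returns the parameter snapshot at the validation
    minimum.  Every class must be present in both the train and val splits.
    """
    config = config or TrainConfig()
    train_images, train_labels = _resolve_dataset(data, "train")
    val_images, val_labels = _resolve_dataset(data, "val")
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("embedder needs nonempty train and val splits")
    label_names = sorted(set(train_labels))
    missing = set(label_names) - set(val_labels)
    if missing:
        raise ValueError(f"classes absent from the val split: {sorted(missing)}")

    label_to_idx = {c: i for i, c in enumerate(label_names)}
    y_tr = np.array([label_to_idx[l] for l in train_labels])
    y_va = np.array([label_to_idx[l] for l in val_labels])

    stats = compute_normalization(train_images)
    x_tr = prepare_batch(train_images, stats, target=target)
    x_va = prepare_batch(val_images, stats, target=target)

    rng = np.random.default_rng(config.seed)
    params = _init_params(target, 2, rng)
    opt = AdamAMSGrad(params, lr=config.embed_lr)

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    stall = 0
    log_rows = []
    for epoch in range(1, config.max_epochs + 1):
        batch_seed = int(rng.integers(2**31))
        losses = []
        for idx in make_pk_batches(y_tr, per_class=config.per_class_batch,
                                   seed=batch_seed):
            out, _, cache = _forward(params, x_tr[idx], want_grad_cache=True)
            loss, demb = batch_all_triplet_loss(out, y_tr[idx],
                                                margin=config.margin,
                                                return_grad=True)
            grads = _backward(params, cache, demb.astype(np.float32))
            opt.step(params, grads)
            losses.append(loss)
        val_loss = _full_triplet_loss(params, x_va, y_va, config.margin)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "val_loss": float(val_loss)})
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= max(config.patience, 1):
                break
    model = EmbeddingModel(params=best_params, labels=label_names, stats=stats,
                           input_side=target)
    log = pd.DataFrame(log_rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_val_loss"] = float(best_loss)
    return model, log


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict(model: ClassifierModel, images: Sequence[ParticleImage]) -> np.ndarray:
    """Argmax class labels using the model's frozen normalization stats."""
    x = prepare_batch(images, model.stats, target=model.input_side)
    preds = []
    for start in range(0, len(images), 512):
        preds.append(model.logits(x[start:start + 512]).argmax(axis=1))
    idx = np.concatenate(preds) if preds else np.array([], dtype=int)
    return np.array([model.labels[i] for i in idx])


def confusion_matrix(pred: np.ndarray, truth: np.ndarray,
                     labels: Sequence[str]) -> ConfusionMatrix:
    """Row-normalized confusion fractions over ``labels``."""
    labels = list(labels)
    unseen = set(truth) - set(labels)
    if unseen:
        raise ValueError(f"ground-truth labels not in label set: {sorted(unseen)}")
    k = len(labels)
    idx = {c: i for i, c in enumerate(labels)}
    m = np.zeros((k, k))
    for p, t in zip(pred, truth):
        m[idx[t], idx[p]] += 1
    counts = m.sum(axis=1)
    if np.any(counts == 0):
        empty = [labels[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"no ground-truth samples for classes: {empty}")
    return ConfusionMatrix(matrix=m / counts[:, None], labels=labels,
                           row_counts=counts.astype(int))


def classify_out_of_sample(model: ClassifierModel,
                           images: Sequence[ParticleImage]) -> pd.Series:
    """Force-assign a foreign class: distribution of predictions over the
    trained classes (one row summing to 1)."""
    pred = predict(model, images)
    counts = pd.Series(pred).value_counts().reindex(model.labels, fill_value=0)
    return counts / counts.sum()


def embed_images(model: EmbeddingModel, images: Sequence[ParticleImage],
                 source: str = "cnn") -> EmbeddingSet:
    x = prepare_batch(images, model.stats, target=model.input_side)
    coords = []
    for start in range(0, len(images), 512):
        coords.append(model.embed(x[start:start + 512]))
    coords = np.vstack(coords) if coords else np.empty((0, 2))
    return EmbeddingSet(coords, np.array([im.label for im in images]),
                        source=source,
                        image_ids=np.array([im.id for im in images]))


def pca_embed(images: Sequence[ParticleImage], dims: int = 2,
              stats: NormalizationStats | None = None,
              target: int = 32) -> EmbeddingSet:
    """Linear unsupervised baseline: PCA of flattened standardized pixels.

    Signs are fixed deterministically: in each principal axis the
    largest-magnitude loading is made positive.
    """
    if len(images) < dims + 1:
        raise ValueError(f"need at least {dims + 1} images for {dims}-D PCA")
    if stats is None:
        stats = compute_normalization(images)
    x = prepare_batch(images, stats, target=target).reshape(len(images), -1)
    pca = PCA(n_components=dims, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(dims):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, j] *= -1.0
    return EmbeddingSet(coords, np.array([im.label for im in images]),
                        source="pca",
                        image_ids=np.array([im.id for im in images]))
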