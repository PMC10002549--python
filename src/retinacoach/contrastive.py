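"""Multilabel supervised contrastive representation learning and the
downstream per-class classifier.

The representation is learned with a supervised contrastive (SupCon) loss
adapted to the multilabel setting: for an anchor image carrying the class
set {Ci}, every other batch sample sharing *any* class with the anchor is a
positive.  With unit-norm projections ``z`` and temperature ``τ``, the loss
is the positives-outside-log (L_out) form,

    L = mean over anchors i with P(i) != {} of
        -(1/|P(i)|) Σ_{p in P(i)} log[ exp(z_i·z_p/τ) / Σ_{a != i} exp(z_i·z_a/τ) ]

Anchors with no positive in the batch are skipped (and counted).  Training
is two-stage: stage 1 fits a projection head (dense + ReLU + linear, 128-d
output) on the contrastive loss with Adam and analytic gradients; stage 2
freezes the representation and fits one sigmoid (logistic) classifier per
class, giving independent per-class probabilities p_C(x) with no sum-to-one
constraint.

At desk scale the encoder is a deterministic pooled-feature extractor
(``tiny-pool``): images are resized to 64 px and mean-pooled over an 8 x 8
grid of four channels (R, G, B, gradient magnitude).  A full-scale deep
encoder is a named configuration slot; it shares the same head and loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from skimage import color, transform as sktransform
from sklearn.linear_model import LogisticRegression

from .imaging import augment

__all__ = [
    "TrainConfig",
    "PredictionVector",
    "FundusModel",
    "supcon_multilabel_loss",
    "supcon_loss_and_grad",
    "pooled_features",
    "train",
    "predict",
    "embed",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# loss

def _positive_mask(label_sets: Sequence[Set[str]]) -> np.ndarray:
    """mask[i, j] = 1 iff i != j and label sets i, j intersect."""
    n = len(label_sets)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if label_sets[i] & label_sets[j]:
                mask[i, j] = mask[j, i] = True
    return mask


def supcon_loss_and_grad(
    projections: np.ndarray,
    label_sets: Sequence[Set[str]],
    temperature: float = 0.1,
) -> Tuple[float, np.ndarray, int]:
    """Multilabel SupCon loss, its gradient w.r.t. the projections, and the
    number of anchors skipped for lack of an in-batch positive.

    ``projections`` must be unit-norm rows.
    """
    z = np.asarray(projections, dtype=float)
    n = z.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    if len(label_sets) != n:
        raise ValueError("labels and projections disagree in length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    pos = _positive_mask(label_sets)
    n_pos = pos.sum(axis=1)
    valid = n_pos > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(z), n

    sims = (z @ z.T) / temperature
    np.fill_diagonal(sims, -np.inf)  # exclude the anchor itself
    logZ = np.logaddexp.reduce(sims, axis=1)
    # loss_i = logZ_i - mean over positives of sims[i, p]
    loss = 0.0
    for i in np.where(valid)[0]:
        loss += logZ[i] - sims[i, pos[i]].mean()
    loss /= n_valid

    # gradient w.r.t. sims: softmax minus the positive indicator average
    soft = np.exp(sims - logZ[:, None])
    D = np.zeros_like(soft)
    D[valid] = soft[valid] - pos[valid] / n_pos[valid, None]
    D /= n_valid * temperature
    grad = D @ z + D.T @ z
    return float(loss), grad, int(n - n_valid)


def supcon_multilabel_loss(projections: np.ndarray,
                           label_sets: Sequence[Set[str]],
                           temperature: float = 0.1) -> float:
    """The multilabel supervised contrastive loss (see module docstring)."""
    loss, _, _ = supcon_loss_and_grad(projections, label_sets, temperature)
    return loss


# ---------------------------------------------------------------------------
# tiny-pool encoder

POOL_GRID = 8
POOL_SIZE = 64


def pooled_features(image: np.ndarray, grid: int = POOL_GRID,
                    size: int = POOL_SIZE) -> np.ndarray:
    """Deterministic desk-scale encoder representation.

    The image is resized to ``size`` px and four channels (R, G, B, and the
    gray-level gradient magnitude) are mean-pooled over a ``grid x grid``
    partition, yielding a ``4 * grid**2`` feature vector.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    img = sktransform.resize(img, (size, size, 3), anti_aliasing=True)
    gray = color.rgb2gray(img)
    gy, gx = np.gradient(gray)
    grad = np.sqrt(gy ** 2 + gx ** 2)
    channels = np.concatenate([img, grad[..., None]], axis=2)
    step = size // grid
    pooled = channels.reshape(grid, step, grid, step, 4).mean(axis=(1, 3))
    return pooled.reshape(-1)


# ---------------------------------------------------------------------------
# model

@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the production recipe where stated (temperature 0.1,
    initial learning rate 5e-4, 30-epoch classifier stage); epochs and batch
    size default to desk-scale values suited to the tiny-pool encoder.
    """

    temperature: float = 0.1
    lr: float = 0.0005
    epochs: int = 60
    batch_size: int = 64
    classifier_epochs: int = 30
    encoder: str = "tiny-pool"  # "resnext50_32x4d" is the full-scale slot
    hidden_dim: int = 64
    projection_dim: int = 128
    n_views: int = 2  # augmented views per image in each contrastive batch
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class PredictionVector:
    """Independent per-class probabilities and the 0.5-thresholded set."""

    classes: Tuple[str, ...]
    probs: np.ndarray

    @property
    def predicted_set(self) -> frozenset:
        return frozenset(c for c, p in zip(self.classes, self.probs)
                         if p >= 0.5)


@dataclass
class FundusModel:
    """Trained state: feature scaler, projection head, per-class classifier."""

    classes: List[str]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    clf_coef: np.ndarray  # (n_classes, embedding_dim)
    clf_intercept: np.ndarray
    encoder: str = "tiny-pool"
    loss_history: List[float] = field(default_factory=list)
    version: str = "1"

    # -- forward passes ----------------------------------------------------

    def _features(self, image: np.ndarray) -> np.ndarray:
        f = pooled_features(image)
        return (f - self.feat_mean) / self.feat_std

    def _project(self, feats: np.ndarray) -> np.ndarray:
        h = np.maximum(feats @ self.W1 + self.b1, 0.0) @ self.W2 + self.b2
        return h / (np.linalg.norm(h, axis=-1, keepdims=True) + 1e-12)

    def save(self, path) -> None:
        doc = {
            "version": self.version,
            "encoder": self.encoder,
            "classes": self.classes,
            "loss_history": self.loss_history,
        }
        for name in ("feat_mean", "feat_std", "W1", "b1", "W2", "b2",
                     "clf_coef", "clf_intercept"):
            doc[name] = getattr(self, name).tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "FundusModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        arrays = {
            name: np.asarray(doc[name], dtype=float)
            for name in ("feat_mean", "feat_std", "W1", "b1", "W2", "b2",
                         "clf_coef", "clf_intercept")
        }
        return cls(classes=list(doc["classes"]), encoder=doc["encoder"],
                   loss_history=list(doc["loss_history"]),
                   version=doc["version"], **arrays)


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _head_forward(feats, W1, b1, W2, b2):
    a1 = feats @ W1 + b1
    r = np.maximum(a1, 0.0)
    h = r @ W2 + b2
    norm = np.linalg.norm(h, axis=1, keepdims=True) + 1e-12
    return a1, r, h, h / norm, norm


def train(dataset: Sequence[Tuple[np.ndarray, Set[str]]],
          config: TrainConfig | None = None) -> FundusModel:
    """Two-stage training: contrastive head, then frozen per-class sigmoid.

    ``dataset`` holds (image, label set) pairs.  Deterministic given
    ``config.seed`` up to floating-point reduction order.
    """
    config = config or TrainConfig()
    if config.encoder != "tiny-pool":
        raise NotImplementedError(
            f"encoder {config.encoder!r} is a named configuration; only the "
            "tiny-pool desk-scale encoder is implemented here"
        )
    label_sets = [set(labels) for _, labels in dataset]
    classes = sorted({c for ls in label_sets for c in ls})
    if len(classes) < 2:
        raise ValueError("training needs at least 2 distinct classes")
    rng = np.random.default_rng(config.seed)

    # views: the raw image plus (n_views - 1) augmented copies, precomputed
    feats_list, view_labels = [], []
    for idx, (image, labels) in enumerate(dataset):
        views = [np.asarray(image, dtype=float)]
        for v in range(config.n_views - 1):
            views.append(augment(image, seed=int(rng.integers(2 ** 31))))
        for v in views:
            feats_list.append(pooled_features(v))
            view_labels.append(set(labels))
    feats = np.asarray(feats_list)
    feat_mean = feats.mean(axis=0)
    feat_std = feats.std(axis=0) + 1e-8
    feats = (feats - feat_mean) / feat_std
    n, fdim = feats.shape

    # projection head init (He for the ReLU layer)
    W1 = rng.normal(0, np.sqrt(2.0 / fdim), (fdim, config.hidden_dim))
    b1 = np.zeros(config.hidden_dim)
    W2 = rng.normal(0, np.sqrt(1.0 / config.hidden_dim),
                    (config.hidden_dim, config.projection_dim))
    b2 = np.zeros(config.projection_dim)
    params = [W1, b1, W2, b2]
    opt = _Adam(params, config.lr)

    losses: List[float] = []
    skipped_total = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue
            fb = feats[idx]
            lb = [view_labels[i] for i in idx]
            a1, r, h, z, norm = _head_forward(fb, W1, b1, W2, b2)
            loss, gz, skipped = supcon_loss_and_grad(z, lb, config.temperature)
            skipped_total += skipped
            # back through the normalisation: dh = (g - (g.z) z) / |h|
            gh = (gz - (gz * z).sum(axis=1, keepdims=True) * z) / norm
            gW2 = r.T @ gh
            gb2 = gh.sum(axis=0)
            gr = gh @ W2.T
            ga1 = gr * (a1 > 0)
            gW1 = fb.T @ ga1
            gb1 = ga1.sum(axis=0)
            opt.step(params, [gW1, gb1, gW2, gb2])
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    if skipped_total:
        log.info("skipped %d anchors with no in-batch positive", skipped_total)

    # stage 2: frozen embeddings of the clean views, one sigmoid per class
    clean = feats[:: config.n_views] if config.n_views > 1 else feats
    clean_labels = label_sets
    _, _, _, emb, _ = _head_forward(clean, W1, b1, W2, b2)
    coef = np.zeros((len(classes), emb.shape[1]))
    intercept = np.zeros(len(classes))
    for ci, c in enumerate(classes):
        y = np.array([c in ls for ls in clean_labels], dtype=int)
        if y.min() == y.max():  # degenerate: class everywhere or nowhere
            intercept[ci] = 20.0 if y[0] else -20.0
            continue
        clf = LogisticRegression(max_iter=200 * max(1, config.classifier_epochs // 30))
        clf.fit(emb, y)
        coef[ci] = clf.coef_[0]
        intercept[ci] = clf.intercept_[0]

    return FundusModel(
        classes=classes,
        feat_mean=feat_mean, feat_std=feat_std,
        W1=W1, b1=b1, W2=W2, b2=b2,
        clf_coef=coef, clf_intercept=intercept,
        encoder=config.encoder, loss_history=losses,
    )


def _check_trained(model) -> None:
    if not isinstance(model, FundusModel):
        raise TypeError("expected a trained FundusModel")


def predict(image: np.ndarray, model: FundusModel) -> PredictionVector:
    """Per-class probabilities for one image, thresholded at 0.5."""
    _check_trained(model)
    z = embed(image, model)
    logits = model.clf_coef @ z + model.clf_intercept
    probs = 1.0 / (1.0 + np.exp(-logits))
    return PredictionVector(classes=tuple(model.classes), probs=probs)


def embed(image: np.ndarray, model: FundusModel) -> np.ndarray:
    """Unit-norm projection-space embedding used for neighbor search."""
    _check_trained(model)
    return model._project(model._features(image))
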