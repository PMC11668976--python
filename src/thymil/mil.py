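"""Attention-based multiple-instance learning for slide classification.

A slide is a *bag* of patch feature vectors with a single slide-level label;
patch labels are unknown.  The model composes a decoupled patch encoder
``E``, a per-class gated-attention aggregator ``F`` and a linear bag
classifier ``C``: the bag prediction is ``C(F(E(X)))``.  For every class c
the aggregator assigns each instance a softmax-normalised attention weight
``a_i^c`` and forms the bag representation ``F_c = sum_i a_i^c z_i``; a
per-class linear score on ``F_c`` followed by a softmax gives the bag
probabilities.

Everything here is plain numpy with hand-derived gradients and an Adam
optimizer, so training is single-threaded and bit-deterministic under a
fixed seed.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "Bag",
    "BagPrediction",
    "TrainConfig",
    "EncoderSpec",
    "IdentityEncoder",
    "LinearEncoder",
    "SmallConvEncoder",
    "make_encoder",
    "encode",
    "GatedAttentionMIL",
    "attention_aggregate",
    "train_mil",
    "evaluate",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Bag:
    """One slide as an ordered set of instance feature vectors.

    ``Z`` has shape (N, D) with N >= 1 varying per slide; ``Y`` is the
    0-based bag class index, or None when unknown.
    """

    slide_id: str
    Z: np.ndarray
    Y: int | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[0] < 1:
            raise ValueError("Bag.Z must be a (N, D) array with N >= 1")

    @property
    def n_instances(self) -> int:
        return self.Z.shape[0]


@dataclass
class BagPrediction:
    """Bag-level output: class probabilities, per-class attention, bag features.

    ``attention`` is (N, C): column c is the softmax-normalised attention of
    every instance for class c (each column sums to 1).  ``bag_features`` is
    (C, D): row c is the attention-weighted sum of instance features for
    class c.
    """

    probs: np.ndarray
    attention: np.ndarray
    bag_features: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.probs < -1e-12) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be a probability vector")
        colsums = self.attention.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("every attention column must sum to 1")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (Adam throughout).

    The MIL head trains with batch size 1 at lr 1e-4; the auxiliary patch
    classifier with batch size 64 at lr 5e-5; both halve the learning rate
    on a fixed epoch interval.  The original fine-tuning recipe decays
    every 10 epochs; because the bag classifier here trains from scratch
    rather than from pretrained weights, the default horizon is doubled
    (decay every 20 epochs, 100 epochs total) — set ``lr_decay_every=10``
    and ``epochs=50`` to match the original schedule.
    """

    mil_batch_size: int = 1
    mil_lr: float = 1e-4
    patch_batch_size: int = 64
    patch_lr: float = 5e-5
    lr_decay: float = 0.5
    lr_decay_every: int = 20
    epochs: int = 100
    patch_epochs: int = 100
    patience: int = 20
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mil_lr <= 0 or self.patch_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must lie in (0, 1]")


# ---------------------------------------------------------------------------
# encoders


@dataclass
class EncoderSpec:
    """Declarative encoder choice.

    kind: 'identity' (precomputed features pass through), 'linear' (trainable
    affine map in feature space — the encoder that pseudo-label refinement
    updates), or 'small-conv' (fixed seeded random convolutional features for
    image tiles).
    """

    kind: str = "identity"
    output_dim: int | None = None
    seed: int = 0


class IdentityEncoder:
    """Pass-through encoder for precomputed feature bags."""

    trainable = False

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)

    def copy(self) -> "IdentityEncoder":
        return self


class LinearEncoder:
    """Trainable affine encoder z -> W z + b, initialised at the identity.

    This is the feature-space stand-in for the fine-tunable backbone: the
    patch classifier shares these weights, so training the patch classifier
    moves the bag features too.
    """

    trainable = True

    def __init__(self, in_dim: int, out_dim: int | None = None,
                 rng: np.random.Generator | None = None):
        out_dim = in_dim if out_dim is None else out_dim
        if out_dim == in_dim:
            self.W = np.eye(out_dim)
        else:
            rng = rng or np.random.default_rng(0)
            self.W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), (out_dim, in_dim))
        self.b = np.zeros(out_dim)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.W.T + self.b

    def copy(self) -> "LinearEncoder":
        return copy.deepcopy(self)

    def params(self) -> dict:
        return {"W": self.W, "b": self.b}


class SmallConvEncoder:
    """Three-layer random-projection convolutional encoder for image tiles.

    Weights are drawn once from a seeded generator and frozen, which gives a
    deterministic, training-free feature map adequate for desk-scale image
    experiments; the downstream trainable LinearEncoder adapts on top of it.
    """

    trainable = False

    def __init__(self, output_dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [3, 8, 16, 32]
        self.kernels = [
            rng.normal(0, 1.0 / np.sqrt(9 * cin), (cout, cin, 3, 3))
            for cin, cout in zip(chans[:-1], chans[1:])
        ]
        self.proj = rng.normal(0, 1.0 / np.sqrt(chans[-1]), (output_dim, chans[-1]))
        self.output_dim = output_dim

    @staticmethod
    def _conv(x: np.ndarray, k: np.ndarray) -> np.ndarray:
        # x: (H, W, Cin), k: (Cout, Cin, 3, 3); valid conv + ReLU + 2x2 mean pool
        H, W, _ = x.shape
        patches = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(0, 1))
        out = np.einsum("hwcij,ocij->hwo", patches, k)
        out = np.maximum(out, 0.0)
        h2, w2 = (H - 2) // 2 * 2, (W - 2) // 2 * 2
        out = out[:h2, :w2]
        return out.reshape(h2 // 2, 2, w2 // 2, 2, -1).mean(axis=(1, 3))

    def __call__(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = []
        for img in images:
            x = np.asarray(img, dtype=float) / 255.0
            if x.ndim != 3 or x.shape[2] != 3:
                raise ValueError("small-conv encoder expects RGB tiles")
            for k in self.kernels:
                x = self._conv(x, k)
            feats.append(self.proj @ x.mean(axis=(0, 1)))
        return np.asarray(feats)

    def copy(self) -> "SmallConvEncoder":
        return self


def make_encoder(spec: EncoderSpec, in_dim: int | None = None,
                 rng: np.random.Generator | None = None):
    """Instantiate an encoder from a spec; unknown kinds raise ValueError."""
    if spec.kind == "identity":
        return IdentityEncoder()
    if spec.kind == "linear":
        if in_dim is None:
            raise ValueError("linear encoder needs the input dimension")
        return LinearEncoder(in_dim, spec.output_dim, rng)
    if spec.kind == "small-conv":
        return SmallConvEncoder(spec.output_dim or 64, spec.seed)
    raise ValueError(f"unknown encoder kind: {spec.kind!r}")


def encode(patches: Sequence[np.ndarray] | np.ndarray, encoder,
           slide_id: str = "", label: int | None = None) -> Bag:
    """Encode a slide's patches into a Bag, preserving patch order."""
    if len(patches) == 0:
        raise ValueError("cannot encode an empty patch list")
    Z = encoder(patches)
    return Bag(slide_id=slide_id, Z=Z, Y=label)


# ---------------------------------------------------------------------------
# gated-attention MIL head


class GatedAttentionMIL:
    """Per-class gated-attention bag classifier.

    For each class c the instance score is ``w_c . (tanh(V z) * sigmoid(U z))``
    (the gated-attention form), softmaxed over instances into a_i^c; the bag
    feature F_c = sum_i a_i^c z_i feeds a per-class linear logit
    ``u_c . F_c + b_c`` and a final softmax over classes.
    """

    def __init__(self, in_dim: int, n_classes: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.n_classes, self.hidden = in_dim, n_classes, hidden
        s = 1.0 / np.sqrt(in_dim)
        # w and u start at zero: attention begins uniform (the bag feature
        # is the instance mean until the loss demands sharper attention)
        # and the class logits begin at zero, so early optimisation drives
        # them straight along the gradient instead of first unlearning a
        # random projection.  Only the gating nets are randomly initialised.
        self.params = {
            "V": rng.normal(0, s, (hidden, in_dim)),
            "U": rng.normal(0, s, (hidden, in_dim)),
            "w": np.zeros((n_classes, hidden)),
            "u": np.zeros((n_classes, in_dim)),
            "b": np.zeros(n_classes),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def forward(self, Z: np.ndarray, with_cache: bool = False):
        P = self.params
        H = np.tanh(Z @ P["V"].T)                       # (N, hidden)
        G = 1.0 / (1.0 + np.exp(-(Z @ P["U"].T)))       # (N, hidden)
        HG = H * G
        E = HG @ P["w"].T                               # (N, C) attention logits
        E = E - E.max(axis=0, keepdims=True)
        A = np.exp(E)
        A /= A.sum(axis=0, keepdims=True)               # softmax over instances
        F = A.T @ Z                                     # (C, D)
        logits = (P["u"] * F).sum(axis=1) + P["b"]
        logits = logits - logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        if with_cache:
            return probs, A, F, {"H": H, "G": G, "HG": HG}
        return probs, A, F

    def predict(self, Z: np.ndarray) -> BagPrediction:
        probs, A, F = self.forward(Z)
        return BagPrediction(probs=probs, attention=A, bag_features=F)

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, Z: np.ndarray, y: int, weight: float = 1.0):
        """Weighted cross-entropy loss and gradients for one bag."""
        P = self.params
        probs, A, F, cache = self.forward(Z, with_cache=True)
        loss = -weight * np.log(max(probs[y], 1e-300))
        dlogits = weight * probs.copy()
        dlogits[y] -= weight
        grads = {}
        grads["u"] = dlogits[:, None] * F
        grads["b"] = dlogits
        dF = dlogits[:, None] * P["u"]                  # (C, D)
        dA = Z @ dF.T                                   # (N, C)
        dE = A * (dA - (A * dA).sum(axis=0, keepdims=True))
        grads["w"] = dE.T @ cache["HG"]
        dHG = dE @ P["w"]                               # (N, hidden)
        H, G = cache["H"], cache["G"]
        grads["V"] = (dHG * G * (1.0 - H * H)).T @ Z
        grads["U"] = (dHG * H * G * (1.0 - G)).T @ Z
        return loss, grads

    def adam_step(self, grads: dict, lr: float, weight_decay: float = 0.0,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            if weight_decay > 0.0:
                self.params[k] -= lr * weight_decay * self.params[k]

    def copy(self) -> "GatedAttentionMIL":
        return copy.deepcopy(self)


def attention_aggregate(bag: Bag, head: GatedAttentionMIL) -> BagPrediction:
    """Run the gated-attention aggregation and bag classifier on one bag."""
    if bag.n_instances < 1:
        raise ValueError("bag is empty")
    return head.predict(bag.Z)


# ---------------------------------------------------------------------------
# training


@dataclass
class MILModel:
    """Trained MIL head plus its training history."""

    head: GatedAttentionMIL
    history: list = field(default_factory=list)
    best_epoch: int | None = None

    def predict(self, bag: Bag) -> BagPrediction:
        return self.head.predict(bag.Z)


def _accuracy(head: GatedAttentionMIL, bags: Sequence[Bag],
              labels: Sequence[int]) -> float:
    pred = [int(np.argmax(head.forward(b.Z)[0])) for b in bags]
    return float(np.mean(np.asarray(pred) == np.asarray(labels)))


def train_mil(bags: Sequence[Bag], labels: Sequence[int], config: TrainConfig,
              class_weights: np.ndarray | None = None,
              val_bags: Sequence[Bag] | None = None,
              val_labels: Sequence[int] | None = None,
              n_classes: int | None = None,
              hidden: int = 32, n_restarts: int = 1) -> MILModel:
    """Train a gated-attention MIL head by per-bag Adam on cross-entropy.

    Deterministic under ``config.seed``.  With a validation set, keeps the
    weights of the best validation-accuracy epoch (early stop after
    ``config.patience`` epochs without improvement).  ``n_restarts`` > 1
    repeats training from consecutive derived seeds and keeps the run with
    the best validation accuracy (ties keep the earlier run), which guards
    against occasional bad initialisations of the attention branch.
    """
    labels_arr = np.asarray(labels, dtype=int)
    if n_restarts > 1 and val_bags is not None:
        best_model, best_acc = None, -np.inf
        for r in range(n_restarts):
            from dataclasses import replace as _replace
            model = train_mil(bags, labels, _replace(config, seed=config.seed + r),
                              class_weights=class_weights, val_bags=val_bags,
                              val_labels=val_labels, n_classes=n_classes,
                              hidden=hidden, n_restarts=1)
            acc = _accuracy(model.head, val_bags, val_labels)
            if acc > best_acc:
                best_model, best_acc = model, acc
        return best_model
    labels = labels_arr
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("train_mil needs at least 2 classes in the labels")
    C = n_classes if n_classes is not None else int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)
    head = GatedAttentionMIL(bags[0].Z.shape[1], C, hidden=hidden, rng=rng)
    weights = np.ones(C) if class_weights is None else np.asarray(class_weights, float)

    best = None
    best_acc, best_epoch, since = -np.inf, None, 0
    history = []
    for epoch in range(config.epochs):
        lr = config.mil_lr * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(len(bags))
        total = 0.0
        for i in order:
            loss, grads = head.loss_and_grads(bags[i].Z, int(labels[i]),
                                              weight=float(weights[labels[i]]))
            head.adam_step(grads, lr, weight_decay=config.weight_decay)
            total += loss
        rec = {"epoch": epoch, "loss": total / len(bags), "lr": lr}
        if val_bags is not None:
            acc = _accuracy(head, val_bags, val_labels)
            rec["val_acc"] = acc
            # >= keeps the latest epoch among ties: equal validation accuracy
            # at a later epoch means a more converged model
            if acc >= best_acc:
                since = 0 if acc > best_acc else since + 1
                best_acc, best_epoch = acc, epoch
                best = head.copy()
            else:
                since += 1
        history.append(rec)
        if val_bags is not None and since >= config.patience:
            break
    if best is not None:
        head = best
    return MILModel(head=head, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             scores: np.ndarray | None = None,
             n_classes: int | None = None) -> dict:
    """Confusion matrix, accuracy and macro one-vs-rest metrics.

    Per class c: TP/FP/TN/FN from the one-vs-rest reduction give
    Acc = (TP+TN)/(TP+FP+TN+FN), Precision = TP/(TP+FP),
    Recall = TP/(TP+FN), F1 = 2*P*R/(P+R); macro values average over the
    classes present in the truth (absent classes are excluded with a
    warning).  ``scores`` (row-normalised, shape (n, C)) adds macro
    one-vs-rest ROC AUC.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    C = n_classes if n_classes is not None else int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((C, C), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)

    present = np.flatnonzero(cm.sum(axis=1) > 0)
    absent = [c for c in range(C) if c not in present]
    if absent:
        warnings.warn(f"classes absent from truth excluded from macro averages: {absent}")

    n = len(y_true)
    prec, rec, f1 = [], [], []
    for c in present:
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if p + r > 0 else 0.0)

    out = {
        "confusion": cm,
        "accuracy": float(np.trace(cm) / n),
        "macro_precision": float(np.mean(prec)),
        "macro_recall": float(np.mean(rec)),
        "macro_f1": float(np.mean(f1)),
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        aucs = []
        for c in present:
            truth_c = (y_true == c).astype(int)
            if truth_c.min() == truth_c.max():
                continue
            aucs.append(roc_auc_score(truth_c, scores[:, c]))
        out["macro_auc"] = float(np.mean(aucs)) if aucs else float("nan")
    return out
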