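"""Pseudo-label-driven encoder refinement.

Patches are initially unlabeled.  Each refinement round scores every patch
of a slide by confidence s = a * p — the product of the patch's attention
for the slide's class (from the current best MIL head) and its class score
(from the current best patch classifier; taken as 1 in the bootstrap round
before a patch classifier exists).  The top-k patches per slide are
pseudo-labeled with the slide class, the bottom-k with the background
class C+1; the auxiliary patch classifier is trained on these labels with
its backbone shared with the MIL encoder, the bag features are re-extracted
with the updated encoder, and a fresh MIL head is trained.  The "current
best" bundle is the one with the highest validation bag accuracy seen so
far (ties keep the earlier round).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mil import (Bag, GatedAttentionMIL, IdentityEncoder, LinearEncoder,
                  MILModel, TrainConfig, _accuracy, train_mil)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceRecord", "PseudoLabelSet", "patch_confidence",
    "select_pseudo_labels", "PatchClassifier", "train_patch_classifier",
    "refine_loop", "RefineResult", "default_k",
    "fit_patch_classifier_from_bundle",
]


def patch_confidence(attention: float, patch_score: float) -> float:
    """Confidence s = a * p; both factors must lie in [0, 1]."""
    if not (0.0 <= attention <= 1.0) or not (0.0 <= patch_score <= 1.0):
        raise ValueError("attention and patch score must lie in [0, 1]")
    return attention * patch_score


@dataclass
class ConfidenceRecord:
    """Per-patch confidence for the slide's category c: s = a^c * p^c."""

    patch_id: object
    category: int
    attention: float
    patch_score: float
    confidence: float = field(init=False)

    def __post_init__(self) -> None:
        self.confidence = patch_confidence(self.attention, self.patch_score)


@dataclass
class PseudoLabelSet:
    """Top-k patches labeled with the slide class, bottom-k with background."""

    positives: list
    negatives: list
    k: int
    positive_label: int
    background_label: int

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives must be disjoint")
        if len(self.positives) != self.k or len(self.negatives) != self.k:
            raise ValueError("each side must contain exactly k patches")


def default_k(n_instances: int) -> int:
    """Scale-free default: 10% of the bag, at least one patch."""
    return max(1, math.ceil(0.1 * n_instances))


def select_pseudo_labels(confidences: list[ConfidenceRecord], slide_class: int,
                         k: int, background_label: int | None = None) -> PseudoLabelSet:
    """Assign the top-k/bottom-k pseudo-labels of one slide.

    Records are sorted by descending confidence, ties broken by ascending
    patch id; the first k become positives (slide class), the last k
    negatives (background).  If 2k > N, k shrinks to floor(N/2) with a
    logged warning; a slide too small to yield both sides is an error.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if any(r.category != slide_class for r in confidences):
        raise ValueError("confidences must all be for the slide's category")
    n = len(confidences)
    if k > n // 2:
        logger.warning("k=%d too large for N=%d; shrinking to %d", k, n, n // 2)
        k = n // 2
    if k == 0:
        raise ValueError("slide has too few patches for pseudo-labeling")
    ordered = sorted(confidences, key=lambda r: (-r.confidence, r.patch_id))
    if background_label is None:
        background_label = slide_class + 1
    return PseudoLabelSet(
        positives=[r.patch_id for r in ordered[:k]],
        negatives=[r.patch_id for r in ordered[-k:]],
        k=k, positive_label=slide_class, background_label=background_label)


# ---------------------------------------------------------------------------
# auxiliary patch classifier (backbone shared with the MIL encoder)


class PatchClassifier:
    """Softmax patch classifier over {1..C+1} on top of the shared encoder.

    The encoder object is held by reference: training here updates the same
    weights the MIL pipeline uses to extract bag features.
    """

    def __init__(self, encoder, n_classes: int, in_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        out_dim = encoder.W.shape[0] if isinstance(encoder, LinearEncoder) else in_dim
        self.encoder = encoder
        self.n_classes = n_classes
        # zero head init: with the small fine-tuning learning rate the head
        # moves little in absolute terms, so the argmax must be decided by
        # accumulated gradient direction, not by random initialisation
        self.W = np.zeros((n_classes, out_dim))
        self.b = np.zeros(n_classes)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.encoder(np.asarray(X, dtype=float))
        logits = Z @ self.W.T + self.b
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax takes the first maximum: ties resolve to the lower class
        return np.argmax(self.predict_proba(X), axis=1)

    def copy(self) -> "PatchClassifier":
        return copy.deepcopy(self)


def train_patch_classifier(X: np.ndarray, y: np.ndarray, n_classes: int,
                           encoder, config: TrainConfig,
                           rng: np.random.Generator | None = None) -> PatchClassifier:
    """Train the patch classifier (and, through sharing, the encoder).

    Minibatch Adam on cross-entropy at the patch batch size / learning rate,
    decaying by ``lr_decay`` every ``lr_decay_every`` epochs.  Requires at
    least two distinct pseudo-label classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("pseudo-label set must contain at least 2 classes")
    rng = rng or np.random.default_rng(config.seed)
    clf = PatchClassifier(encoder, n_classes, X.shape[1], rng)
    train_enc = getattr(encoder, "trainable", False)
    # the background class holds half of all pseudo-labels (bottom-k of every
    # slide); inverse-frequency weights keep it from dominating the head
    freq = np.bincount(y, minlength=n_classes).astype(float)
    present = freq > 0
    cls_w = np.zeros(n_classes)
    cls_w[present] = freq[present].sum() / (present.sum() * freq[present])

    params = {"W": clf.W, "b": clf.b}
    if train_enc:
        params["eW"] = encoder.W
        params["eb"] = encoder.b
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = X.shape[0]
    for epoch in range(config.patch_epochs):
        lr = config.patch_lr * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        for start in range(0, n, config.patch_batch_size):
            idx = order[start:start + config.patch_batch_size]
            Xb, yb = X[idx], y[idx]
            Z = encoder(Xb)
            logits = Z @ clf.W.T + clf.b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            d = p.copy()
            d[np.arange(len(yb)), yb] -= 1.0
            d *= cls_w[yb, None] / len(yb)
            grads = {"W": d.T @ Z, "b": d.sum(axis=0)}
            if train_enc:
                dZ = d @ clf.W
                grads["eW"] = dZ.T @ Xb
                grads["eb"] = dZ.sum(axis=0)
            t += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                params[k] -= lr * (m[k] / (1 - beta1 ** t)) / (
                    np.sqrt(v[k] / (1 - beta2 ** t)) + eps)
    return clf


# ---------------------------------------------------------------------------
# alternating refinement loop


@dataclass
class RefineResult:
    """Best bundle out of the refinement loop, plus the per-round log."""

    encoder: object
    mil: MILModel
    patch_classifier: PatchClassifier | None
    history: list
    best_round: int

    def encode_bag(self, bag: Bag) -> np.ndarray:
        return self.encoder(bag.Z)

    def predict(self, bag: Bag):
        return self.mil.head.predict(self.encode_bag(bag))


def _encode_bags(encoder, bags):
    return [Bag(b.slide_id, encoder(b.Z), b.Y) for b in bags]


def refine_loop(train_bags, train_labels, val_bags, val_labels,
                config: TrainConfig, n_rounds: int = 3, k: int | None = None,
                class_weights=None, encoder=None, n_classes: int | None = None,
                patience_rounds: int = 1, hidden: int = 32,
                n_restarts: int = 1) -> RefineResult:
    """Alternate MIL-head training with pseudo-label encoder refinement.

    Round 0 trains a MIL head on the initial encoding (with a frozen
    encoder this is the whole loop: refinement's only lever is the encoder,
    so the procedure degenerates to plain MIL training).  Each later round
    (1) scores per-slide confidences with the current best head and patch
    classifier, (2) selects top-k/bottom-k pseudo-labels, regenerated from
    scratch, (3) trains the shared-backbone patch classifier, (4)
    re-extracts bag features and trains a fresh head, (5) keeps the bundle
    if validation accuracy improved (ties keep the earlier round).  Stops
    early after ``patience_rounds`` rounds without improvement.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    train_labels = [int(y) for y in train_labels]
    val_labels = [int(y) for y in val_labels]
    C = n_classes if n_classes is not None else max(train_labels) + 1
    in_dim = train_bags[0].Z.shape[1]
    if encoder is None:
        encoder = LinearEncoder(in_dim)

    def fit_head(enc, seed):
        cfg = replace(config, seed=seed)
        enc_train = _encode_bags(enc, train_bags)
        enc_val = _encode_bags(enc, val_bags)
        model = train_mil(enc_train, train_labels, cfg,
                          class_weights=class_weights, val_bags=enc_val,
                          val_labels=val_labels, n_classes=C, hidden=hidden,
                          n_restarts=n_restarts)
        acc = _accuracy(model.head, enc_val, val_labels)
        return model, acc

    seeds = np.random.SeedSequence(config.seed).generate_state(2 * n_rounds + 2)
    seeds = [int(s % (2 ** 31)) for s in seeds]

    enc0 = encoder.copy() if encoder.trainable else encoder
    model0, acc0 = fit_head(enc0, config.seed)
    history = [{"round": 0, "val_acc": acc0}]
    best = RefineResult(encoder=enc0, mil=model0, patch_classifier=None,
                        history=history, best_round=0)
    best_acc = acc0
    if not encoder.trainable:
        return best

    since = 0
    for r in range(1, n_rounds + 1):
        rng = np.random.default_rng(seeds[2 * r])
        X_rows, y_rows = [], []
        for bag, y in zip(train_bags, train_labels):
            Zenc = best.encoder(bag.Z)
            _, A, _ = best.mil.head.forward(Zenc)
            att = A[:, y]
            if best.patch_classifier is not None:
                score = best.patch_classifier.predict_proba(bag.Z)[:, y]
            else:
                score = np.ones(bag.n_instances)
            recs = [ConfidenceRecord(patch_id=i, category=y,
                                     attention=float(att[i]),
                                     patch_score=float(score[i]))
                    for i in range(bag.n_instances)]
            kk = k if k is not None else default_k(bag.n_instances)
            pls = select_pseudo_labels(recs, y, kk, background_label=C)
            for pid in pls.positives:
                X_rows.append(bag.Z[pid])
                y_rows.append(y)
            for pid in pls.negatives:
                X_rows.append(bag.Z[pid])
                y_rows.append(C)
        enc_new = best.encoder.copy()
        clf = train_patch_classifier(np.asarray(X_rows), np.asarray(y_rows),
                                     C + 1, enc_new, config, rng)
        model_r, acc_r = fit_head(enc_new, seeds[2 * r + 1])
        history.append({"round": r, "val_acc": acc_r})
        if acc_r > best_acc:
            best = RefineResult(encoder=enc_new, mil=model_r,
                                patch_classifier=clf, history=history,
                                best_round=r)
            best_acc = acc_r
            since = 0
        else:
            since += 1
            if since >= patience_rounds:
                break
    best.history = history
    return best


def fit_patch_classifier_from_bundle(bundle: RefineResult, bags, labels,
                                     config: TrainConfig, n_classes: int,
                                     k: int | None = None, n_iters: int = 2,
                                     seed: int | None = None) -> PatchClassifier:
    """Train a standalone auxiliary patch classifier from a fitted bundle.

    Intended for producing per-patch class maps (heatmaps) after bag-level
    training.  Pseudo-labels are regenerated ``n_iters`` times and scored
    by the full confidence s = a * p.  Before a patch classifier exists,
    the patch score is bootstrapped from the MIL head itself evaluated on
    each patch as a singleton bag (whose attention is exactly 1, so the
    bag probabilities reduce to the head's linear classifier on that
    patch's feature) — attention alone is uninformative when the bag task
    is solved with near-uniform attention.  The default k here is
    ceil(0.3 N) — wider than the 10% used for encoder refinement —
    because a patch classifier needs boundary coverage, not just the
    purest extremes.  A final self-labeling pass relaxes the labels by
    nearest-centroid reassignment over all patches and refits, which
    moves decision boundaries from the confident extremes toward the
    class midpoints.  The bundle's encoder is copied, never mutated.
    """
    base_seed = config.seed if seed is None else seed
    clf = bundle.patch_classifier
    for it in range(n_iters):
        X_rows, y_rows = [], []
        for bag, y in zip(bags, labels):
            y = int(y)
            Zenc = bundle.encoder(bag.Z)
            _, A, _ = bundle.mil.head.forward(Zenc)
            att = A[:, y]
            if clf is None:
                # singleton-bag evaluation of the MIL head per patch
                score = np.array([bundle.mil.head.forward(z[None, :])[0][y]
                                  for z in Zenc])
            else:
                score = clf.predict_proba(bag.Z)[:, y]
            recs = [ConfidenceRecord(patch_id=i, category=y,
                                     attention=float(att[i]),
                                     patch_score=float(score[i]))
                    for i in range(bag.n_instances)]
            kk = k if k is not None else max(1, math.ceil(0.3 * bag.n_instances))
            pls = select_pseudo_labels(recs, y, kk, background_label=n_classes)
            for pid in pls.positives:
                X_rows.append(bag.Z[pid])
                y_rows.append(y)
            for pid in pls.negatives:
                X_rows.append(bag.Z[pid])
                y_rows.append(n_classes)
        rng = np.random.default_rng(base_seed + it)
        enc = bundle.encoder.copy() if bundle.encoder.trainable else bundle.encoder
        clf = train_patch_classifier(np.asarray(X_rows), np.asarray(y_rows),
                                     n_classes + 1, enc, config, rng)
    # Self-labeling refinement over all patches: the extremes-trained head
    # has systematically offset boundaries (its positives oversample
    # class-looking patches), so labels are relaxed by a few nearest-centroid
    # EM iterations in the raw feature space — the maximum-likelihood
    # assignment under isotropic class-conditional features — and the head
    # is refit on the relaxed labels with a convergence-level step budget.
    X_all = np.vstack([bag.Z for bag in bags])
    y_all = clf.predict(X_all)
    for _ in range(3):
        if np.unique(y_all).size < 2:
            break
        cents = np.vstack([
            X_all[y_all == c].mean(axis=0) if np.any(y_all == c)
            else np.full(X_all.shape[1], np.inf)
            for c in range(n_classes + 1)])
        d2 = ((X_all[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        y_all = d2.argmin(axis=1)
    if np.unique(y_all).size >= 2:
        steps_per_epoch = max(1, math.ceil(len(y_all) / config.patch_batch_size))
        epochs = math.ceil(30000 / steps_per_epoch)
        final_cfg = replace(config, patch_epochs=epochs,
                            lr_decay_every=max(1, epochs // 2))
        rng = np.random.default_rng(base_seed + n_iters)
        enc = bundle.encoder.copy() if bundle.encoder.trainable else bundle.encoder
        clf = train_patch_classifier(X_all, y_all, n_classes + 1, enc,
                                     final_cfg, rng)
    return clf
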