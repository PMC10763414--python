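"""Joint backbone classifier + loss prediction module (LPM).

The LPM is an auxiliary head that learns, during ordinary supervised training,
to predict each example's training loss from the backbone's intermediate
features.  Backbone and LPM are trained simultaneously on a joint objective

    L = L_target(y_hat, y) + lambda * L_loss(l_hat, l)

where ``L_target`` is mean cross-entropy and ``L_loss`` is a pairwise
margin-ranking hinge over the batch: consecutive examples are paired, and for
a pair (i, j) the hinge

    max(0, -sign(l_i - l_j) * (l_hat_i - l_hat_j) + epsilon)

is zero exactly when the predicted losses are ordered like the true losses
with a gap of at least ``epsilon``.  The true losses enter only as ranking
targets (no gradient flows through them); the predicted losses backpropagate
through the LPM head into the backbone.

The desk-scale backbone is a four-stage fully connected network on top of a
fixed feature stem that average-pools the patch into an 8x8 grid and keeps,
per cell, the mean colour and the local colour contrast (within-cell standard
deviation).  The contrast channels preserve the high-frequency information a
convolutional front end would see, which is what distinguishes defocused or
occluded patches from sharp tissue.  One LPM tap per backbone stage follows
the usual pattern: FC to a common width, ReLU, concatenate all taps, final FC
to a scalar, with a softplus keeping the predicted loss non-negative and
loss-like.  The ranking hinge constrains only differences between predicted
losses, so without the softplus the l_hat scale is a free random walk and the
per-class thresholds built from l_hat lose their meaning (alpha > 1 must
loosen the gate, which requires a non-negative base value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, log_softmax, softmax

__all__ = [
    "TrainConfig",
    "JointModel",
    "TrainingTrace",
    "BatchRecord",
    "NotTrainedError",
    "margin_ranking_loss",
    "joint_loss",
    "train_joint",
    "predict_losses",
]


class NotTrainedError(RuntimeError):
    """Prediction requested from a model that has not been trained."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for one from-scratch fit.

    Defaults follow the method's protocol: SGD, batch 32, 50 epochs,
    learning rate 0.001; momentum 0.5; lambda = epsilon = 1.0.
    """

    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    momentum: float = 0.5
    lam: float = 1.0
    epsilon: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (ranking loss pairs examples)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


# ---------------------------------------------------------------------------
# losses


def margin_ranking_loss(
    true_losses: np.ndarray, predicted_losses: np.ndarray, epsilon: float = 1.0
) -> float:
    """Mean pairwise margin-ranking hinge over consecutive pairs (1,2),(3,4),...

    Zero iff, in every pair, the predicted-loss difference has the sign of the
    true-loss difference and magnitude >= ``epsilon``.
    """
    l = np.asarray(true_losses, dtype=float)
    lh = np.asarray(predicted_losses, dtype=float)
    if l.shape != lh.shape or l.ndim != 1:
        raise ValueError("true and predicted losses must be equal-length vectors")
    if l.size % 2 != 0:
        raise ValueError("batch size must be even to form pairs")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    li, lj = l[0::2], l[1::2]
    hi, hj = lh[0::2], lh[1::2]
    sign = np.where(li > lj, 1.0, -1.0)
    return float(np.mean(np.maximum(0.0, -sign * (hi - hj) + epsilon)))


def joint_loss(target_losses: np.ndarray, ranking_loss: float, lam: float = 1.0) -> float:
    """Mean target loss plus ``lam`` times the LPM ranking loss."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return float(np.mean(np.asarray(target_losses, dtype=float)) + lam * ranking_loss)


# ---------------------------------------------------------------------------
# model


def _featurize(images: np.ndarray, cell: int = 4) -> np.ndarray:
    """Fixed stem: per-cell mean colour (centred) and colour contrast.

    images: (B, H, W, 3) in [0, 1]; H == W, divisible by ``cell``.
    Returns (B, (H/cell)^2 * 6) float32 (single precision keeps the desk-scale
    training loop fast on one CPU).
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    b, h, w, c = x.shape
    if h != w or h % cell != 0:
        raise ValueError(f"patch size {h}x{w} not divisible into {cell}x{cell} cells")
    g = h // cell
    x = x.reshape(b, g, cell, g, cell, c)
    mean = x.mean(axis=(2, 4))
    std = x.std(axis=(2, 4))
    feats = np.concatenate([mean - 0.5, std], axis=-1)
    return feats.reshape(b, -1)


class JointModel:
    """Backbone classifier with an attached loss-prediction head.

    ``forward`` maps a batch of images to per-class scores and a scalar
    predicted loss per image.  All parameters live in ``self.params`` as plain
    numpy arrays; gradients are computed by hand in :meth:`_loss_and_grads`.
    """

    STAGE_WIDTHS = (128, 64, 64, 32)
    LPM_WIDTH = 128

    def __init__(
        self,
        n_classes: int = 3,
        patch_size: int = 32,
        stem_cell: int = 4,
        seed: int = 0,
        lam: float = 1.0,
        epsilon: float = 1.0,
    ):
        self.n_classes = n_classes
        self.patch_size = patch_size
        self.stem_cell = stem_cell
        self.lam = lam
        self.epsilon = epsilon
        self.trained = False
        d_in = (patch_size // stem_cell) ** 2 * 6
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10DE1]))
        self.params: dict[str, np.ndarray] = {}

        def he(name, d0, d1):
            w = rng.normal(0.0, np.sqrt(2.0 / d0), size=(d0, d1))
            self.params[f"W{name}"] = w.astype(np.float32)
            self.params[f"b{name}"] = np.zeros(d1, dtype=np.float32)

        dims = (d_in,) + self.STAGE_WIDTHS
        for k in range(4):
            he(f"s{k}", dims[k], dims[k + 1])
            he(f"t{k}", dims[k + 1], self.LPM_WIDTH)  # LPM tap per stage
        he("cls", dims[-1], n_classes)
        he("lpm", 4 * self.LPM_WIDTH, 1)

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        images: np.ndarray,
        *,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Return (logits, predicted_losses, cache) for a batch of images."""
        p = self.params
        h = _featurize(images, self.stem_cell)
        cache = {"h": [h], "a": []}
        for k in range(4):
            a = h @ p[f"Ws{k}"] + p[f"bs{k}"]
            h = np.maximum(a, 0.0)
            cache["a"].append(a)
            cache["h"].append(h)
        h_cls = h
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            mask = (rng.uniform(size=h.shape) >= dropout) / (1.0 - dropout)
            h_cls = h * mask
        logits = h_cls @ p["Wcls"] + p["bcls"]
        taps, tap_pre = [], []
        for k in range(4):
            at = cache["h"][k + 1] @ p[f"Wt{k}"] + p[f"bt{k}"]
            tap_pre.append(at)
            taps.append(np.maximum(at, 0.0))
        u = np.concatenate(taps, axis=1)
        lhat_pre = (u @ p["Wlpm"] + p["blpm"]).ravel().astype(np.float64)
        lhat = np.logaddexp(0.0, lhat_pre)  # softplus: non-negative, loss-like
        cache.update(
            {"tap_pre": tap_pre, "u": u, "logits": logits,
             "lhat_pre": lhat_pre, "lhat": lhat}
        )
        return logits, lhat, cache

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate backbone activations (core-set embedding space)."""
        _, _, cache = self.forward(images)
        return cache["h"][-1]

    def predict_proba(self, images: np.ndarray, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch):
            logits, _, _ = self.forward(images[i : i + batch])
            out.append(softmax(logits, axis=1))
        return np.concatenate(out)

    def stochastic_proba(
        self, images: np.ndarray, passes: int, rng: np.random.Generator, p_drop: float = 0.5
    ) -> np.ndarray:
        """(passes, B, C) softmax outputs with head dropout active (for BALD)."""
        if passes < 2:
            raise ValueError("at least 2 stochastic passes are required")
        out = []
        for _ in range(passes):
            logits, _, _ = self.forward(images, dropout=p_drop, rng=rng)
            out.append(softmax(logits, axis=1))
        return np.stack(out)

    # -- backward -----------------------------------------------------------

    def _loss_and_grads(self, images: np.ndarray, y: np.ndarray):
        """Joint loss, per-example CE losses, predictions, and param grads."""
        p = self.params
        dtype = p["Wcls"].dtype  # grads follow the parameter precision
        logits, lhat, cache = self.forward(images)
        b = len(y)
        logp = log_softmax(logits.astype(np.float64), axis=1)
        ce = -logp[np.arange(b), y]  # per-example true loss (ranking target)
        probs = np.exp(logp)
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits = (dlogits / b).astype(dtype)

        # ranking loss on the even-length prefix; odd tail joins CE only
        n_pair = (b // 2) * 2
        dlhat = np.zeros(b)
        rank = 0.0
        if n_pair >= 2 and self.lam > 0.0:
            li, lj = ce[0:n_pair:2], ce[1:n_pair:2]
            hi, hj = lhat[0:n_pair:2], lhat[1:n_pair:2]
            sign = np.where(li > lj, 1.0, -1.0)
            hinge = -sign * (hi - hj) + self.epsilon
            active = hinge > 0.0
            rank = float(np.mean(np.maximum(hinge, 0.0)))
            scale = self.lam / (n_pair / 2)
            dlhat[0:n_pair:2] = np.where(active, -sign, 0.0) * scale
            dlhat[1:n_pair:2] = np.where(active, sign, 0.0) * scale
        elif n_pair >= 2:
            rank = margin_ranking_loss(ce[:n_pair], lhat[:n_pair], self.epsilon)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        hs = cache["h"]
        dh = [np.zeros_like(h) for h in hs]

        # LPM head (through the softplus)
        dlhat_pre = (dlhat * expit(cache["lhat_pre"])).astype(dtype)
        u = cache["u"]
        grads["Wlpm"] = u.T @ dlhat_pre[:, None]
        grads["blpm"] = np.array([dlhat_pre.sum()], dtype=dtype)
        du = dlhat_pre[:, None] * p["Wlpm"].T  # (B, 4*width)
        w = self.LPM_WIDTH
        for k in range(4):
            da = du[:, k * w : (k + 1) * w] * (cache["tap_pre"][k] > 0.0)
            grads[f"Wt{k}"] = hs[k + 1].T @ da
            grads[f"bt{k}"] = da.sum(axis=0)
            dh[k + 1] += da @ p[f"Wt{k}"].T

        # classifier head
        grads["Wcls"] = hs[-1].T @ dlogits
        grads["bcls"] = dlogits.sum(axis=0)
        dh[-1] += dlogits @ p["Wcls"].T

        # backbone
        for k in range(3, -1, -1):
            da = dh[k + 1] * (cache["a"][k] > 0.0)
            grads[f"Ws{k}"] = hs[k].T @ da
            grads[f"bs{k}"] = da.sum(axis=0)
            dh[k] += da @ p[f"Ws{k}"].T

        total = float(ce.mean() + self.lam * rank)
        pred = np.argmax(logits, axis=1)
        return total, ce, lhat, pred, rank, grads


# ---------------------------------------------------------------------------
# training trace


@dataclass(frozen=True)
class BatchRecord:
    """Everything the threshold collector needs from one training batch."""

    epoch: int
    true_losses: np.ndarray
    predicted_losses: np.ndarray
    labels: np.ndarray
    predicted: np.ndarray

    @property
    def correct(self) -> np.ndarray:
        return self.labels == self.predicted


@dataclass
class TrainingTrace:
    """Per-batch training records across all epochs of one fit."""

    n_epochs: int
    batch_size: int
    n_classes: int
    records: list[BatchRecord] = field(default_factory=list)

    def epoch_records(self, epoch: int) -> list[BatchRecord]:
        return [r for r in self.records if r.epoch == epoch]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(
                    json.dumps(
                        {
                            "epoch": r.epoch,
                            "true_losses": r.true_losses.round(6).tolist(),
                            "predicted_losses": r.predicted_losses.round(6).tolist(),
                            "labels": r.labels.tolist(),
                            "predicted": r.predicted.tolist(),
                        }
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# training / inference


def train_joint(
    model: JointModel, images: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> tuple[JointModel, TrainingTrace]:
    """Train ``model`` in place with SGD on the joint objective.

    Examples are reshuffled every epoch; an odd-sized final batch contributes
    to the cross-entropy term but is excluded from the pairwise ranking term.
    Fixed seed implies a bit-reproducible trace.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("labeled set is empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7A311]))
    model.lam = config.lam
    model.epsilon = config.epsilon
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    trace = TrainingTrace(config.epochs, config.batch_size, model.n_classes)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, ce, lhat, pred, _, grads = model._loss_and_grads(images[idx], labels[idx])
            for k, g in grads.items():
                velocity[k] = config.momentum * velocity[k] + g
                model.params[k] -= config.lr * velocity[k]
            trace.records.append(
                BatchRecord(epoch, ce.copy(), lhat.copy(), labels[idx].copy(), pred.copy())
            )
    model.trained = True
    return model, trace


def predict_losses(
    model: JointModel, images: np.ndarray, batch: int = 512, require_trained: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic eval-mode pass: (predicted classes, predicted losses)."""
    if require_trained and not model.trained:
        raise NotTrainedError("model has not been trained; call train_joint first")
    classes, losses = [], []
    for i in range(0, len(images), batch):
        logits, lhat, _ = model.forward(images[i : i + batch])
        classes.append(np.argmax(logits, axis=1))
        losses.append(lhat)
    return np.concatenate(classes), np.concatenate(losses)
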