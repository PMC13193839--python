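"""The sequential hybrid classifier: CNN backbone -> BiGRU head -> softmax.

The backbone collapses a 224x224x3 input into a pooled feature vector which a
linear projection widens (or narrows) to ``feature_dim``.  That vector is
treated as a one-step sequence and passed through two stacked bidirectional
GRU layers whose gates act as a learned feature-reweighting mechanism (not
temporal modeling), then through two ReLU dense layers with dropout, and
finally a 3-way softmax.  At the default configuration the head widths along
the forward pass are 1024 -> 512 -> 256 -> 256 -> 128 -> 3.

The training protocol is Adam + categorical cross-entropy with a batch size
of 32, at most 30 epochs, and early stopping that monitors the held-out loss
with patience 5 and restores the best-epoch weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import AugmentConfig, Augmenter
from .errors import ConfigurationError, ValidationError
from .image_core import BACKBONE_SIZE, to_backbone_input
from .manifest import CLASS_NAMES, decode_labels, encode_labels

#: Channel widths of the three conv blocks per backbone variant.
_BACKBONES = {
    "tiny_cnn": (16, 32, 64),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the hybrid classifier."""

    backbone: str = "tiny_cnn"
    #: off = ablation variant: the two BiGRU layers are replaced by plain
    #: ReLU dense layers of matched output widths (2*g1, 2*g2)
    use_bigru_head: bool = True
    feature_dim: int = 1024
    gru_units: tuple[int, int] = (256, 128)
    gru_dropout: float = 0.3
    gru_recurrent_dropout: float = 0.3
    dense_units: tuple[int, int] = (256, 128)
    head_dropout: tuple[float, float] = (0.5, 0.3)
    n_classes: int = 3
    input_size: int = BACKBONE_SIZE

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone!r}; available: {sorted(_BACKBONES)}"
            )
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")

    @property
    def head_widths(self) -> tuple[int, ...]:
        """Layer output widths along the head's forward pass."""
        return (
            self.feature_dim,
            2 * self.gru_units[0],
            2 * self.gru_units[1],
            self.dense_units[0],
            self.dense_units[1],
            self.n_classes,
        )

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration: same topology, small widths."""
        defaults = dict(feature_dim=64, gru_units=(16, 8), dense_units=(32, 16))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (Adam, cross-entropy, early stopping)."""

    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    restore_best: bool = True
    freeze_policy: str = "all_but_last_block"  # or "none"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not self.patience < self.max_epochs:
            raise ValidationError("patience must be smaller than max_epochs")
        if self.freeze_policy not in ("all_but_last_block", "none"):
            raise ConfigurationError(f"unknown freeze policy {self.freeze_policy!r}")


@dataclass
class TrainHistory:
    """Per-epoch record of one training run (epochs are 1-based)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_loss": self.val_loss,
            "val_acc": self.val_acc,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }


class EarlyStopping:
    """Patience-based stopping on a monitored loss, with best-epoch tracking.

    ``update(epoch, loss)`` returns True when training should stop: the loss
    has failed to improve for ``patience`` consecutive epochs.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class HybridModel:
    """Built network plus the bookkeeping needed for training and inference."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng([seed, 0x1C4])
        widths = _BACKBONES[config.backbone]
        # max-pool downsampling at the front: the lesions of interest are a
        # handful of bright pixels after masking, and averaging them away at
        # the input would blind the network to the smallest class
        layers: list[nn.Layer] = [nn.MaxPool2(), nn.MaxPool2()]
        in_ch = 3
        block_slices = []
        for w in widths:
            start = len(layers)
            layers += [nn.Conv2D(in_ch, w, rng=rng), nn.BatchNorm2D(w), nn.ReLU(), nn.MaxPool2()]
            block_slices.append((start, len(layers)))
            in_ch = w
        layers.append(nn.GlobalAvgMaxPool())
        layers.append(nn.BatchNorm(2 * widths[-1]))
        layers.append(nn.Dense(2 * widths[-1], config.feature_dim, rng=rng))
        self._backbone_end = len(layers)
        self._block_slices = block_slices
        g1, g2 = config.gru_units
        d1, d2 = config.dense_units
        p1, p2 = config.head_dropout
        if config.use_bigru_head:
            layers += [
                nn.BiGRU(config.feature_dim, g1, dropout=config.gru_dropout,
                         recurrent_dropout=config.gru_recurrent_dropout, rng=rng),
                nn.BiGRU(2 * g1, g2, dropout=config.gru_dropout,
                         recurrent_dropout=config.gru_recurrent_dropout, rng=rng),
            ]
        else:
            # dense-head ablation: matched widths so parameter scale is comparable
            layers += [
                nn.Dense(config.feature_dim, 2 * g1, rng=rng),
                nn.ReLU(),
                nn.Dense(2 * g1, 2 * g2, rng=rng),
                nn.ReLU(),
            ]
        layers += [
            nn.Dense(2 * g2, d1, rng=rng),
            nn.ReLU(),
            nn.Dropout(p1, rng=rng),
            nn.Dense(d1, d2, rng=rng),
            nn.ReLU(),
            nn.Dropout(p2, rng=rng),
            nn.Dense(d2, config.n_classes, rng=rng),
        ]
        self.net = nn.Sequential(layers)

    # -- freeze policy -----------------------------------------------------
    def apply_freeze_policy(self, policy: str) -> None:
        """Freeze all backbone conv blocks except the last one ("all_but_last_block"),
        or unfreeze everything ("none").  The pooled projection stays trainable."""
        for layer in self.net.layers:
            layer.frozen = False
        if policy == "all_but_last_block":
            for start, stop in self._block_slices[:-1]:
                for layer in self.net.layers[start:stop]:
                    layer.frozen = True

    # -- inference ---------------------------------------------------------
    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        s = self.config.input_size
        if batch.ndim != 4 or batch.shape[1:] != (s, s, 3):
            raise ValidationError(
                f"expected batch shape (n, {s}, {s}, 3), got {batch.shape}"
            )
        if batch.dtype == np.uint8:
            batch = batch.astype(nn.DTYPE) / 255.0
        return batch.astype(nn.DTYPE)

    def forward_logits(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._check_batch(batch), training=training)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) in the fixed class order."""
        return nn.softmax(self.forward_logits(batch, training=False))

    def extract_features(self, batch: np.ndarray) -> np.ndarray:
        """Pooled-and-projected feature matrix, one row of ``feature_dim`` per image."""
        x = self._check_batch(batch)
        for layer in self.net.layers[: self._backbone_end]:
            x = layer.forward(x, training=False)
        return x

    # -- checkpointing -----------------------------------------------------
    def save_weights(self, path) -> None:
        """Write all weights (including batch-norm running stats) as .npz."""
        flat = {f"{li}/{name}": p for (li, name), p in self.net.get_weights().items()}
        np.savez(path, **flat)

    def load_weights(self, path) -> None:
        """Restore weights saved by :meth:`save_weights` into this network."""
        with np.load(path) as data:
            weights = {}
            for key in data.files:
                li, name = key.split("/", 1)
                weights[(int(li), name)] = data[key]
        self.net.set_weights(weights)


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> HybridModel:
    """Construct the hybrid network with seeded initialization."""
    return HybridModel(config, seed=seed)


def _prepare_inputs(images, size: int) -> np.ndarray:
    """Gray images -> float32 batch (n, size, size, 3) scaled to [0,1]."""
    batch = np.stack([to_backbone_input(img) for img in images])
    if size != batch.shape[1]:
        raise ValidationError(f"model expects {size}x{size} inputs")
    return batch.astype(nn.DTYPE) / 255.0


def predict(model: HybridModel, images) -> tuple[np.ndarray, list[str]]:
    """Probabilities and argmax labels for a stream of gray images."""
    batch = _prepare_inputs(list(images), model.config.input_size)
    probs = model.predict_proba(batch)
    return probs, decode_labels(probs.argmax(axis=1))


def train(
    model: HybridModel,
    train_images,
    train_labels: list[str],
    monitor_images,
    monitor_labels: list[str],
    tcfg: TrainConfig = TrainConfig(),
    aug: AugmentConfig | None = None,
) -> TrainHistory:
    """Fit the model; returns the per-epoch history.

    ``train_images``/``monitor_images`` are sequences of preprocessed 2-D
    gray images (augmentation, when configured, is applied to the training
    stream only — monitor images are never transformed).  Training stops at
    ``max_epochs`` or earlier when the monitored loss stalls for ``patience``
    epochs; the returned model weights are those of the best epoch when
    ``restore_best`` is on.
    """
    train_images = list(train_images)
    monitor_images = list(monitor_images)
    if not train_images:
        raise ValidationError("empty training set")
    if len(train_images) != len(train_labels):
        raise ValidationError("train image/label length mismatch")

    model.apply_freeze_policy(tcfg.freeze_policy)
    rng = np.random.default_rng([tcfg.seed, 0xBEEF])
    for li, layer in enumerate(model.net.layers):  # deterministic dropout streams
        if isinstance(layer, (nn.Dropout, nn.BiGRU)):
            layer.rng = np.random.default_rng([tcfg.seed, li, 0xD0])

    augmenter = Augmenter(aug) if aug is not None else None
    y_train = encode_labels(list(train_labels))
    x_val = _prepare_inputs(monitor_images, model.config.input_size)
    y_val = encode_labels(list(monitor_labels))

    optimizer = nn.Adam(model.net, lr=tcfg.learning_rate)
    stopper = EarlyStopping(tcfg.patience)
    history = TrainHistory()
    best_weights = model.net.get_weights()

    n = len(train_images)
    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            imgs = [
                augmenter(train_images[i]) if augmenter else train_images[i]
                for i in idx
            ]
            xb = _prepare_inputs(imgs, model.config.input_size)
            yb = y_train[idx]
            logits = model.net.forward(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.net.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history.train_loss.append(epoch_loss / n)
        history.train_acc.append(epoch_correct / n)

        val_logits = model.net.forward(x_val, training=False)
        val_loss, _ = nn.softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val.argmax(axis=1)).mean())
        if not np.isfinite(val_loss) or not np.isfinite(history.train_loss[-1]):
            raise ValidationError(f"non-finite loss at epoch {epoch}")
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)

        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = model.net.get_weights()
        history.stopped_epoch = epoch
        if stop:
            break

    history.best_epoch = stopper.best_epoch
    if tcfg.restore_best:
        model.net.set_weights(best_weights)
    return history


def evaluate_accuracy(model: HybridModel, images, labels: list[str]) -> float:
    """Fraction of images whose argmax label matches the truth."""
    _, pred = predict(model, images)
    return float(np.mean([p == t for p, t in zip(pred, labels)]))
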