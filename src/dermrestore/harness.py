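"""Transfer-learning classification harness.

The training scheme: a frozen convolutional feature extractor (the
backbone), a new fully connected layer mapping features to the seven
lesion classes, softmax probabilities, categorical cross-entropy loss,
and an Adam loop (learning rate 1e-3, batch size 32, 25 epochs) over a
stratified 80/20 train/validation split.  Four metrics — training and
validation accuracy and loss — are recorded every epoch and reported at
epochs 10, 15 and 25.

Because only the head is trainable, any feature extractor with a fixed
output dimension can serve as the backbone.  The package ships
``TinyConvFeatures``, a small 3-conv-block reference CNN with fixed
seeded weights (forward pass only), so the whole harness runs offline at
desk scale; adapters around large pretrained networks satisfy the same
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "TrainConfig",
    "EpochMetrics",
    "TinyConvFeatures",
    "relu",
    "softmax",
    "categorical_cross_entropy",
    "accuracy",
    "split_dataset",
    "LesionHeadClassifier",
    "attach_head",
    "train",
    "run_experiment",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the study settings)."""

    input_size: tuple[int, int, int] = (224, 224, 3)
    batch_size: int = 32
    epochs: int = 25
    learning_rate: float = 1e-3
    n_classes: int = 7
    split_fraction: float = 0.8
    seed: int = 0
    report_epochs: tuple[int, ...] = (10, 15, 25)

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if min(self.batch_size, self.epochs, self.n_classes) < 1:
            raise ValueError("positive integers required")


@dataclass
class EpochMetrics:
    """The four per-epoch metrics: TAcc, TLoss, VAcc, VLoss."""

    epoch: int
    train_acc: float
    train_loss: float
    val_acc: float = float("nan")
    val_loss: float = float("nan")


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis; rows sum to 1."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def categorical_cross_entropy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over samples of -sum_c truth_c log(pred_c).

    *pred* rows are probability vectors (sum to 1 within 1e-6, checked);
    *truth* is one-hot or integer labels.  Probabilities are clipped to
    [1e-12, 1] before the log.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    if not np.allclose(pred.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("prediction rows must sum to 1")
    truth = np.asarray(truth)
    if truth.ndim == 1:
        onehot = np.zeros_like(pred)
        onehot[np.arange(len(truth)), truth.astype(int)] = 1.0
        truth = onehot
    if truth.shape != pred.shape:
        raise ValueError("prediction/label shape mismatch")
    logp = np.log(np.clip(pred, 1e-12, 1.0))
    return float(-np.mean(np.sum(truth * logp, axis=1)))


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of samples whose argmax prediction matches the label.

    Argmax ties break toward the lowest class index (numpy convention),
    which keeps the metric deterministic.
    """
    pred = np.atleast_2d(np.asarray(pred))
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(pred.argmax(axis=1) == truth))


def split_dataset(
    labels: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, seed-deterministic train/validation index split.

    Each class contributes ``round(n_c * fraction)`` training samples
    (at least 1, never all); the split is a disjoint, exhaustive
    partition of the indices.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_ids, val_ids = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 1:
            raise ValueError(f"class {cls} is empty")
        perm = rng.permutation(idx)
        n_train = int(round(len(idx) * fraction))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else 1
        train_ids.append(perm[:n_train])
        val_ids.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_ids)),
        np.sort(np.concatenate(val_ids)).astype(int),
    )


class TinyConvFeatures:
    """Frozen 3-conv-block reference CNN (forward pass only).

    Each block is a 3 x 3 convolution with fixed He-initialised weights
    (seeded), ReLU, and 2 x 2 average pooling.  The feature vector
    concatenates the global average pool of every block with the global
    standard deviation of the last block's maps, so both colour and
    texture statistics survive; the feature dimension is constant across
    calls.  Inputs are RGB images scaled to [-0.5, 0.5].
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (16, 32, 64),
        weight_seed: int = 12345,
    ):
        self.channels = channels
        self.weight_seed = weight_seed
        self.name = f"tiny-cnn-{'x'.join(map(str, channels))}"
        self.frozen = True
        rng = np.random.default_rng(weight_seed)
        self.weights = []
        c_in = 3
        for c_out in channels:
            fan_in = 9 * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, c_in, c_out))
            self.weights.append(w)
            c_in = c_out
        self.n_features = sum(channels) + channels[-1]

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        # x: (n, H, W, Cin); w: (3, 3, Cin, Cout); symmetric padding
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="symmetric")
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # win: (n, H, W, Cin, 3, 3)
        return np.einsum("nhwcij,ijco->nhwo", win, w, optimize=True)

    @staticmethod
    def _pool(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : 2 * h2, : 2 * w2]
        return x.reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        x = x / 255.0 - 0.5
        feats = []
        for w in self.weights:
            x = self._pool(relu(self._conv(x, w)))
            feats.append(x.mean(axis=(1, 2)))
        feats.append(x.std(axis=(1, 2)))
        return np.concatenate(feats, axis=1)


class LesionHeadClassifier(ClassifierMixin, BaseEstimator):
    """Frozen-backbone classifier with a trainable fully connected head.

    ``fit`` extracts features once with the (frozen) backbone, then runs
    Adam on the softmax cross-entropy of a single fully connected layer.
    Mini-batches are shuffled with ``random_state``; two fits with the
    same seed produce identical parameter traces.  Per-epoch metrics are
    recorded in ``history_`` (validation columns populated when
    ``fit(..., validation=(X_val, y_val))`` is given).
    """

    def __init__(
        self,
        backbone=None,
        epochs: int = 25,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.random_state = random_state

    def _backbone(self):
        return self.backbone if self.backbone is not None else TinyConvFeatures()

    def fit(self, X, y, validation=None):
        backbone = self._backbone()
        feats = backbone(np.asarray(X))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        class_index = {c: k for k, c in enumerate(self.classes_)}
        yk = np.array([class_index[c] for c in y])
        n, dim = feats.shape
        self.n_features_in_ = dim

        val_feats = val_yk = None
        if validation is not None:
            Xv, yv = validation
            val_feats = backbone(np.asarray(Xv))
            val_yk = np.array([class_index[c] for c in np.asarray(yv)])

        # standardise features with training statistics (shared with val)
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        self.feature_mean_, self.feature_scale_ = mu, sd
        ft = (feats - mu) / sd
        fv = (val_feats - mu) / sd if val_feats is not None else None

        rng = np.random.default_rng(self.random_state)
        # zero-initialised head: the softmax is exactly uniform before the
        # first step, and the trajectory depends only on the batch order
        w = np.zeros((dim, n_classes))
        b = np.zeros(n_classes)
        mw = np.zeros_like(w)
        vw = np.zeros_like(w)
        mb = np.zeros_like(b)
        vb = np.zeros_like(b)
        onehot = np.eye(n_classes)[yk]
        step = 0
        self.history_ = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = ft[idx] @ w + b
                probs = softmax(logits)
                if not np.all(np.isfinite(probs)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (non-finite loss)"
                    )
                grad = (probs - onehot[idx]) / len(idx)
                gw = ft[idx].T @ grad
                gb = grad.sum(axis=0)
                step += 1
                for g, p, m, v in ((gw, w, mw, vw), (gb, b, mb, vb)):
                    m *= self.beta1
                    m += (1 - self.beta1) * g
                    v *= self.beta2
                    v += (1 - self.beta2) * g * g
                    mhat = m / (1 - self.beta1**step)
                    vhat = v / (1 - self.beta2**step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + self.adam_eps)
            train_probs = softmax(ft @ w + b)
            metrics = EpochMetrics(
                epoch=epoch,
                train_acc=accuracy(train_probs, yk),
                train_loss=categorical_cross_entropy(train_probs, yk),
            )
            if fv is not None:
                val_probs = softmax(fv @ w + b)
                metrics.val_acc = accuracy(val_probs, val_yk)
                metrics.val_loss = categorical_cross_entropy(val_probs, val_yk)
            self.history_.append(metrics)
        self.coef_ = w
        self.intercept_ = b
        return self

    def predict_proba(self, X) -> np.ndarray:
        feats = self._backbone()(np.asarray(X))
        ft = (feats - self.feature_mean_) / self.feature_scale_
        return softmax(ft @ self.coef_ + self.intercept_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def attach_head(backbone, n_classes: int = 7, random_state: int = 0):
    """Build a classifier with *backbone* frozen and a new FC head.

    The head has ``dim * n_classes + n_classes`` trainable parameters
    (weights plus biases) and emits softmax probabilities.
    """
    return LesionHeadClassifier(backbone=backbone, random_state=random_state)


def train(
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    backbone=None,
) -> tuple[LesionHeadClassifier, list[EpochMetrics]]:
    """Split, fit and report: the full training scheme on one corpus."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    train_ids, val_ids = split_dataset(labels, cfg.split_fraction, cfg.seed)
    clf = LesionHeadClassifier(
        backbone=backbone,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        random_state=cfg.seed,
    )
    X = np.asarray(images)
    validation = (
        (X[val_ids], labels[val_ids]) if len(val_ids) else None
    )
    clf.fit(X[train_ids], labels[train_ids], validation=validation)
    return clf, clf.history_


def run_experiment(
    corpora: dict[str, np.ndarray],
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    backbone=None,
):
    """Train one model per corpus variant per seed; tabulate the metrics.

    All variants of a replicate share the same labels, split seed and
    head initialisation, so differences in the table reflect the images
    alone.  Returns a pandas DataFrame with columns
    ``variant, seed, epoch, TAcc, TLoss, VAcc, VLoss`` restricted to the
    reporting epochs.
    """
    import pandas as pd

    cfg = cfg or TrainConfig()
    rows = []
    for seed in seeds:
        run_cfg = TrainConfig(
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            n_classes=cfg.n_classes,
            split_fraction=cfg.split_fraction,
            seed=seed,
            report_epochs=cfg.report_epochs,
        )
        for variant, images in corpora.items():
            _, history = train(images, labels, run_cfg, backbone=backbone)
            for m in history:
                if m.epoch in run_cfg.report_epochs:
                    rows.append(
                        {
                            "variant": variant,
                            "seed": seed,
                            "epoch": m.epoch,
                            "TAcc": m.train_acc,
                            "TLoss": m.train_loss,
                            "VAcc": m.val_acc,
                            "VLoss": m.val_loss,
                        }
                    )
    return pd.DataFrame(rows)
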