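"""Transfer-learning CNN classifier: frozen convolutional backbone + trained head.

The deep route keeps a pretrained convolutional feature extractor fixed and
trains only a small fully-connected head on top:

    features (d) -> Dense(512) -> ReLU -> Dropout(0.5) -> Dense(3) -> softmax

trained with categorical cross-entropy and Adam (learning rate 1e-4), batch
size 16, inputs resized to input_size × input_size × 3 — 100 epochs at full
scale, far fewer on the separable synthetic patches used for testing.

Backbones are pluggable objects exposing ``forward``/``backward``/``params``.
The bundled :class:`TinyBackbone` (two 3×3 conv + ReLU + 2×2 max-pool blocks,
seeded random filters) is a desk-scale feature extractor that keeps the whole
training protocol — freezing, head optimisation, history — exercisable on a
laptop CPU; large ImageNet-pretrained backbones plug in through the same
interface.  Everything is plain NumPy: forward and backward passes are
written out layer by layer, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from .metrics import stratified_split

__all__ = [
    "HeadSpec",
    "TrainConfig",
    "TinyBackbone",
    "build_head",
    "train_transfer",
    "TrainedClassifier",
]


# ---------------------------------------------------------------- layers

class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # He-style init, suited to the ReLU that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class Conv3x3:
    """3×3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp_shape = xp.shape
        self._patches = [
            xp[:, :, i : i + h, j : j + w] for i in range(3) for j in range(3)
        ]
        out = np.zeros((n, self.W.shape[0], h, w))
        for k, patch in enumerate(self._patches):
            i, j = divmod(k, 3)
            out += np.einsum("nchw,oc->nohw", patch, self.W[:, :, i, j])
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, o, h, w = dout.shape
        dxp = np.zeros(self._xp_shape)
        for k, patch in enumerate(self._patches):
            i, j = divmod(k, 3)
            self.dW[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, patch)
            dxp[:, :, i : i + h, j : j + w] += np.einsum(
                "nohw,oc->nchw", dout, self.W[:, :, i, j]
            )
        self.db = dout.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2:
    """2×2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        self._mask = blocks == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        expanded = dout[:, :, :, None, :, None] * self._mask
        n, c, h2, _, w2, _ = expanded.shape
        return expanded.reshape(n, c, h2 * 2, w2 * 2)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))


class Adam:
    """Adam optimiser with the standard defaults (β1=0.9, β2=0.999)."""

    def __init__(self, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        for key, (p, g) in enumerate(params):
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------- specs

@dataclass(frozen=True)
class HeadSpec:
    """Fully-connected classification head: Dense(hidden)+ReLU+Dropout, Dense(classes)+softmax."""

    hidden_width: int = 512
    dropout: float = 0.5
    n_classes: int = 3

    def __post_init__(self):
        if self.hidden_width < 1 or self.n_classes < 1:
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam at 1e-4 on categorical cross-entropy,
    batch 16, inputs input_size×input_size×3, backbone frozen."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-4
    input_size: int = 128
    freeze_backbone: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch size positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")


def build_head(d: int, n_classes: int = 3, spec: HeadSpec = None,
               seed: int = 0) -> Sequential:
    """Parameterised classification head for d-dimensional backbone features.

    Parameter count is d·hidden + hidden + hidden·n_classes + n_classes.
    Softmax is applied by the caller (folded into the loss during training).
    """
    if d < 1:
        raise ValueError("feature dimension must be positive")
    spec = spec or HeadSpec(n_classes=n_classes)
    rng = np.random.default_rng(seed)
    return Sequential([
        Dense(d, spec.hidden_width, rng),
        ReLU(),
        Dropout(spec.dropout, np.random.default_rng(rng.integers(2**31))),
        Dense(spec.hidden_width, spec.n_classes, rng),
    ])


class TinyBackbone:
    """Two conv blocks (3×3 conv + ReLU + 2×2 max-pool), seeded random filters,
    closed by a coarse 2×2 spatial average.

    The final average over spatial quadrants makes the features near
    translation-invariant texture-energy statistics — what a plant patch
    actually carries — instead of position-tied activations; output feature
    dimension is 4 · channels[-1], independent of input size (which must be
    divisible by 8).
    """

    name = "tiny"

    def __init__(self, seed: int = 0, channels=(32, 64)):
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.net = Sequential([
            Conv3x3(3, c1, rng), ReLU(), MaxPool2(),
            Conv3x3(c1, c2, rng), ReLU(), MaxPool2(),
        ])
        self.out_channels = c2

    def feature_dim(self, input_size: int) -> int:
        return 4 * self.out_channels

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, s, s) images -> (N, 4·C) quadrant-averaged feature maps."""
        out = self.net.forward(x, train=train)
        n, c, h, w = out.shape
        self._out_shape = out.shape
        quads = out.reshape(n, c, 2, h // 2, 2, w // 2).mean(axis=(3, 5))
        return quads.reshape(n, -1)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        n, c, h, w = self._out_shape
        dquads = dfeat.reshape(n, c, 2, 1, 2, 1) / ((h // 2) * (w // 2))
        dout = np.broadcast_to(dquads, (n, c, 2, h // 2, 2, w // 2))
        return self.net.backward(dout.reshape(self._out_shape))

    def params(self):
        return self.net.params()


# ---------------------------------------------------------------- training

def _prepare_images(patches, size: int) -> np.ndarray:
    """ROI patches / RGB arrays -> (N, 3, size, size) float batch in [0, 1]."""
    batch = np.empty((len(patches), 3, size, size))
    for k, patch in enumerate(patches):
        pixels = np.asarray(getattr(patch, "pixels", patch), dtype=np.float64)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("each patch must be an (m, n, 3) RGB array")
        img = resize(pixels / 255.0, (size, size), order=1,
                     anti_aliasing=False, preserve_range=True)
        batch[k] = np.moveaxis(img, -1, 0)
    return batch


@dataclass
class TrainedClassifier:
    """Fitted transfer classifier: backbone + head + per-epoch history."""

    backbone: object
    head: Sequential
    classes: tuple
    config: TrainConfig
    history: pd.DataFrame
    feat_mean: np.ndarray = field(default=None, repr=False)
    feat_std: np.ndarray = field(default=None, repr=False)

    def _features(self, images: np.ndarray) -> np.ndarray:
        feats = self.backbone.forward(images, train=False)
        if self.feat_mean is not None:
            feats = (feats - self.feat_mean) / self.feat_std
        return feats

    def predict_proba(self, patches) -> np.ndarray:
        """Class probabilities (softmax outputs, rows sum to 1)."""
        images = _prepare_images(patches, self.config.input_size)
        logits = self.head.forward(self._features(images), train=False)
        return softmax(logits)

    def predict(self, patches) -> np.ndarray:
        """Argmax class labels; ties go to the earliest class."""
        probs = self.predict_proba(patches)
        return np.asarray([self.classes[i] for i in probs.argmax(axis=1)])


def _evaluate(head, feats, onehot) -> tuple[float, float]:
    probs = softmax(head.forward(feats, train=False))
    loss = cross_entropy(probs, onehot)
    acc = float(np.mean(probs.argmax(axis=1) == onehot.argmax(axis=1)))
    return loss, acc


def train_transfer(
    patches,
    labels,
    backbone=None,
    config: TrainConfig = None,
    head_spec: HeadSpec = None,
) -> TrainedClassifier:
    """Train the classification head on backbone features of labelled patches.

    Data are split 70/20/10 (train/validation/test) stratified by class; the
    head is optimised on the training split with Adam and categorical
    cross-entropy, and per-epoch loss/accuracy on train and validation are
    recorded in ``history``.  With ``freeze_backbone`` (default) the backbone
    weights never change — its features are computed once and standardised
    (train-split mean/std) before entering the head; unfreezing backpropagates
    through the backbone as well.
    """
    config = config or TrainConfig()
    labels = np.asarray(list(labels))
    classes = tuple(np.unique(labels).tolist())
    if len(patches) != len(labels):
        raise ValueError("patches and labels differ in length")
    if any(np.sum(labels == c) < 3 for c in classes):
        raise ValueError("every class needs at least 3 samples for the 70/20/10 split")

    backbone = backbone or TinyBackbone(seed=config.seed)
    spec = head_spec or HeadSpec(n_classes=len(classes))
    rng = np.random.default_rng(config.seed)

    images = _prepare_images(patches, config.input_size)
    y = np.asarray([classes.index(l) for l in labels])
    onehot = np.eye(len(classes))[y]

    idx_train, idx_val, _idx_test = stratified_split(
        labels, (0.7, 0.2, 0.1), seed=config.seed
    )

    frozen = config.freeze_backbone
    feat_mean = feat_std = None
    if frozen:
        feats_all = _forward_in_batches(backbone, images)
        feat_mean = feats_all[idx_train].mean(axis=0)
        feat_std = feats_all[idx_train].std(axis=0) + 1e-8
        feats_all = (feats_all - feat_mean) / feat_std
        d = feats_all.shape[1]
    else:
        d = backbone.feature_dim(config.input_size)

    head = build_head(d, len(classes), spec, seed=int(rng.integers(2**31)))
    optimizer = Adam(lr=config.learning_rate)
    frozen_snapshot = [p.copy() for p, _ in backbone.params()]

    history_rows = []
    for epoch in range(config.epochs):
        order = idx_train.copy()
        rng.shuffle(order)
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            if frozen:
                feats = feats_all[batch]
            else:
                feats = backbone.forward(images[batch], train=True)
            logits = head.forward(feats, train=True)
            probs = softmax(logits)
            dlogits = (probs - onehot[batch]) / batch.size
            dfeats = head.backward(dlogits)
            params = head.params()
            if not frozen:
                backbone.backward(dfeats)
                params = params + backbone.params()
            optimizer.step(params)

        if frozen:
            train_feats, val_feats = feats_all[idx_train], feats_all[idx_val]
        else:
            train_feats = _forward_in_batches(backbone, images[idx_train])
            val_feats = _forward_in_batches(backbone, images[idx_val])
        train_loss, train_acc = _evaluate(head, train_feats, onehot[idx_train])
        val_loss, val_acc = _evaluate(head, val_feats, onehot[idx_val])
        history_rows.append({
            "epoch": epoch + 1,
            "train_loss": train_loss, "train_acc": train_acc,
            "val_loss": val_loss, "val_acc": val_acc,
        })

    if frozen:
        for snap, (p, _) in zip(frozen_snapshot, backbone.params()):
            np.copyto(p, snap)  # guard: a frozen backbone is bit-identical

    return TrainedClassifier(
        backbone=backbone,
        head=head,
        classes=classes,
        config=config,
        history=pd.DataFrame(history_rows),
        feat_mean=feat_mean,
        feat_std=feat_std,
    )


def _forward_in_batches(backbone, images: np.ndarray, batch: int = 32) -> np.ndarray:
    outs = [
        backbone.forward(images[s : s + batch], train=False)
        for s in range(0, images.shape[0], batch)
    ]
    return np.concatenate(outs, axis=0)
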