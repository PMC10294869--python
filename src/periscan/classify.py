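"""Damaged/healthy classification of enhanced half-implant images.

The classifier is an AlexNet-style CNN adapted to the elongated aspect
of half-implant crops: a 450×250×3 input (tall, not square, so halves
are neither stretched nor over-padded), an 11×11 stride-4 stem, two
grouped convolution stages with cross-channel normalization, and a
compact fully connected head (1152 → 144 → 2). Training data are
balanced to roughly 1:1 damaged:healthy, split 80/20 stratified, and
the training portion is augmented ×4 by horizontal/vertical flips
(validation is never augmented, and no flip-variant of a training image
can reach the validation set because augmentation happens after the
split). Optimization is SGD with momentum under a stepped learning-rate
schedule: ``rate(epoch) = initial × factor^floor((epoch-1)/period)``.

``width_scale`` shrinks every channel and hidden width proportionally;
it exists so the same architecture can be exercised end to end at desk
scale on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .enhance import EnhancedHalf

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "LabeledImage",
    "DatasetSplit",
    "ClassifierModel",
    "SplitError",
    "TrainingError",
    "augment_flips",
    "make_split",
    "build_classifier",
    "classifier_layer_table",
    "learning_rate_at",
    "train_classifier",
    "classify_half",
    "fit_to_frame",
]

CLASSES = ("damaged", "healthy")


class SplitError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    input_height: int = 450
    input_width: int = 250
    channels: int = 3
    n_classes: int = 2
    optimizer: str = "sgdm"
    momentum: float = 0.9
    initial_learning_rate: float = 6e-5
    max_epoch: int = 50
    mini_batch_size: int = 16
    lr_drop_factor: float = 0.75
    lr_drop_period: int = 30
    dropout_probability: float = 0.5
    width_scale: float = 1.0

    def __post_init__(self):
        if min(self.input_height, self.input_width, self.n_classes,
               self.max_epoch, self.mini_batch_size, self.lr_drop_period) <= 0:
            raise ValueError("all size/schedule parameters must be positive")
        if not 0.0 < self.lr_drop_factor <= 1.0:
            raise ValueError("lr_drop_factor must lie in (0, 1]")
        if not 0.0 <= self.dropout_probability < 1.0:
            raise ValueError("dropout_probability must lie in [0, 1)")


@dataclass
class LabeledImage:
    pixels: np.ndarray
    label: str
    uid: str = ""


@dataclass
class DatasetSplit:
    train: list[LabeledImage]
    validation: list[LabeledImage]
    train_fraction: float
    class_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dataset assembly


def augment_flips(images: list[LabeledImage]) -> list[LabeledImage]:
    """×4 flip augmentation: {original, h-flip, v-flip, hv-flip}.

    Labels are preserved and every variant is emitted even if flips
    coincide pixel-wise on symmetric inputs.
    """
    if not images:
        raise ValueError("no images to augment")
    out = []
    for im in images:
        px = im.pixels
        out.append(im)
        out.append(LabeledImage(px[:, ::-1].copy(), im.label, im.uid + ":h"))
        out.append(LabeledImage(px[::-1].copy(), im.label, im.uid + ":v"))
        out.append(LabeledImage(px[::-1, ::-1].copy(), im.label, im.uid + ":hv"))
    return out


_BALANCE_TOLERANCE = 1.05  # keep classes as-is when within 5% of 1:1


def make_split(images: list[LabeledImage], train_fraction: float = 0.8,
               seed: int = 0) -> DatasetSplit:
    """Stratified train/validation split with class balancing.

    If the classes are further than ~5% from 1:1 the majority class is
    down-sampled (seeded, without replacement) to the minority count
    before splitting; flips are applied to the training portion only.
    """
    by_class: dict[str, list[LabeledImage]] = {}
    for im in images:
        by_class.setdefault(im.label, []).append(im)
    if len(by_class) < 2:
        raise SplitError(f"both classes required, got {sorted(by_class)}")
    rng = np.random.default_rng(seed)
    counts = {k: len(v) for k, v in by_class.items()}
    lo = min(counts.values())
    for k, members in by_class.items():
        if len(members) > _BALANCE_TOLERANCE * lo:
            keep = rng.choice(len(members), size=lo, replace=False)
            by_class[k] = [members[i] for i in sorted(keep)]
            logger.info("down-sampled %s from %d to %d for class balance",
                        k, len(members), lo)
    train, val = [], []
    for k in sorted(by_class):
        members = by_class[k]
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train.extend(members[i] for i in order[:n_train])
        val.extend(members[i] for i in order[n_train:])
    if not val:
        logger.warning("train_fraction %.2f leaves an empty validation set",
                       train_fraction)
    train = augment_flips(train) if train else train
    split = DatasetSplit(
        train=train, validation=val, train_fraction=train_fraction,
        class_counts={
            "train": {k: sum(im.label == k for im in train) for k in by_class},
            "validation": {k: sum(im.label == k for im in val) for k in by_class},
        })
    return split


# ---------------------------------------------------------------------------
# model


def _scaled(width: int, scale: float, multiple: int = 2) -> int:
    return max(multiple, int(round(width * scale / multiple)) * multiple)


class ClassifierModel:
    def __init__(self, net: nn.Sequential, config: ClassifierConfig):
        self.net = net
        self.config = config
        self.classes = CLASSES[:config.n_classes] if config.n_classes == 2 \
            else tuple(f"class_{i}" for i in range(config.n_classes))
        self.trained = False

    def activation_shapes(self):
        c = self.config
        return self.net.activation_shapes((c.channels, c.input_height, c.input_width))


def build_classifier(config: ClassifierConfig | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Assemble the AlexNet-variant network for ``config``.

    With the default geometry the first convolution maps 450×250×3 to
    110×60×96 and the head emits two logits through softmax.
    """
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    ws = config.width_scale
    c1, c2, c3, c4, c5 = (_scaled(96, ws), _scaled(256, ws), _scaled(384, ws),
                          _scaled(384, ws), _scaled(256, ws))
    f1, f2 = _scaled(1152, ws), _scaled(144, ws)
    p = config.dropout_probability
    layers = [
        nn.Conv2d(config.channels, c1, 11, stride=4, rng=rng),
        nn.ReLU(),
        nn.LRN(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(c1, c2, 5, padding=2, groups=2, rng=rng),
        nn.ReLU(),
        nn.LRN(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(c2, c3, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.Conv2d(c3, c4, 3, padding=1, groups=2, rng=rng),
        nn.ReLU(),
        nn.Conv2d(c4, c5, 3, padding=1, groups=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Flatten(),
    ]
    shape = (config.channels, config.input_height, config.input_width)
    for lay in layers:
        shape = lay.out_shape(shape)
        if any(s <= 0 for s in shape):
            raise ValueError(
                f"input {config.input_height}×{config.input_width} too small "
                "for the stride chain")
    layers += [
        nn.Dense(shape[0], f1, rng=rng),
        nn.ReLU(),
        nn.Dropout(p, rng=rng),
        nn.Dense(f1, f2, rng=rng),
        nn.ReLU(),
        nn.Dropout(p, rng=rng),
        nn.Dense(f2, config.n_classes, rng=rng),
    ]
    return ClassifierModel(nn.Sequential(layers), config)


def classifier_layer_table(config: ClassifierConfig | None = None):
    """Auditable (layer type, (H, W, C)) rows, image input through
    softmax/classification output, mirroring the build order."""
    config = config or ClassifierConfig()
    model = build_classifier(config)
    rows = [("Image Input",
             (config.input_height, config.input_width, config.channels))]
    names = {
        nn.ReLU: "ReLU",
        nn.LRN: "Cross Channel Normalization",
        nn.MaxPool2d: "2-D Max Pooling",
        nn.Dropout: "Dropout",
        nn.Flatten: None,
        nn.Dense: "Fully Connected",
    }
    shape = (config.channels, config.input_height, config.input_width)
    for lay in model.net.layers:
        shape = lay.out_shape(shape)
        if isinstance(lay, nn.Conv2d):
            name = "2-D Grouped Convolution" if lay.g > 1 else "2-D Convolution"
        else:
            name = names[type(lay)]
        if name is None:
            continue
        if len(shape) == 1:
            rows.append((name, (1, 1, shape[0])))
        else:
            rows.append((name, (shape[1], shape[2], shape[0])))
    rows.append(("Softmax", rows[-1][1]))
    rows.append(("Classification Output", rows[-1][1]))
    return rows


def learning_rate_at(epoch: int, config: ClassifierConfig) -> float:
    """Stepped schedule: ``initial × factor^floor((epoch-1)/period)``."""
    if epoch < 1:
        raise ValueError("epochs count from 1")
    drops = (epoch - 1) // config.lr_drop_period
    return config.initial_learning_rate * config.lr_drop_factor ** drops


# ---------------------------------------------------------------------------
# training and inference


def fit_to_frame(img: np.ndarray, frame: tuple[int, int]) -> np.ndarray:
    """Aspect-preserving resize into (H, W), symmetric zero padding.

    Avoids both failure modes of naive preparation: stretching the
    elongated half to a square distorts the thread features, while
    padding without rescaling buries them in black.
    """
    h, w = frame
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    ih, iw = img.shape[:2]
    scale = min(h / ih, w / iw)
    nh, nw = max(1, int(round(ih * scale))), max(1, int(round(iw * scale)))
    nh, nw = min(nh, h), min(nw, w)
    resized = resize(img.astype(np.float32), (nh, nw, img.shape[2]),
                     order=1, preserve_range=True, anti_aliasing=True)
    out = np.zeros((h, w, img.shape[2]), dtype=np.float32)
    top, left = (h - nh) // 2, (w - nw) // 2
    out[top:top + nh, left:left + nw] = resized
    return out


def _prep_batch(images: list[LabeledImage], config: ClassifierConfig,
                classes: tuple) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([
        fit_to_frame(im.pixels, (config.input_height, config.input_width))
        .transpose(2, 0, 1) for im in images]).astype(np.float32)
    xs = xs / 255.0 - 0.5
    ys = np.array([classes.index(im.label) for im in images])
    return xs, ys


def train_classifier(model: ClassifierModel, split: DatasetSplit,
                     config: ClassifierConfig | None = None, seed: int = 0):
    """Train with SGDM under the stepped learning-rate schedule.

    Runs ``max_epoch`` epochs (trailing incomplete batches are kept for
    the classifier); dropout is active in training passes only. Returns
    (model, history) where history rows carry epoch, learning rate,
    training/validation accuracy and loss.
    """
    config = config or model.config
    if not split.train:
        raise TrainingError("empty training set")
    rng = np.random.default_rng(seed)
    x_train, y_train = _prep_batch(split.train, config, model.classes)
    has_val = bool(split.validation)
    if has_val:
        x_val, y_val = _prep_batch(split.validation, config, model.classes)
    opt = nn.SGDM(model.net.params(), lr=config.initial_learning_rate,
                  momentum=config.momentum)
    n = len(split.train)
    bs = config.mini_batch_size
    history = []
    for epoch in range(1, config.max_epoch + 1):
        lr = learning_rate_at(epoch, config)
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = model.net.forward(x_train[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            model.net.backward(grad.astype(np.float32))
            opt.step(lr=lr)
            losses.append(loss)
            accs.append(float((logits.argmax(axis=1) == y_train[idx]).mean()))
        row = {"epoch": epoch, "lr": lr,
               "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs)),
               "val_loss": None, "val_acc": None}
        if has_val:
            logits = _forward_eval(model, x_val)
            row["val_loss"] = nn.softmax_cross_entropy(logits, y_val)[0]
            row["val_acc"] = float((logits.argmax(axis=1) == y_val).mean())
        history.append(row)
    model.trained = True
    if history:
        logger.info("classifier trained %d epochs; final val_acc=%s",
                    config.max_epoch, history[-1]["val_acc"])
    return model, history


def _forward_eval(model: ClassifierModel, x: np.ndarray,
                  batch: int = 32) -> np.ndarray:
    outs = [model.net.forward(x[i:i + batch], train=False)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def classify_half(model: ClassifierModel, half) -> tuple[str, float]:
    """Predict damaged/healthy for one enhanced half.

    Returns (label, probability of that label); the probability of the
    reported label is at least 0.5 for the binary head.
    """
    if not model.trained:
        raise TrainingError("classifier has not been trained")
    pixels = half.pixels if isinstance(half, EnhancedHalf) else np.asarray(half)
    cfg = model.config
    x = fit_to_frame(pixels, (cfg.input_height, cfg.input_width))
    x = (x / 255.0 - 0.5).transpose(2, 0, 1)[None].astype(np.float32)
    logits = model.net.forward(x, train=False)[0]
    probs = nn.softmax(logits[None], axis=1)[0]
    k = int(probs.argmax())
    return model.classes[k], float(probs[k])
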