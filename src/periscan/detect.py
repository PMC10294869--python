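"""Single-class grid detector for implant-thread regions.

The detector is a compact fully convolutional network in the YOLOv2
family: a stack of 3×3 conv / batch-norm / leaky-ReLU blocks with five
stride-2 max pools (so a 416×416 input yields a 13×13 grid), a stride-1
"same" pool, two wider conv blocks, and a 1×1 prediction head emitting
``n_anchors × (5 + n_classes)`` channels per cell — 30 for the default
five anchors and a single "implant" class. Training follows the usual
multi-part squared-error objective (localization + objectness) with
anchor priors estimated by IoU k-means over the training boxes.

Detection quality is summarised in the 2×2 confusion-matrix convention
used throughout the package: implant truths matched at an IoU threshold
are true positives; separately annotated tooth regions provide the
negative class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import nn
from .evaluate import ConfusionMatrix2x2

logger = logging.getLogger(__name__)

__all__ = [
    "Box",
    "DetectorConfig",
    "DetectorModel",
    "TrainingSchedule",
    "ConfigurationError",
    "ScheduleError",
    "TrainingError",
    "InputError",
    "box_iou",
    "build_detector",
    "detector_layer_table",
    "compute_schedule",
    "estimate_anchors",
    "train_detector",
    "detect_implants",
    "nms",
    "evaluate_detection",
]


class ConfigurationError(ValueError):
    pass


class ScheduleError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


class InputError(ValueError):
    pass


@dataclass
class Box:
    """Axis-aligned box: top-left corner (x, y), width, height, in pixels."""

    x: float
    y: float
    w: float
    h: float
    confidence: float | None = None
    class_name: str = "implant"

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w} h={self.h}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# configuration and architecture


@dataclass
class DetectorConfig:
    """Detector geometry and training settings.

    ``channels`` lists the widths of the conv blocks: the first six are
    each followed by a max pool (stride 2 for the first five, stride 1
    for the sixth), the remaining entries are extra 3×3 blocks before
    the 1×1 prediction head. The default widths give the canonical
    416→13 grid with a 30-channel output map.
    """

    input_size: int = 416
    anchors: tuple[tuple[float, float], ...] | None = None
    n_anchors: int = 5
    n_classes: int = 1
    conf_threshold: float = 0.5
    nms_iou: float = 0.5
    use_nms: bool = True
    optimizer: str = "sgdm"
    momentum: float = 0.9
    initial_learning_rate: float = 0.001
    max_epoch: int = 24
    mini_batch_size: int = 16
    channels: tuple[int, ...] = (16, 32, 64, 128, 256, 512, 1024, 512)

    def __post_init__(self):
        if self.input_size % 32:
            raise ConfigurationError(
                f"input_size must be divisible by 32 (got {self.input_size}); "
                "five stride-2 pools reduce the image by a factor of 32")
        if not 0.0 < self.conf_threshold < 1.0 or not 0.0 < self.nms_iou < 1.0:
            raise ConfigurationError("conf_threshold and nms_iou must lie in (0, 1)")
        if len(self.channels) < 6:
            raise ConfigurationError("need at least six conv blocks (one per pool stage)")
        if self.anchors is not None and len(self.anchors) != self.n_anchors:
            raise ConfigurationError("anchors length must equal n_anchors")

    @property
    def grid(self) -> int:
        return self.input_size // 32

    @property
    def output_depth(self) -> int:
        return self.n_anchors * (5 + self.n_classes)


class DetectorModel:
    """A built (possibly trained) detector."""

    def __init__(self, net: nn.Sequential, config: DetectorConfig):
        self.net = net
        self.config = config
        self.anchors: np.ndarray | None = (
            np.asarray(config.anchors, dtype=float) if config.anchors else None)
        self.trained = False

    def activation_shapes(self):
        s = self.config.input_size
        return self.net.activation_shapes((3, s, s))


def build_detector(config: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    """Assemble the detector network for ``config``.

    The layer sequence is conv/BN/leaky-ReLU blocks with interleaved
    pooling as described on :class:`DetectorConfig`, closed by a 1×1
    convolution onto ``n_anchors × (5 + n_classes)`` channels.
    """
    config = config or DetectorConfig()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 3
    for i, ch in enumerate(config.channels[:6]):
        layers += [
            nn.Conv2d(in_ch, ch, 3, padding="same", rng=rng),
            nn.BatchNorm2d(ch),
            nn.LeakyReLU(0.1),
        ]
        if i < 5:
            layers.append(nn.MaxPool2d(2, 2))
        else:
            layers.append(nn.MaxPool2d(2, 1, padding=(0, 1, 0, 1)))
        in_ch = ch
    for ch in config.channels[6:]:
        layers += [
            nn.Conv2d(in_ch, ch, 3, padding="same", rng=rng),
            nn.BatchNorm2d(ch),
            nn.LeakyReLU(0.1),
        ]
        in_ch = ch
    layers.append(nn.Conv2d(in_ch, config.output_depth, 1, rng=rng))
    return DetectorModel(nn.Sequential(layers), config)


def detector_layer_table(config: DetectorConfig | None = None) -> list[tuple[str, tuple[int, int, int]]]:
    """Human-auditable layer table: (layer type, (H, W, C)) per row.

    Rows follow the build order, starting with the image input and
    ending with the transform/output bookkeeping rows of the prediction
    map, so the default configuration can be compared row by row against
    the reference architecture.
    """
    config = config or DetectorConfig()
    model = build_detector(config)
    s = config.input_size
    rows = [("Image Input", (s, s, 3))]
    names = {
        nn.Conv2d: "2-D Convolution",
        nn.BatchNorm2d: "Batch Normalization",
        nn.LeakyReLU: "Leaky ReLU",
        nn.MaxPool2d: "2-D Max Pooling",
    }
    shape = (3, s, s)
    for lay in model.net.layers:
        shape = lay.out_shape(shape)
        rows.append((names[type(lay)], (shape[1], shape[2], shape[0])))
    rows.append(("Transform Layer", rows[-1][1]))
    rows.append(("Output", rows[-1][1]))
    return rows


# ---------------------------------------------------------------------------
# schedule


@dataclass
class TrainingSchedule:
    """Dataset/batch/epoch bookkeeping: one epoch is a full pass and an
    iteration one mini-batch update; trailing incomplete batches are
    discarded, so dataset_size // batch_size updates make up an epoch."""

    dataset_size: int
    batch_size: int
    max_epoch: int
    iterations_per_epoch: int = field(init=False)
    total_iterations: int = field(init=False)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ScheduleError("batch_size must be >= 1")
        self.iterations_per_epoch = self.dataset_size // self.batch_size
        if self.iterations_per_epoch == 0:
            raise ScheduleError(
                f"dataset of {self.dataset_size} yields zero iterations at "
                f"batch size {self.batch_size}")
        self.total_iterations = self.iterations_per_epoch * self.max_epoch


def compute_schedule(dataset_size: int, batch_size: int, max_epoch: int) -> TrainingSchedule:
    return TrainingSchedule(dataset_size, batch_size, max_epoch)


# ---------------------------------------------------------------------------
# anchors


def _iou_wh(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """IoU of centred (w,h) pairs against each anchor; wh (N,2), anchors (K,2)."""
    inter = np.minimum(wh[:, None, 0], anchors[None, :, 0]) * \
        np.minimum(wh[:, None, 1], anchors[None, :, 1])
    union = wh[:, None, 0] * wh[:, None, 1] + \
        anchors[None, :, 0] * anchors[None, :, 1] - inter
    return inter / union


def estimate_anchors(whs: np.ndarray, k: int = 5, seed: int = 0,
                     n_iter: int = 50) -> np.ndarray:
    """k-means over box (w, h) with 1 - IoU distance (Lloyd iterations)."""
    whs = np.asarray(whs, dtype=float)
    rng = np.random.default_rng(seed)
    if len(whs) == 0:
        raise ValueError("no boxes to estimate anchors from")
    if len(whs) <= k:
        reps = np.tile(whs, (int(np.ceil(k / len(whs))), 1))[:k]
        return reps * (1.0 + 0.05 * np.arange(k)[:, None])  # break ties
    centers = whs[rng.choice(len(whs), size=k, replace=False)].copy()
    for _ in range(n_iter):
        assign = _iou_wh(whs, centers).argmax(axis=1)
        new = centers.copy()
        for j in range(k):
            members = whs[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
            else:
                new[j] = whs[rng.integers(len(whs))]
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return centers[order]


# ---------------------------------------------------------------------------
# training


def _prep_image(pixels: np.ndarray, input_size: int):
    """Resize to the square network input; returns (chw float32, sx, sy)."""
    img = np.asarray(pixels)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    h, w = img.shape[:2]
    out = resize(img.astype(np.float32), (input_size, input_size, 3),
                 order=1, preserve_range=True, anti_aliasing=False)
    chw = (out / 255.0 - 0.5).transpose(2, 0, 1).astype(np.float32)
    return chw, input_size / w, input_size / h


def _boxes_to_grid(boxes, sx: float, sy: float, grid: int, input_size: int):
    """Ground-truth boxes → (cx, cy, w, h) in grid-cell units."""
    stride = input_size / grid
    out = []
    for b in boxes:
        cx = (b.x + b.w / 2.0) * sx / stride
        cy = (b.y + b.h / 2.0) * sy / stride
        out.append((cx, cy, b.w * sx / stride, b.h * sy / stride))
    return out


_LAMBDA_COORD = 10.0
_LAMBDA_OBJ = 5.0
_LAMBDA_NOOBJ = 0.5


def _yolo_loss_grad(out: np.ndarray, gts: list, anchors: np.ndarray, grid: int):
    """Multi-part squared-error objective; returns (loss, dloss/dout)."""
    n = out.shape[0]
    a = len(anchors)
    d = out.shape[1] // a
    p = out.reshape(n, a, d, grid, grid)
    txy_raw = p[:, :, 0:2]
    twh = p[:, :, 2:4]
    to_raw = p[:, :, 4]
    sxy = nn.sigmoid(txy_raw)
    so = nn.sigmoid(to_raw)
    grad = np.zeros_like(p)
    loss = 0.0
    obj_mask = np.zeros((n, a, grid, grid), dtype=bool)
    for ni, boxes in enumerate(gts):
        for (cx, cy, w, h) in boxes:
            j = min(grid - 1, max(0, int(cx)))
            i = min(grid - 1, max(0, int(cy)))
            ai = int(_iou_wh(np.array([[w, h]]), anchors).argmax())
            obj_mask[ni, ai, i, j] = True
            tx, ty = cx - j, cy - i
            for c, t in ((0, tx), (1, ty)):
                s = sxy[ni, ai, c, i, j]
                loss += _LAMBDA_COORD * (s - t) ** 2
                grad[ni, ai, c, i, j] += 2 * _LAMBDA_COORD * (s - t) * s * (1 - s)
            tw_t = np.log(max(w, 1e-6) / anchors[ai, 0])
            th_t = np.log(max(h, 1e-6) / anchors[ai, 1])
            for c, t in ((2, tw_t), (3, th_t)):
                v = twh[ni, ai, c - 2, i, j]
                loss += _LAMBDA_COORD * (v - t) ** 2
                grad[ni, ai, c, i, j] += 2 * _LAMBDA_COORD * (v - t)
            s = so[ni, ai, i, j]
            loss += _LAMBDA_OBJ * (s - 1.0) ** 2
            grad[ni, ai, 4, i, j] += 2 * _LAMBDA_OBJ * (s - 1.0) * s * (1 - s)
    # objectness suppression everywhere no anchor is responsible
    noobj = ~obj_mask
    loss += _LAMBDA_NOOBJ * float((so[noobj] ** 2).sum())
    g_no = 2 * _LAMBDA_NOOBJ * so * so * (1 - so)
    grad[:, :, 4][noobj] += g_no[noobj]
    return loss / n, (grad / n).reshape(out.shape).astype(out.dtype)


def train_detector(model: DetectorModel, data, config: DetectorConfig | None = None,
                   seed: int = 0):
    """Train the detector on annotated images; returns (model, loss_trace).

    No validation split is consumed: every image contributes to
    training, and the trace records one loss value per iteration. The
    iteration count follows :func:`compute_schedule` exactly.
    """
    config = config or model.config
    data = list(data)
    if not data:
        raise TrainingError("empty training dataset")
    sched = compute_schedule(len(data), config.mini_batch_size, config.max_epoch)
    rng = np.random.default_rng(seed)
    grid = config.grid

    imgs, gts, all_wh = [], [], []
    for im in data:
        chw, sx, sy = _prep_image(im.pixels, config.input_size)
        g = _boxes_to_grid(im.boxes, sx, sy, grid, config.input_size)
        imgs.append(chw)
        gts.append(g)
        all_wh.extend([(w, h) for (_, _, w, h) in g])
    if model.anchors is None:
        if all_wh:
            model.anchors = estimate_anchors(np.array(all_wh),
                                             k=config.n_anchors, seed=seed)
        else:
            # background-only training: geometry priors are arbitrary
            model.anchors = np.column_stack(
                [np.linspace(1.0, 4.0, config.n_anchors)] * 2)
    x_all = np.stack(imgs)

    opt = nn.SGDM(model.net.params(), lr=config.initial_learning_rate,
                  momentum=config.momentum)
    trace = []
    bs = config.mini_batch_size
    for _epoch in range(config.max_epoch):
        order = rng.permutation(len(data))
        for it in range(sched.iterations_per_epoch):
            idx = order[it * bs:(it + 1) * bs]
            out = model.net.forward(x_all[idx], train=True)
            loss, gout = _yolo_loss_grad(out, [gts[i] for i in idx],
                                         model.anchors, grid)
            opt.zero_grad()
            model.net.backward(gout)
            opt.step()
            trace.append(float(loss))
    model.trained = True
    logger.info("detector trained: %d iterations, loss %.3f -> %.3f",
                len(trace), trace[0], trace[-1])
    return model, trace


# ---------------------------------------------------------------------------
# inference


def nms(boxes: list[Box], iou_threshold: float) -> list[Box]:
    """Greedy non-maximum suppression by descending confidence."""
    remaining = sorted(boxes, key=lambda b: -(b.confidence or 0.0))
    kept: list[Box] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if box_iou(best, b) < iou_threshold]
    return kept


def detect_implants(model: DetectorModel, image: np.ndarray) -> list[Box]:
    """Run the trained detector on one radiograph.

    Returns confidence-sorted boxes in the image's pixel coordinates,
    thresholded at ``conf_threshold`` and (by default) de-duplicated by
    NMS at ``nms_iou``.
    """
    if not model.trained:
        raise TrainingError("model is not trained")
    img = np.asarray(image)
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise InputError(f"image too small for detection: {img.shape}")
    cfg = model.config
    grid = cfg.grid
    stride = cfg.input_size / grid
    chw, sx, sy = _prep_image(img, cfg.input_size)
    out = model.net.forward(chw[None], train=False)[0]
    a = len(model.anchors)
    p = out.reshape(a, out.shape[0] // a, grid, grid)
    conf = nn.sigmoid(p[:, 4])
    if cfg.n_classes > 1:
        conf = conf * nn.softmax(p[:, 5:], axis=1).max(axis=1)
    sx_off = nn.sigmoid(p[:, 0])
    sy_off = nn.sigmoid(p[:, 1])
    boxes = []
    ai, ii, jj = np.nonzero(conf >= cfg.conf_threshold)
    for a_i, i, j in zip(ai, ii, jj):
        bx = (j + sx_off[a_i, i, j]) * stride / sx
        by = (i + sy_off[a_i, i, j]) * stride / sy
        bw = model.anchors[a_i, 0] * np.exp(np.clip(p[a_i, 2, i, j], -8, 8)) * stride / sx
        bh = model.anchors[a_i, 1] * np.exp(np.clip(p[a_i, 3, i, j], -8, 8)) * stride / sy
        boxes.append(Box(bx - bw / 2, by - bh / 2, max(bw, 1e-3), max(bh, 1e-3),
                         confidence=float(conf[a_i, i, j])))
    if cfg.use_nms:
        boxes = nms(boxes, cfg.nms_iou)
    return sorted(boxes, key=lambda b: -(b.confidence or 0.0))


# ---------------------------------------------------------------------------
# evaluation


def _as_keyed(obj, keys=None):
    if isinstance(obj, dict):
        return obj
    return dict(enumerate(obj))


def evaluate_detection(predictions, truth_implants, truth_teeth=None,
                       iou_match: float = 0.5) -> ConfusionMatrix2x2:
    """Score per-image predictions against implant (and tooth) truths.

    Matching is one-to-one and greedy by descending confidence: each
    prediction claims the best-overlapping unmatched implant truth at
    IoU ≥ ``iou_match`` (a true positive), failing that an unmatched
    tooth region or nothing (a false positive). Unmatched implant truths
    are false negatives; unclaimed tooth regions are true negatives.
    """
    if not 0.0 < iou_match < 1.0:
        raise ValueError("iou_match must lie in (0, 1)")
    preds = _as_keyed(predictions)
    imps = _as_keyed(truth_implants)
    teeth = _as_keyed(truth_teeth) if truth_teeth is not None else {k: [] for k in imps}
    if set(preds) != set(imps) or set(preds) != set(teeth):
        raise ValueError("predictions and truths must share the same image keys")
    tp = fp = fn = tn = 0
    for key in preds:
        gt_imp = list(imps[key])
        gt_tooth = list(teeth[key])
        used_imp = [False] * len(gt_imp)
        used_tooth = [False] * len(gt_tooth)
        for pb in sorted(preds[key], key=lambda b: -(b.confidence or 0.0)):
            ious = [0.0 if used_imp[i] else box_iou(pb, g)
                    for i, g in enumerate(gt_imp)]
            if ious and max(ious) >= iou_match:
                used_imp[int(np.argmax(ious))] = True
                tp += 1
                continue
            tious = [0.0 if used_tooth[i] else box_iou(pb, g)
                     for i, g in enumerate(gt_tooth)]
            if tious and max(tious) >= iou_match:
                used_tooth[int(np.argmax(tious))] = True
            fp += 1
        fn += used_imp.count(False)
        tn += used_tooth.count(False)
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn,
                              positive_name="Implant", negative_name="Tooth")
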