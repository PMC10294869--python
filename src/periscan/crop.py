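"""Crop a detected implant and split it into two half-images.

The detector's thread box is expanded horizontally by a configurable
margin (the gingival context next to the threads carries the damage
signal), the implant is extracted from the crop by Otsu binarization
(largest connected component kept), and its long axis — nearly vertical
in a periapical film, but rarely exactly so — is found by ordinary
least squares of column on row over the foreground pixels. The crop is
then cut along that midline row by row; both halves are zero-padded on
their cut edge to the width of the wider one so left/right pairs share
dimensions, and the split is lossless: every crop pixel lands in
exactly one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .detect import Box

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionLine",
    "ImplantCrop",
    "HalfCrop",
    "DegenerateThresholdError",
    "RankError",
    "GeometryError",
    "expand_box",
    "crop_implant",
    "binarize_implant",
    "fit_midline",
    "split_halves",
    "merge_halves",
]

DEFAULT_MARGIN = 20


class DegenerateThresholdError(ValueError):
    pass


class RankError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass
class RegressionLine:
    """Implant midline as column = beta0 + beta1 × row."""

    beta0: float
    beta1: float

    def column_at(self, rows: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(rows, dtype=float)


@dataclass
class ImplantCrop:
    pixels: np.ndarray
    source_box: Box
    margin: int


@dataclass
class HalfCrop:
    """One half of a split implant crop.

    ``pad_columns`` counts the zero columns added on the cut edge at
    the half's widest row; ``cut_positions`` (per-row split column in
    crop coordinates) and ``source_width`` allow lossless reassembly.
    """

    pixels: np.ndarray
    side: str
    pad_columns: int
    cut_positions: np.ndarray | None = None
    source_width: int | None = None


def expand_box(box: Box, margin: int, image_extent: tuple[int, int]) -> Box:
    """Widen a box horizontally by ``margin`` px per side, clipped to the image."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    width, height = image_extent
    x1 = max(0.0, box.x - margin)
    x2 = min(float(width), box.x + box.w + margin)
    if x1 != box.x - margin or x2 != box.x + box.w + margin:
        logger.debug("expand_box clipped at image border: %s margin=%d", box, margin)
    return Box(x=x1, y=box.y, w=x2 - x1, h=box.h,
               confidence=box.confidence, class_name=box.class_name)


def crop_implant(image: np.ndarray, box: Box, margin: int = DEFAULT_MARGIN) -> ImplantCrop:
    """Extract the expanded box region from a grayscale radiograph."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 0]
    h, w = img.shape
    eb = expand_box(box, margin, (w, h))
    y1, y2 = int(round(eb.y)), int(round(eb.y + eb.h))
    x1, x2 = int(round(eb.x)), int(round(eb.x + eb.w))
    y1, x1 = max(0, y1), max(0, x1)
    pixels = img[y1:min(h, y2), x1:min(w, x2)]
    return ImplantCrop(pixels=pixels.copy(), source_box=box, margin=margin)


def binarize_implant(crop: ImplantCrop | np.ndarray) -> np.ndarray:
    """Foreground mask of the implant: pixels at or above the automatic
    global threshold (the lowest gray level strictly above the Otsu
    split), with the largest connected component retained."""
    pixels = crop.pixels if isinstance(crop, ImplantCrop) else np.asarray(crop)
    if pixels.size == 0:
        raise DegenerateThresholdError("empty crop")
    if pixels.max() == pixels.min():
        raise DegenerateThresholdError(
            "uniform crop: no threshold separates implant from background")
    mask = pixels > threshold_otsu(pixels)
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        raise DegenerateThresholdError("binarization produced no foreground")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def fit_midline(mask: np.ndarray) -> RegressionLine:
    """Least-squares centerline of a foreground mask.

    Fits column (dependent) on row (independent) over all foreground
    pixels. The implant's long axis is near-vertical, so regressing
    across rows recovers the centerline; the coefficients are reported
    in that rotated convention (intercept in columns, slope in columns
    per row).
    """
    rows, cols = np.nonzero(np.asarray(mask))
    if len(np.unique(rows)) < 2:
        raise RankError("midline fit needs foreground in at least 2 distinct rows")
    a = np.column_stack([np.ones_like(rows, dtype=float), rows.astype(float)])
    beta, *_ = np.linalg.lstsq(a, cols.astype(float), rcond=None)
    return RegressionLine(beta0=float(beta[0]), beta1=float(beta[1]))


def _cut_columns(line: RegressionLine, n_rows: int, width: int) -> np.ndarray:
    """Per-row split index k: columns [0, k) go left, [k, width) go right.

    A pixel centre exactly on the midline goes to the left half.
    """
    cols = line.column_at(np.arange(n_rows))
    k = np.floor(cols + 0.5).astype(int)
    return np.clip(k, 0, width)


def split_halves(crop: ImplantCrop | np.ndarray, line: RegressionLine) -> tuple[HalfCrop, HalfCrop]:
    """Cut a crop along the midline into equal-size left/right halves."""
    pixels = crop.pixels if isinstance(crop, ImplantCrop) else np.asarray(crop)
    n_rows, width = pixels.shape[:2]
    cols = line.column_at(np.arange(n_rows))
    if np.all(cols <= 0) or np.all(cols >= width):
        raise GeometryError("midline lies entirely outside the crop")
    k = _cut_columns(line, n_rows, width)
    w_half = int(max(k.max(initial=0), (width - k).max(initial=0)))
    left = np.zeros((n_rows, w_half), dtype=pixels.dtype)
    right = np.zeros((n_rows, w_half), dtype=pixels.dtype)
    for r in range(n_rows):
        kr = k[r]
        left[r, :kr] = pixels[r, :kr]
        if width - kr:
            right[r, w_half - (width - kr):] = pixels[r, kr:]
    return (
        HalfCrop(pixels=left, side="left", pad_columns=int(w_half - k.max(initial=0)),
                 cut_positions=k, source_width=width),
        HalfCrop(pixels=right, side="right",
                 pad_columns=int(w_half - (width - k).max(initial=0)),
                 cut_positions=k, source_width=width),
    )


def merge_halves(left: HalfCrop, right: HalfCrop) -> np.ndarray:
    """Reassemble the original crop from a split pair (exact inverse)."""
    if left.cut_positions is None or left.source_width is None:
        raise ValueError("halves lack reassembly metadata")
    k = left.cut_positions
    width = left.source_width
    n_rows, w_half = left.pixels.shape
    out = np.zeros((n_rows, width), dtype=left.pixels.dtype)
    for r in range(n_rows):
        kr = k[r]
        out[r, :kr] = left.pixels[r, :kr]
        if width - kr:
            out[r, kr:] = right.pixels[r, w_half - (width - kr):]
    return out
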