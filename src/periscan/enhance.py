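"""Half-image enhancement: equalization, gradients, region coloring.

The chain turns a raw half-implant crop into the high-contrast colored
image the damage classifier consumes:

1. global histogram equalization — the output level is the plain scaled
   cumulative distribution ``floor(255 · cdf(g))`` with no cdf-minimum
   renormalization, so a constant image maps to 255;
2. contrast-limited adaptive histogram equalization (tile-local
   mappings with the same cdf convention, clipped histograms with
   uniform excess redistribution, bilinear blending between tiles);
3. the absolute difference of the two is overlaid (pixel-wise maximum)
   onto the original to sharpen boundaries;
4. the gradient-magnitude surface of the overlay supplies edge
   evidence: a pixel whose local min–max gradient range exceeds a
   threshold is an edge;
5. flat pixels are split by original intensity into implant (above the
   implant/gum threshold), gum, and background (below the gate value,
   which wins over everything);
6. implant pixels are painted green, gum orange, background black,
   edges keep their overlay gray, and a pure red reference line marks
   the implant platform row.

The three intensity thresholds default to Otsu splits computed from the
image itself and can all be pinned explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter
from skimage.filters import threshold_otsu

from .crop import HalfCrop

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceParams",
    "EnhancedHalf",
    "Label",
    "COLORS",
    "equalize_histogram",
    "adaptive_equalize",
    "enhancement_difference",
    "gradient_magnitude",
    "classify_surface",
    "colorize",
    "preprocess_half",
]


class Label:
    """Per-pixel region codes."""

    BACKGROUND = 0
    GUM = 1
    IMPLANT = 2
    EDGE = 3


COLORS = {
    Label.IMPLANT: (0, 255, 0),
    Label.GUM: (255, 165, 0),
    Label.BACKGROUND: (0, 0, 0),
}
RED = (255, 0, 0)


@dataclass(frozen=True)
class SurfaceParams:
    """Edge/flat and implant/gum discrimination parameters.

    ``None`` thresholds are derived per image: the edge-range threshold
    as an Otsu split of the local gradient ranges, the implant/gum
    threshold as an Otsu split of the flat-pixel intensities, and the
    gum/background gate as an Otsu split of the flat pixels below it.
    """

    range_window: int = 3
    range_threshold: float | None = None
    z_threshold: float | None = None
    gate_value: float | None = None

    def __post_init__(self):
        if self.range_window < 3 or self.range_window % 2 == 0:
            raise ValueError("range_window must be an odd integer >= 3")
        if (self.gate_value is not None and self.z_threshold is not None
                and not 0 <= self.gate_value <= self.z_threshold <= 255):
            raise ValueError("need 0 <= gate_value <= z_threshold <= 255")


@dataclass
class EnhancedHalf:
    """Colored, labeled half-image ready for classification."""

    pixels: np.ndarray          # (H, W, 3) uint8
    label_map: np.ndarray       # (H, W) codes from Label
    reference_row: int


def equalize_histogram(gray: np.ndarray) -> np.ndarray:
    """Global histogram equalization, ``out = floor(255 · cdf(g))``.

    The mapping is monotone in the input level. Note the deliberate
    plain-cdf convention: the cumulative probability of the lowest
    occupied level is included, so a constant image maps to 255.
    """
    g = np.asarray(gray)
    if g.size == 0:
        raise ValueError("empty image")
    g = g.astype(np.uint8)
    hist = np.bincount(g.ravel(), minlength=256)
    cdf = np.cumsum(hist) / g.size
    lut = np.floor(255.0 * cdf).astype(np.uint8)
    return lut[g]


def _clipped_lut(region: np.ndarray, clip_limit: float) -> np.ndarray:
    """Tile mapping: clipped histogram, uniform redistribution, scaled cdf."""
    hist = np.bincount(region.ravel(), minlength=256).astype(float)
    npix = region.size
    limit = clip_limit * npix
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(hist) / npix
    return np.floor(255.0 * cdf)


def adaptive_equalize(gray: np.ndarray, tiles: tuple[int, int] = (8, 8),
                      clip_limit: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    The image is divided into ``tiles`` (remainder rows/columns spread
    across tiles), a clipped equalization mapping is computed per tile,
    and each pixel blends the mappings of the four surrounding tile
    centres bilinearly (clamped to the nearest tile outside the centre
    grid). With a single tile and ``clip_limit=1`` this reduces exactly
    to :func:`equalize_histogram`.
    """
    g = np.asarray(gray).astype(np.uint8)
    tr, tc = tiles
    h, w = g.shape
    if not 0.0 < clip_limit <= 1.0:
        raise ValueError("clip_limit must lie in (0, 1]")
    if tr < 1 or tc < 1 or h // tr < 2 or w // tc < 2:
        raise ValueError(
            f"tiles {tiles} leave tiles smaller than 2×2 for a {h}×{w} image")
    row_edges = np.linspace(0, h, tr + 1).round().astype(int)
    col_edges = np.linspace(0, w, tc + 1).round().astype(int)
    luts = np.empty((tr, tc, 256))
    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    for i in range(tr):
        for j in range(tc):
            luts[i, j] = _clipped_lut(
                g[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]],
                clip_limit)

    def _interp_coords(coords, centers):
        idx = np.searchsorted(centers, coords) - 1
        i0 = np.clip(idx, 0, len(centers) - 1)
        i1 = np.clip(idx + 1, 0, len(centers) - 1)
        span = np.where(i1 > i0, centers[i1] - centers[i0], 1.0)
        t = np.clip((coords - centers[i0]) / span, 0.0, 1.0)
        return i0, i1, t

    r0, r1, ty = _interp_coords(np.arange(h) + 0.5, centers_r)
    c0, c1, tx = _interp_coords(np.arange(w) + 0.5, centers_c)
    ty = ty[:, None]
    tx = tx[None, :]
    out = ((1 - ty) * (1 - tx) * luts[r0[:, None], c0[None, :], g]
           + (1 - ty) * tx * luts[r0[:, None], c1[None, :], g]
           + ty * (1 - tx) * luts[r1[:, None], c0[None, :], g]
           + ty * tx * luts[r1[:, None], c1[None, :], g])
    return np.clip(np.floor(out), 0, 255).astype(np.uint8)


def enhancement_difference(he: np.ndarray, ahe: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference of the two equalized images."""
    he = np.asarray(he)
    ahe = np.asarray(ahe)
    if he.shape != ahe.shape:
        raise ValueError(f"shape mismatch: {he.shape} vs {ahe.shape}")
    return np.abs(he.astype(np.int16) - ahe.astype(np.int16)).astype(np.uint8)


def gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    """Euclidean norm of the horizontal and vertical image gradients.

    Central differences in the interior, one-sided at the borders.
    """
    g = np.asarray(gray, dtype=float)
    if g.ndim != 2 or g.shape[0] < 3 or g.shape[1] < 3:
        raise ValueError(f"need a 2-D image of at least 3×3, got {g.shape}")
    gy, gx = np.gradient(g)
    return np.hypot(gx, gy)


def _otsu_or(values: np.ndarray, fallback: float) -> float:
    vals = np.asarray(values).ravel()
    if vals.size < 2 or np.ptp(vals) < 1e-9:
        return fallback
    return float(threshold_otsu(vals, nbins=256))


def resolve_params(original: np.ndarray, grad: np.ndarray,
                   params: SurfaceParams) -> SurfaceParams:
    """Fill in any automatic (None) thresholds from the image itself."""
    win = params.range_window
    rng_map = (maximum_filter(grad, size=win, mode="nearest")
               - minimum_filter(grad, size=win, mode="nearest"))
    rt = params.range_threshold
    if rt is None:
        rt = _otsu_or(rng_map, fallback=np.inf)
    flat = rng_map <= rt
    flat_vals = original[flat] if flat.any() else original.ravel()
    zt = params.z_threshold
    if zt is None:
        zt = _otsu_or(flat_vals, fallback=float(np.median(flat_vals)))
    gv = params.gate_value
    if gv is None:
        below = flat_vals[flat_vals < zt]
        gv = _otsu_or(below, fallback=0.0) if below.size else 0.0
        gv = min(gv, zt)
    return replace(params, range_threshold=float(rt), z_threshold=float(zt),
                   gate_value=float(gv))


def classify_surface(original: np.ndarray, grad: np.ndarray,
                     params: SurfaceParams | None = None) -> np.ndarray:
    """Label every pixel background / gum / implant / edge.

    The gate takes precedence: a pixel darker than ``gate_value`` is
    background regardless of its local gradient range. Otherwise a
    pixel whose local min–max range of the gradient surface (within
    ``range_window``) exceeds ``range_threshold`` is an edge; remaining
    flat pixels are implant if brighter than ``z_threshold``, else gum.
    """
    original = np.asarray(original, dtype=float)
    grad = np.asarray(grad, dtype=float)
    params = resolve_params(original, grad, params or SurfaceParams())
    win = params.range_window
    rng_map = (maximum_filter(grad, size=win, mode="nearest")
               - minimum_filter(grad, size=win, mode="nearest"))
    labels = np.full(original.shape, Label.GUM, dtype=np.uint8)
    labels[original > params.z_threshold] = Label.IMPLANT
    labels[rng_map > params.range_threshold] = Label.EDGE
    labels[original < params.gate_value] = Label.BACKGROUND
    return labels


def colorize(base: HalfCrop | np.ndarray, labels: np.ndarray,
             reference_row: int) -> EnhancedHalf:
    """Paint the label map onto a 3-channel image.

    Implant → green, gum → orange, background → black; edge pixels keep
    their gray value from ``base`` (the boundary-enhanced overlay); the
    ``reference_row`` is overwritten with pure red across the width.
    """
    gray = base.pixels if isinstance(base, HalfCrop) else np.asarray(base)
    if gray.shape != labels.shape:
        raise ValueError("base image and label map differ in shape")
    if not 0 <= reference_row < gray.shape[0]:
        raise ValueError(
            f"reference_row {reference_row} outside image of {gray.shape[0]} rows")
    out = np.zeros(gray.shape + (3,), dtype=np.uint8)
    for code, color in COLORS.items():
        out[labels == code] = color
    edge = labels == Label.EDGE
    out[edge] = np.repeat(gray[edge, None].astype(np.uint8), 3, axis=1)
    out[reference_row, :] = RED
    return EnhancedHalf(pixels=out, label_map=labels.astype(np.uint8),
                        reference_row=int(reference_row))


def preprocess_half(half: HalfCrop | np.ndarray,
                    params: SurfaceParams | None = None,
                    platform_row: int = 0,
                    tiles: tuple[int, int] | None = None,
                    clip_limit: float = 0.01) -> EnhancedHalf:
    """Full enhancement chain for one half-crop (deterministic).

    equalize → adaptive equalize → absolute difference → max-overlay on
    the original → gradient surface → surface labeling → coloring with
    the damage reference line at ``platform_row`` (the implant platform,
    by default the top row of the thread box, i.e. row 0 of the crop).
    """
    gray = half.pixels if isinstance(half, HalfCrop) else np.asarray(half)
    if gray.ndim == 3:
        gray = gray[..., 0]
    h, w = gray.shape[:2]
    if h < 3 or w < 3:
        raise ValueError(f"half-image too small to enhance: {gray.shape}")
    if tiles is None:
        tiles = (min(8, max(1, h // 8)), min(8, max(1, w // 8)))
    he = equalize_histogram(gray)
    ahe = adaptive_equalize(gray, tiles=tiles, clip_limit=clip_limit)
    diff = enhancement_difference(he, ahe)
    overlay = np.maximum(gray.astype(np.uint8), diff)
    grad = gradient_magnitude(overlay)
    labels = classify_surface(gray, grad, params)
    return colorize(overlay, labels, platform_row)
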