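"""Synthetic periapical-like radiographs with ground truth.

Clinical periapical films of dental implants are not publicly
distributable, so this module renders the statistical structure the
pipeline relies on: a bright threaded titanium shaft (alternating
crest/trough bands orthogonal to the shaft axis, a smooth collar above
the first thread) over a darker, noisy gingiva/bone texture, optionally
with a dark triangular erosion wedge abutting the coronal threads of
one or both sides — the radiographic signature of peri-implantitis bone
loss. Each image carries thread-only bounding boxes and per-half
(mesial/distal, here "left"/"right") damaged/healthy labels, plus the
exact masks used during rendering so downstream stages can be scored
against generator truth.

Determinism contract: a given spec (including its seed) reproduces the
image and annotations bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .detect import Box

logger = logging.getLogger(__name__)

__all__ = [
    "SynthSpec",
    "AnnotatedImage",
    "SynthSpecError",
    "PlacementError",
    "generate_radiograph",
    "generate_dataset",
    "write_annotated",
    "read_annotated",
]

SIDES = ("left", "right")


class SynthSpecError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic radiograph.

    Intensities are 8-bit gray levels; geometry is in pixels. The shaft
    must render brighter than the background (the premise the
    binarization and height-threshold stages rest on). ``defect_sides``
    optionally gives per-implant (left, right) damage flags and takes
    precedence over the scalar ``defect_present``/``defect_side``.
    """

    image_width: int = 256
    image_height: int = 256
    n_implants: int = 1
    thread_pitch: int = 12
    shaft_width: int = 28
    shaft_intensity: int = 220
    background_mean: int = 90
    background_noise_sd: float = 10.0
    defect_present: bool = False
    defect_depth_threads: int = 3
    defect_darkening: int = 60
    seed: int = 0
    defect_side: str = "left"
    rotation_max_deg: float = 5.0
    defect_sides: tuple[tuple[bool, bool], ...] | None = None

    def __post_init__(self):
        if self.image_width < 128 or self.image_height < 128:
            raise SynthSpecError("image dimensions must be at least 128×128")
        if self.shaft_intensity <= self.background_mean:
            raise SynthSpecError(
                "shaft_intensity must exceed background_mean (implants render "
                "brighter than gingiva)")
        if self.defect_present and self.defect_depth_threads < 1:
            raise SynthSpecError(
                "defect_depth_threads must be >= 1 when a defect is present "
                "(erosion to the first thread is the damage criterion)")
        if self.n_implants < 0:
            raise SynthSpecError("n_implants must be non-negative")
        if self.defect_side not in SIDES + ("both",):
            raise SynthSpecError(f"defect_side must be one of {SIDES + ('both',)}")
        if self.defect_sides is not None and len(self.defect_sides) != self.n_implants:
            raise SynthSpecError("defect_sides must give one (left, right) pair per implant")


@dataclass
class AnnotatedImage:
    """A radiograph plus ground truth.

    ``half_labels`` maps ``(box_id, side)`` to "damaged"/"healthy";
    ``truth`` holds rendering masks ("shaft", "wedge", "wedge_mirror")
    keyed by box id (shaft) or (box id, side).
    """

    pixels: np.ndarray
    boxes: list[Box]
    half_labels: dict[tuple[int, str], str]
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering

_RIDGE = 3           # extra half-width of thread crests, px
_TROUGH_INSET = 2    # half-width reduction between crests, px
_CREST_FRACTION = 0.5
_COLLAR_PITCHES = 2.0
_MAX_PLACEMENT_TRIES = 60


def _implant_defect_flags(spec: SynthSpec) -> tuple[tuple[bool, bool], ...]:
    if spec.defect_sides is not None:
        return tuple((bool(l), bool(r)) for l, r in spec.defect_sides)
    if not spec.defect_present:
        return tuple((False, False) for _ in range(spec.n_implants))
    flag = {
        "left": (True, False),
        "right": (False, True),
        "both": (True, True),
    }[spec.defect_side]
    return tuple(flag for _ in range(spec.n_implants))


def _render_implant(canvas, spec, rng, cx0, y0, theta, n_threads, defects):
    """Draw one implant; returns (thread box, shaft mask, wedge masks)."""
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx0, yy - y0
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    t = dx * sin_t + dy * cos_t          # axial coordinate, downward
    d = dx * cos_t - dy * sin_t          # signed perpendicular offset

    collar_h = _COLLAR_PITCHES * spec.thread_pitch
    thread_len = n_threads * spec.thread_pitch
    half = spec.shaft_width / 2.0

    collar = (t >= 0) & (t < collar_h) & (np.abs(d) <= 0.85 * half)
    zone = (t >= collar_h) & (t < collar_h + thread_len)
    phase = np.mod(t - collar_h, spec.thread_pitch)
    crest = phase < _CREST_FRACTION * spec.thread_pitch
    halfw = np.where(crest, half + _RIDGE, half - _TROUGH_INSET)
    threads = zone & (np.abs(d) <= halfw)
    shaft = collar | threads

    tone = np.full_like(canvas, float(spec.shaft_intensity))
    tone[collar] -= 12.0
    tone[zone & ~crest] -= 25.0
    canvas[shaft] = tone[shaft] + rng.normal(0.0, 3.0, size=int(shaft.sum()))

    ys, xs = np.nonzero(threads)
    if len(ys) == 0:
        raise PlacementError("thread region fell outside the image")
    box = Box(x=int(xs.min()), y=int(ys.min()),
              w=int(xs.max() - xs.min() + 1), h=int(ys.max() - ys.min() + 1))

    depth_px = spec.defect_depth_threads * spec.thread_pitch
    wmax = min(0.8 * depth_px, 30.0)
    frac = np.clip((t - collar_h) / max(depth_px, 1), 0.0, 1.0)
    width_here = wmax * (1.0 - frac)
    t_ok = (t >= collar_h - 2) & (t <= collar_h + depth_px)
    outer_edge = half + _RIDGE
    wedges = {}
    for side, sgn, damaged in (("left", -1.0, defects[0]), ("right", 1.0, defects[1])):
        geom = t_ok & (sgn * d > outer_edge) & \
            (sgn * d <= outer_edge + width_here) & ~shaft
        mirror = t_ok & (-sgn * d > outer_edge) & \
            (-sgn * d <= outer_edge + width_here) & ~shaft
        if damaged:
            canvas[geom] -= float(spec.defect_darkening)
        wedges[side] = (geom if damaged else None, mirror)
    return box, shaft, wedges


def generate_radiograph(spec: SynthSpec) -> AnnotatedImage:
    """Render one annotated synthetic radiograph from ``spec``.

    Implants are placed without overlap (bounded retries, then
    :class:`PlacementError`); each thread box stays fully inside the
    image, and a half is labeled damaged exactly when an erosion wedge
    was rendered on that side.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width

    lowfreq = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    sd = max(float(lowfreq.std()), 1e-9)
    canvas = (spec.background_mean
              + lowfreq * (0.15 * spec.background_noise_sd / sd)
              + rng.normal(0.0, spec.background_noise_sd, size=(h, w)))

    defects = _implant_defect_flags(spec)
    boxes: list[Box] = []
    half_labels: dict[tuple[int, str], str] = {}
    truth = {"shaft": {}, "wedge": {}, "wedge_mirror": {}}

    depth_px = spec.defect_depth_threads * spec.thread_pitch
    side_room = spec.shaft_width / 2 + _RIDGE + min(0.8 * depth_px, 30.0) + 4
    placed: list[Box] = []
    for idx in range(spec.n_implants):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            theta = np.deg2rad(rng.uniform(-spec.rotation_max_deg,
                                           spec.rotation_max_deg))
            n_threads = int(rng.integers(7, 11))
            total_len = (_COLLAR_PITCHES + n_threads) * spec.thread_pitch
            if total_len > 0.9 * h or 2 * side_room > 0.9 * w:
                raise PlacementError(
                    f"implant geometry of spec does not fit a {w}×{h} image")
            cx0 = rng.uniform(side_room + abs(np.tan(theta)) * total_len,
                              w - side_room - abs(np.tan(theta)) * total_len)
            y0 = rng.uniform(4, h - total_len - 4)
            probe = Box(x=cx0 - side_room, y=y0,
                        w=2 * side_room, h=total_len)
            from .detect import box_iou
            if all(box_iou(probe, p) == 0.0 for p in placed):
                break
        else:
            raise PlacementError(
                f"could not place implant {idx} without overlap after "
                f"{_MAX_PLACEMENT_TRIES} tries for spec {spec}")
        placed.append(probe)
        box, shaft, wedges = _render_implant(
            canvas, spec, rng, cx0, y0, theta, n_threads, defects[idx])
        boxes.append(box)
        truth["shaft"][idx] = shaft
        for side in SIDES:
            geom, mirror = wedges[side]
            damaged = geom is not None
            half_labels[(idx, side)] = "damaged" if damaged else "healthy"
            if damaged:
                truth["wedge"][(idx, side)] = geom
            truth["wedge_mirror"][(idx, side)] = mirror

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels=pixels, boxes=boxes,
                          half_labels=half_labels, truth=truth)


def generate_dataset(spec: SynthSpec, n_images: int, damaged_fraction: float,
                     seed: int = 0) -> list[AnnotatedImage]:
    """Generate ``n_images`` radiographs with a controlled damage rate.

    The realized fraction of damaged half-labels equals
    ``round(damaged_fraction × total halves)`` (deviation below one
    image's worth); per-image seeds derive deterministically from the
    master seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0.0 <= damaged_fraction <= 1.0:
        raise ValueError("damaged_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_halves = n_images * spec.n_implants * 2
    flags = np.zeros(n_halves, dtype=bool)
    flags[:round(damaged_fraction * n_halves)] = True
    rng.shuffle(flags)
    flags = flags.reshape(n_images, spec.n_implants, 2)
    seeds = rng.integers(0, 2**31, size=n_images)
    images = []
    for i in range(n_images):
        sides = tuple((bool(l), bool(r)) for l, r in flags[i])
        images.append(generate_radiograph(
            replace(spec, seed=int(seeds[i]), defect_sides=sides)))
    return images


# ---------------------------------------------------------------------------
# serialization (PNG + one JSON per image)


def write_annotated(image: AnnotatedImage, directory, stem: str) -> tuple[Path, Path]:
    """Write pixels as PNG and annotations as JSON; returns both paths.

    Coordinates are 0-based, x rightward, y downward; boxes are
    half-open ``[x, x+w) × [y, y+h)``. Truth masks are not serialized.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{stem}.png"
    js = directory / f"{stem}.json"
    iio.imwrite(png, image.pixels)
    payload = {
        "image": png.name,
        "boxes": [
            {"id": i, "x": int(b.x), "y": int(b.y), "w": int(b.w), "h": int(b.h)}
            for i, b in enumerate(image.boxes)
        ],
        "half_labels": [
            {"box_id": k[0], "side": k[1], "label": v}
            for k, v in sorted(image.half_labels.items())
        ],
    }
    js.write_text(json.dumps(payload, indent=1))
    return png, js


def read_annotated(json_path) -> AnnotatedImage:
    """Load a PNG + JSON pair written by :func:`write_annotated`."""
    json_path = Path(json_path)
    payload = json.loads(json_path.read_text())
    pixels = iio.imread(json_path.parent / payload["image"])
    boxes = [Box(x=b["x"], y=b["y"], w=b["w"], h=b["h"])
             for b in sorted(payload["boxes"], key=lambda b: b["id"])]
    half_labels = {(e["box_id"], e["side"]): e["label"]
                   for e in payload["half_labels"]}
    return AnnotatedImage(pixels=pixels, boxes=boxes, half_labels=half_labels)
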