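"""Frame sampling, letterbox resizing and training-time augmentation.

One representative frame is sampled per labeled second (at the second's
midpoint, maximally distant from boundary transitions).  Frames are brought
to the square model resolution by scaling the longest edge down to the
target, preserving aspect ratio, and centering the content on a black
canvas ("letterboxing") — this handles portrait and landscape inputs alike.
Augmentation follows the usual anti-overfitting trio for long static shots:
random horizontal flips, +/-10 percent lightness jitter (applied on the HLS
lightness channel), and random crops retaining 80–100 percent of the area.

Images are numpy ``uint8`` arrays of shape (H, W, 3), RGB channel order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "ImageFrame",
    "FrameSpec",
    "AugmentParams",
    "sample_timestamps",
    "letterbox_resize",
    "augment",
    "rgb_to_hls",
    "hls_to_rgb",
]


@dataclass(frozen=True)
class ImageFrame:
    """Pixel payload plus provenance for manifest bookkeeping."""

    pixels: np.ndarray  # (H, W, 3) uint8, RGB
    source_video: str = ""
    timestamp_s: float = 0.0


@dataclass(frozen=True)
class FrameSpec:
    """Target square edge (224 or 384 for the usual pre-trained backbones),
    frames sampled per labeled second, and padding intensity."""

    target_edge: int = 224
    sampling_rate: int = 1
    pad_value: int = 0

    def __post_init__(self) -> None:
        if self.target_edge < 1 or self.sampling_rate < 1:
            raise ValueError("target_edge and sampling_rate must be positive")


@dataclass(frozen=True)
class AugmentParams:
    flip_probability: float = 0.5
    lightness_low: float = 0.9
    lightness_high: float = 1.1
    crop_probability: float = 0.5
    crop_area_low: float = 0.8
    crop_area_high: float = 1.0
    lightness_probability: float = 0.5


def sample_timestamps(duration_s: int, spec: FrameSpec | None = None) -> list[float]:
    """Timestamps of the representative frames for a video of integer length.

    At rate r, each second [i, i+1) is subdivided uniformly and the midpoint
    of each subdivision is sampled, so rate 1 gives i + 0.5 and the frames
    align 1:1 with the per-second label records.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    spec = spec or FrameSpec()
    r = spec.sampling_rate
    return [i + (k + 0.5) / r for i in range(duration_s) for k in range(r)]


def _as_array(frame) -> np.ndarray:
    px = frame.pixels if isinstance(frame, ImageFrame) else frame
    px = np.asarray(px)
    if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
        raise ValueError(f"expected a (H, W, 3) image, got shape {px.shape}")
    return px


def letterbox_resize(frame, spec: FrameSpec | None = None) -> np.ndarray:
    """Scale the longest edge to ``target_edge`` and pad to a square.

    Aspect ratio is preserved (short edge rounded to the nearest integer,
    at least 1 pixel); the content is centered and every padding pixel is
    exactly ``pad_value``.  An already-square input at the target edge
    passes through pixel-identical.
    """
    spec = spec or FrameSpec()
    px = _as_array(frame)
    h, w = px.shape[:2]
    edge = spec.target_edge
    if h == w == edge:
        return px.copy()
    scale = edge / max(h, w)
    new_h = max(1, int(round(h * scale))) if h < w else edge
    new_w = max(1, int(round(w * scale))) if w < h else edge
    if h == w:
        new_h = new_w = edge
    resized = np.asarray(
        Image.fromarray(px).resize((new_w, new_h), Image.BILINEAR)
    )
    canvas = np.full((edge, edge, 3), spec.pad_value, dtype=px.dtype)
    top = (edge - new_h) // 2
    left = (edge - new_w) // 2
    canvas[top : top + new_h, left : left + new_w] = resized
    return canvas


# -- HLS color space (vectorized; hue in [0,1), lightness/saturation in [0,1])

def rgb_to_hls(rgb: np.ndarray) -> np.ndarray:
    """Vectorized RGB -> HLS on float arrays in [0, 1]."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.max(rgb, axis=-1)
    minc = np.min(rgb, axis=-1)
    l = (maxc + minc) / 2.0
    delta = maxc - minc
    s = np.zeros_like(l)
    nz = delta > 0
    denom = np.where(l <= 0.5, maxc + minc, 2.0 - maxc - minc)
    s[nz] = delta[nz] / denom[nz]
    h = np.zeros_like(l)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(nz, (maxc - r) / np.where(nz, delta, 1), 0)
        gc = np.where(nz, (maxc - g) / np.where(nz, delta, 1), 0)
        bc = np.where(nz, (maxc - b) / np.where(nz, delta, 1), 0)
    h = np.where(maxc == r, bc - gc, h)
    h = np.where((maxc == g) & (maxc != r), 2.0 + rc - bc, h)
    h = np.where((maxc == b) & (maxc != r) & (maxc != g), 4.0 + gc - rc, h)
    h = (h / 6.0) % 1.0
    h = np.where(nz, h, 0.0)
    return np.stack([h, l, s], axis=-1)


def _hls_component(m1, m2, hue):
    hue = hue % 1.0
    return np.where(
        hue < 1 / 6,
        m1 + (m2 - m1) * hue * 6.0,
        np.where(
            hue < 0.5,
            m2,
            np.where(hue < 2 / 3, m1 + (m2 - m1) * (2 / 3 - hue) * 6.0, m1),
        ),
    )


def hls_to_rgb(hls: np.ndarray) -> np.ndarray:
    """Vectorized HLS -> RGB, inverse of :func:`rgb_to_hls`."""
    h, l, s = hls[..., 0], hls[..., 1], hls[..., 2]
    m2 = np.where(l <= 0.5, l * (1.0 + s), l + s - l * s)
    m1 = 2.0 * l - m2
    r = _hls_component(m1, m2, h + 1 / 3)
    g = _hls_component(m1, m2, h)
    b = _hls_component(m1, m2, h - 1 / 3)
    gray = s == 0
    r = np.where(gray, l, r)
    g = np.where(gray, l, g)
    b = np.where(gray, l, b)
    return np.stack([r, g, b], axis=-1)


def scale_lightness(px: np.ndarray, factor: float) -> np.ndarray:
    """Scale the HLS lightness channel by ``factor``, clipping to [0, 255]."""
    hls = rgb_to_hls(px.astype(np.float64) / 255.0)
    hls[..., 1] = np.clip(hls[..., 1] * factor, 0.0, 1.0)
    out = hls_to_rgb(hls) * 255.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment(
    frame,
    rng: np.random.Generator,
    params: AugmentParams | None = None,
) -> np.ndarray:
    """Apply the training augmentations with a seeded generator.

    Order: horizontal flip, lightness jitter, random crop (the crop window
    keeps the input aspect ratio and is resized back, so the output shape
    always equals the input shape).  With all probabilities zero the input
    is returned unchanged; identical seeds give identical outputs.
    """
    params = params or AugmentParams()
    px = _as_array(frame).copy()
    h, w = px.shape[:2]

    if rng.random() < params.flip_probability:
        px = px[:, ::-1, :].copy()

    if rng.random() < params.lightness_probability:
        factor = rng.uniform(params.lightness_low, params.lightness_high)
        px = scale_lightness(px, factor)

    if rng.random() < params.crop_probability:
        area = rng.uniform(params.crop_area_low, params.crop_area_high)
        f = float(np.sqrt(area))
        ch, cw = max(1, int(round(h * f))), max(1, int(round(w * f)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = px[top : top + ch, left : left + cw]
        px = np.asarray(Image.fromarray(crop).resize((w, h), Image.BILINEAR))

    return px
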