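"""Egg-localisation preprocessing chain for candling photographs.

The chain mirrors what a transmission image of an egg in a dark box needs
before classification: grayscale conversion, median filtering to remove
impulse noise, Otsu thresholding by the maximum between-class variance
principle

    sigma_B^2(T) = w0(T) * w1(T) * (mu0(T) - mu1(T))^2

with a manual offset of +100 added to the automatic threshold (the
automatic value sits mid-range because shell light leakage saturates near
255, while dark-box wall reflections sit around 180-200 and must stay below
the effective threshold), selection of the largest connected foreground
region, a 1.1x bounding-box crop to avoid truncating the egg, and a resize
of the colour crop to the model input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "PipelineError",
    "NoContrastError",
    "NoEggError",
    "RegionBox",
    "ThresholdResult",
    "PreprocessConfig",
    "PreprocessResult",
    "to_grayscale",
    "median_filter",
    "histogram256",
    "between_class_variance",
    "otsu_threshold",
    "largest_foreground_region",
    "scale_and_clamp_bbox",
    "preprocess_pipeline",
]

#: ITU-R BT.601 luma weights used for grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class PipelineError(ValueError):
    """Base class for preprocessing failures."""


class NoContrastError(PipelineError):
    """Raised for single-valued images where thresholding is degenerate."""


class NoEggError(PipelineError):
    """Raised when no foreground pixel survives the effective threshold."""


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned pixel rectangle, 0-based, half-open.

    Covers columns [x, x+w) and rows [y, y+h).
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box {self}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    def contains(self, other: "RegionBox") -> bool:
        return (self.x <= other.x and self.y <= other.y
                and self.x2 >= other.x2 and self.y2 >= other.y2)

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for numpy indexing."""
        return slice(self.y, self.y2), slice(self.x, self.x2)

    @staticmethod
    def from_mask(mask: np.ndarray) -> "RegionBox":
        """Tight box around the nonzero pixels of a 2-D mask."""
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise NoEggError("mask has no foreground pixels")
        return RegionBox(int(cols[0]), int(rows[0]),
                         int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1))


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold, its between-class variance, and the offset result."""

    T_otsu: int
    sigma_b2: float
    offset: int
    T_effective: int


@dataclass(frozen=True)
class PreprocessConfig:
    median_kernel: int = 5
    otsu_offset: int = 100
    bbox_scale: float = 1.1
    input_size: int = 224

    def __post_init__(self):
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 3")
        if self.bbox_scale < 1.0:
            raise ValueError("bbox_scale must be >= 1")
        if self.input_size < 16:
            raise ValueError("input_size must be >= 16")


@dataclass(frozen=True)
class PreprocessResult:
    image: np.ndarray          # (input_size, input_size, 3) uint8 colour crop
    threshold: ThresholdResult
    crop_box: RegionBox        # the scaled, clamped box in original coords


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an (H, W, 3) image, rounded to uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * image[..., 0] + wg * image[..., 1] + wb * image[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_filter(image: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Square-neighbourhood median with reflect edge handling."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be an odd integer >= 3")
    return ndimage.median_filter(np.asarray(image), size=kernel, mode="reflect")


def histogram256(image: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a uint8 grayscale image."""
    return np.bincount(np.asarray(image, dtype=np.uint8).ravel(), minlength=256)


def between_class_variance(hist: np.ndarray, T: int) -> float:
    """sigma_B^2(T) = w0 w1 (mu0 - mu1)^2 with class 0 = levels <= T.

    Returns 0 when either class is empty.
    """
    if not 0 <= T <= 255:
        raise ValueError(f"threshold {T} outside [0, 255]")
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    levels = np.arange(256, dtype=np.float64)
    n0 = hist[: T + 1].sum()
    n1 = total - n0
    if n0 == 0 or n1 == 0:
        return 0.0
    mu0 = (hist[: T + 1] * levels[: T + 1]).sum() / n0
    mu1 = (hist[T + 1 :] * levels[T + 1 :]).sum() / n1
    w0 = n0 / total
    w1 = n1 / total
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def _sigma_b2_all(hist: np.ndarray) -> np.ndarray:
    """Vectorised sigma_B^2(T) for every T in [0, 255]."""
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    n0 = np.cumsum(hist)
    s0 = np.cumsum(hist * levels)
    n1 = total - n0
    s1 = s0[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(n0 > 0, s0 / n0, 0.0)
        mu1 = np.where(n1 > 0, s1 / n1, 0.0)
    sb2 = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    sb2[(n0 == 0) | (n1 == 0)] = 0.0
    return sb2


def otsu_threshold(image: np.ndarray, offset: int = 100) -> ThresholdResult:
    """Exhaustive-argmax Otsu threshold plus an additive offset.

    Ties are broken toward the smallest maximising level; the effective
    threshold is capped at 255 and foreground is defined as strictly
    greater than it.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    hist = histogram256(image)
    if np.count_nonzero(hist) < 2:
        raise NoContrastError("image has a single gray level; no threshold exists")
    sb2 = _sigma_b2_all(hist)
    t = int(np.argmax(sb2))  # argmax returns the smallest maximiser
    return ThresholdResult(
        T_otsu=t,
        sigma_b2=float(sb2[t]),
        offset=int(offset),
        T_effective=int(min(t + offset, 255)),
    )


def largest_foreground_region(mask: np.ndarray) -> tuple[RegionBox, np.ndarray]:
    """Largest 8-connected component of a binary mask and its tight box."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise NoEggError("empty foreground mask: no egg detected")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    best = int(np.argmax(counts))
    component = labels == best
    return RegionBox.from_mask(component), component


def scale_and_clamp_bbox(box: RegionBox, factor: float,
                         image_w: int, image_h: int) -> RegionBox:
    """Scale a box about its centre, then clamp it to the image bounds."""
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    cx = box.x + box.w / 2.0
    cy = box.y + box.h / 2.0
    new_w = int(round(box.w * factor))
    new_h = int(round(box.h * factor))
    x = int(round(cx - new_w / 2.0))
    y = int(round(cy - new_h / 2.0))
    x = max(x, 0)
    y = max(y, 0)
    new_w = min(new_w, image_w - x)
    new_h = min(new_h, image_h - y)
    return RegionBox(x, y, new_w, new_h)


def preprocess_pipeline(image: np.ndarray,
                        config: PreprocessConfig = PreprocessConfig()
                        ) -> PreprocessResult:
    """Full localisation chain from colour photograph to model-input crop.

    Raises :class:`NoEggError` when nothing survives the effective
    threshold and :class:`NoContrastError` on degenerate images.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) colour image")
    h, w = image.shape[:2]
    gray = to_grayscale(image)
    smoothed = median_filter(gray, config.median_kernel)
    thr = otsu_threshold(smoothed, config.otsu_offset)
    mask = smoothed > thr.T_effective
    if not mask.any():
        raise NoEggError(
            f"no pixel above effective threshold {thr.T_effective}"
        )
    box, _component = largest_foreground_region(mask)
    crop_box = scale_and_clamp_bbox(box, config.bbox_scale, w, h)
    crop = image[crop_box.slices()]  # crop the ORIGINAL colour image
    out = _sk_resize(crop.astype(np.float64),
                     (config.input_size, config.input_size),
                     order=1, anti_aliasing=False, preserve_range=True)
    return PreprocessResult(
        image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        threshold=thr,
        crop_box=crop_box,
    )
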