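"""Seeded synthetic candling-image generator.

Emulates transmission photographs of duck eggs in a dark box at roughly
12-day embryo age, at 1/8 of the original 3840x2160 capture resolution by
default. Each image contains:

* a dark box background,
* one axis-aligned elliptical egg whose interior colour follows a
  class-specific palette — pale amber-yellow for unfertilized eggs,
  tan-brown with prominent brown regions (plus dark foci for early dead
  embryos or a large blackened mass for late ones) for abnormal dead eggs,
  uniform yellow for yolk-dispersed abnormal eggs, and dark red with a
  branching dark vessel network for live embryonated eggs,
* a bright shell-glow annulus at the egg rim where transmitted light
  escapes around the shell edge (all classes), with near-saturated light
  leakage arcs (gray 254-255) on unfertilized eggs,
* one wall-reflection patch (gray 180-200) on the image side opposite the
  egg, spatially separate from the egg and smaller than it,
* Gaussian intensity noise and salt-and-pepper impulse noise, applied last.

Every sample is a pure function of its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import GRAY_WEIGHTS, RegionBox

__all__ = [
    "CLASS_NAMES",
    "ABNORMAL_SUBTYPES",
    "ClassLabel",
    "GeneratorParams",
    "EggSample",
    "luminance_intervals",
    "palettes_disjoint",
    "render_egg_image",
    "generate_dataset",
    "write_dataset",
]

CLASS_NAMES = ("unfertilized", "live", "abnormal")
ABNORMAL_SUBTYPES = ("dead_early", "dead_late", "yolk_dispersed")
_SUBTYPES = ("none",) + ABNORMAL_SUBTYPES


@dataclass(frozen=True)
class ClassLabel:
    """Top-level viability class plus abnormal subtype."""

    value: str
    subtype: str = "none"

    def __post_init__(self):
        if self.value not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.value!r}; expected {CLASS_NAMES}")
        if self.subtype not in _SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype != "none" and self.value != "abnormal":
            raise ValueError("subtypes apply only to the abnormal class")


def _default_palettes() -> dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]:
    # RGB (low, high) corners per appearance; chosen so the three top-level
    # classes occupy disjoint mean-luminance intervals (see luminance_intervals).
    return {
        "unfertilized": ((235, 210, 130), (250, 225, 160)),   # pale amber-yellow
        "live": ((120, 30, 25), (150, 55, 45)),               # dark red
        "abnormal_dead": ((190, 150, 100), (215, 175, 125)),  # tan-brown
        "abnormal_yolk": ((200, 160, 80), (220, 180, 100)),   # uniform yellow
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the renderer. Defaults are the package's study
    conditions; intensity units are 8-bit gray/colour levels."""

    image_width: int = 480
    image_height: int = 270
    egg_axes_range: tuple[tuple[int, int], tuple[int, int]] = ((78, 96), (56, 70))
    class_palettes: dict = field(default_factory=_default_palettes)
    background_gray_range: tuple[int, int] = (8, 22)
    reflection_gray_range: tuple[int, int] = (180, 200)
    leakage_gray_range: tuple[int, int] = (254, 255)
    glow_gray_range: tuple[int, int] = (235, 252)
    glow_width: float = 9.0
    falloff_min: float = 0.92
    reflection_axes: tuple[int, int] = (24, 16)
    vessel_count: int = 4
    vessel_step: int = 60
    vessel_width: int = 2
    spot_count: int = 4
    spot_radius: tuple[int, int] = (3, 8)
    noise_sigma: float = 6.0
    salt_pepper_fraction: float = 0.002
    min_contrast: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("image dimensions must be >= 64")
        if not 0.0 <= self.salt_pepper_fraction <= 0.05:
            raise ValueError("salt_pepper_fraction must lie in [0, 0.05]")
        for name, rng_ in [
            ("background_gray_range", self.background_gray_range),
            ("reflection_gray_range", self.reflection_gray_range),
            ("leakage_gray_range", self.leakage_gray_range),
            ("glow_gray_range", self.glow_gray_range),
        ]:
            lo, hi = rng_
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} must be an interval within [0, 255]")
        for lo, hi in self.class_palettes.values():
            if not all(0 <= a <= b <= 255 for a, b in zip(lo, hi)):
                raise ValueError("palette corners must be intervals within [0, 255]")
        if not 0.0 < self.falloff_min <= 1.0:
            raise ValueError("falloff_min must lie in (0, 1]")
        (a_lo, a_hi), (b_lo, b_hi) = self.egg_axes_range
        if not (0 < a_lo <= a_hi and 0 < b_lo <= b_hi):
            raise ValueError("egg_axes_range must be positive intervals")
        # reflection patch must stay well smaller than any egg so that
        # largest-region selection is meaningful
        if np.pi * np.prod(self.reflection_axes) > 0.25 * np.pi * a_lo * b_lo:
            raise ValueError("reflection patch area exceeds 25% of the egg area")


@dataclass(frozen=True)
class EggSample:
    """One rendered candling image with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    label: ClassLabel
    egg_bbox: RegionBox  # tight box of the rendered ellipse mask
    seed: int


def _lum(rgb) -> float:
    return float(sum(w * c for w, c in zip(GRAY_WEIGHTS, rgb)))


def luminance_intervals(params: GeneratorParams) -> dict[str, tuple[float, float]]:
    """Mean-luminance interval of each top-level class's interior palette,
    including the radial falloff factor (assertable without rendering)."""
    pal = params.class_palettes
    out: dict[str, tuple[float, float]] = {}
    for cls, keys in [
        ("unfertilized", ["unfertilized"]),
        ("live", ["live"]),
        ("abnormal", ["abnormal_dead", "abnormal_yolk"]),
    ]:
        lo = min(_lum(pal[k][0]) for k in keys) * params.falloff_min
        hi = max(_lum(pal[k][1]) for k in keys)
        out[cls] = (lo, hi)
    return out


def palettes_disjoint(params: GeneratorParams) -> bool:
    """True when the three classes' palette luminance intervals do not
    overlap (the class-separability knob for noise-free data)."""
    iv = sorted(luminance_intervals(params).values())
    return all(iv[i][1] < iv[i + 1][0] for i in range(len(iv) - 1))


def _ellipse_radius(h: int, w: int, cx: float, cy: float,
                    a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)


def _draw_vessels(interior: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                  cx: float, cy: float, a: float, b: float,
                  params: GeneratorParams) -> None:
    """Branching random-walk vessel network radiating from an embryo focus."""
    h, w = mask.shape
    fx = cx + rng.uniform(-0.35, 0.35) * a
    fy = cy + rng.uniform(-0.35, 0.35) * b
    colour = np.array([40.0, 10.0, 10.0])
    walkers = [(fx, fy, rng.uniform(0, 2 * np.pi)) for _ in range(params.vessel_count)]
    r = max(1, params.vessel_width // 2)
    for _ in range(params.vessel_step):
        next_walkers = []
        for x, y, theta in walkers:
            theta += rng.normal(0.0, 0.35)
            x += 2.0 * np.cos(theta)
            y += 2.0 * np.sin(theta)
            ix, iy = int(round(x)), int(round(y))
            if not (0 <= ix < w and 0 <= iy < h) or not mask[iy, ix]:
                continue
            interior[max(0, iy - r):iy + r, max(0, ix - r):ix + r] = colour
            if rng.random() < 0.04 and len(next_walkers) + len(walkers) < 24:
                next_walkers.append((x, y, theta + rng.uniform(-1.2, 1.2)))
            next_walkers.append((x, y, theta))
        walkers = next_walkers
        if not walkers:
            break
    # the embryo body at the focus
    rr = _ellipse_radius(h, w, fx, fy, 6.0, 5.0)
    interior[(rr <= 1.0) & mask] = colour


def _paint_spot(interior: np.ndarray, mask: np.ndarray, cx: float, cy: float,
                ax_: float, ay: float, colour) -> None:
    rr = _ellipse_radius(*mask.shape, cx, cy, ax_, ay)
    interior[(rr <= 1.0) & mask] = np.asarray(colour, dtype=np.float64)


def render_egg_image(label: ClassLabel, params: GeneratorParams,
                     seed: int) -> EggSample:
    """Render one labelled candling image, fully determined by `seed`."""
    if not isinstance(label, ClassLabel):
        raise TypeError("label must be a ClassLabel")
    if label.value == "abnormal" and label.subtype == "none":
        raise ValueError("abnormal samples need an explicit subtype")
    rng = np.random.default_rng(seed)
    h, w = params.image_height, params.image_width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = rng.uniform(*params.background_gray_range)

    # --- egg geometry -----------------------------------------------------
    (a_lo, a_hi), (b_lo, b_hi) = params.egg_axes_range
    a = rng.uniform(a_lo, a_hi)
    b = rng.uniform(b_lo, b_hi)
    off_x = rng.choice([-1, 1]) * rng.uniform(18, 40)
    off_y = rng.choice([-1, 1]) * rng.uniform(6, 14)
    cx = w / 2.0 + off_x
    cy = h / 2.0 + off_y
    r = _ellipse_radius(h, w, cx, cy, a, b)
    mask = r <= 1.0

    # --- interior colour --------------------------------------------------
    if label.value == "abnormal" and label.subtype == "yolk_dispersed":
        key = "abnormal_yolk"
    elif label.value == "abnormal":
        key = "abnormal_dead"
    else:
        key = label.value
    lo, hi = params.class_palettes[key]
    base = rng.uniform(lo, hi)  # one base colour per egg
    interior = np.empty((h, w, 3), dtype=np.float64)
    interior[:] = base
    interior += rng.normal(0.0, 2.0, size=(h, w, 1))  # gentle mottling
    # radial brightness falloff of the transmitted light
    falloff = 1.0 - (1.0 - params.falloff_min) * np.clip(r, 0.0, 1.0) ** 2
    interior *= falloff[..., None]

    # --- class-specific structure ----------------------------------------
    if label.value == "live":
        _draw_vessels(interior, mask, rng, cx, cy, a, b, params)
    elif label.subtype == "dead_early":
        n_spots = max(1, int(rng.integers(params.spot_count - 1, params.spot_count + 2)))
        for _ in range(n_spots):
            sx = cx + rng.uniform(-0.5, 0.5) * a
            sy = cy + rng.uniform(-0.5, 0.5) * b
            rad = rng.uniform(*params.spot_radius)
            shade = rng.uniform(0.0, 1.0)
            colour = (1 - shade) * np.array([80, 15, 12]) + shade * np.array([30, 18, 15])
            _paint_spot(interior, mask, sx, sy, rad, rad, colour)
    elif label.subtype == "dead_late":
        _paint_spot(interior, mask,
                    cx + rng.uniform(-0.15, 0.15) * a,
                    cy + rng.uniform(-0.15, 0.15) * b,
                    0.5 * a, 0.5 * b, (35, 22, 18))
    if label.value == "abnormal" and label.subtype != "yolk_dispersed":
        # prominent brown regions on the tan-brown field
        for _ in range(int(rng.integers(2, 5))):
            _paint_spot(interior, mask,
                        cx + rng.uniform(-0.6, 0.6) * a,
                        cy + rng.uniform(-0.6, 0.6) * b,
                        rng.uniform(0.12, 0.25) * a, rng.uniform(0.12, 0.25) * b,
                        rng.uniform((110, 60, 35), (140, 85, 55)))

    # --- shell glow annulus ----------------------------------------------
    glow_r0 = 1.0 - params.glow_width / ((a + b) / 2.0)
    band = (r >= glow_r0) & mask
    # ramp over the inner half of the band, full glow over the outer half,
    # so the bright rim is wide enough to survive median filtering
    t = np.clip(1.8 * (r - glow_r0) / (1.0 - glow_r0), 0.0, 1.0)
    glow_gray = rng.uniform(*params.glow_gray_range, size=(h, w))
    for c in range(3):
        ch = interior[..., c]
        ch[band] = (1 - t[band]) * ch[band] + t[band] * glow_gray[band]

    img[mask] = interior[mask]

    # --- light leakage arcs (unfertilized) --------------------------------
    if label.value == "unfertilized":
        theta = np.arctan2((np.mgrid[0:h, 0:w][0] - cy) / b,
                           (np.mgrid[0:h, 0:w][1] - cx) / a)
        rim = (r >= 0.96) & mask
        for _ in range(int(rng.integers(2, 5))):
            centre = rng.uniform(-np.pi, np.pi)
            width = rng.uniform(0.2, 0.6)
            delta = np.angle(np.exp(1j * (theta - centre)))
            arc = rim & (np.abs(delta) < width)
            img[arc] = rng.uniform(*params.leakage_gray_range,
                                   size=(h, w, 1))[arc]

    # --- wall reflection patch, opposite the egg --------------------------
    ra, rb = params.reflection_axes
    ref_cx = w - (ra + 16.0) if off_x < 0 else ra + 16.0
    ref_cy = float(np.clip(h - cy + rng.uniform(-8, 8), rb + 4, h - rb - 4))
    ref_mask = _ellipse_radius(h, w, ref_cx, ref_cy, ra, rb) <= 1.0
    img[ref_mask] = rng.integers(params.reflection_gray_range[0],
                                 params.reflection_gray_range[1] + 1,
                                 size=(h, w, 1)).astype(np.float64)[ref_mask]

    # --- noise, applied last ---------------------------------------------
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    if params.salt_pepper_fraction > 0:
        n_imp = int(round(params.salt_pepper_fraction * h * w))
        ys = rng.integers(0, h, n_imp)
        xs = rng.integers(0, w, n_imp)
        img[ys, xs] = rng.choice([0.0, 255.0], size=(n_imp, 1))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    sample = EggSample(image=image, label=label,
                       egg_bbox=RegionBox.from_mask(mask), seed=int(seed))
    _check_contrast(sample, params, key)
    return sample


def _check_contrast(sample: EggSample, params: GeneratorParams, key: str) -> None:
    lo_lum = _lum(params.class_palettes[key][0]) * params.falloff_min
    bg_hi = params.background_gray_range[1]
    if lo_lum - bg_hi < params.min_contrast:
        raise ValueError(
            f"palette {key!r} too dark: interior-background contrast "
            f"{lo_lum - bg_hi:.1f} below the required {params.min_contrast}"
        )


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _normalise_counts(n_per_class) -> list[tuple[ClassLabel, int]]:
    out = []
    for key, count in n_per_class.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        label = key if isinstance(key, ClassLabel) else ClassLabel(key)
        out.append((label, int(count)))
    return out


def generate_dataset(n_per_class, params: GeneratorParams, seed: int
                     ) -> tuple[list[EggSample], pd.DataFrame]:
    """Render a labelled dataset plus its manifest table.

    `n_per_class` maps class names (or ClassLabel instances) to counts.
    Abnormal samples requested without an explicit subtype cycle
    deterministically through the three subtypes. Per-sample seeds derive
    from the master seed, so equal calls give identical datasets.
    """
    requests = _normalise_counts(n_per_class)
    total = sum(c for _, c in requests)
    seeds = _spawn_seeds(seed, total)
    samples: list[EggSample] = []
    rows = []
    i = 0
    for label, count in requests:
        for j in range(count):
            lab = label
            if lab.value == "abnormal" and lab.subtype == "none":
                lab = ClassLabel("abnormal", ABNORMAL_SUBTYPES[j % len(ABNORMAL_SUBTYPES)])
            s = render_egg_image(lab, params, seeds[i])
            samples.append(s)
            rows.append({
                "path": f"{lab.value}/{lab.value}_{lab.subtype}_{j:04d}.png",
                "class": lab.value,
                "subtype": lab.subtype,
                "seed": s.seed,
                "x": s.egg_bbox.x, "y": s.egg_bbox.y,
                "w": s.egg_bbox.w, "h": s.egg_bbox.h,
            })
            i += 1
    return samples, pd.DataFrame(rows, columns=["path", "class", "subtype",
                                                "seed", "x", "y", "w", "h"])


def write_dataset(samples: list[EggSample], manifest: pd.DataFrame,
                  out_dir) -> pd.DataFrame:
    """Write PNGs and the manifest CSV under `out_dir`; returns the manifest
    with paths resolved."""
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(out_dir)
    for sample, path in zip(samples, manifest["path"]):
        target = out_dir / path
        target.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(target, sample.image)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
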