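"""Augmentation chain and class-balancing upsampling.

The chain applies, in order: random integer translation, random rotation
about the image centre (bilinear), and additive Gaussian pixel noise on the
[0,1] intensity scale, clipped back to [0,1].  Defaults are shifts in
[-10, +10] px per axis, angles in [-15, +15] degrees, and noise with mean 0
and variance 0.1.  Shift and angle are drawn uniformly from their ranges.

Class balancing upsamples every class to the size of the largest class by
appending augmented copies of uniformly resampled originals; originals are
never modified or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .synthetic_data import LabeledImage


@dataclass(frozen=True)
class AugmentConfig:
    shift_range: int = 10          # max |shift| in pixels, per axis
    rotation_range: float = 15.0   # max |angle| in degrees
    noise_mean: float = 0.0
    noise_var: float = 0.1         # variance on the [0,1] intensity scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_range < 0:
            raise ValueError("shift_range must be >= 0")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")


# ---------------------------------------------------------------------------
# deterministic kernels (exposed so forced-parameter behaviour is testable)
# ---------------------------------------------------------------------------

def translate(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift by ``dx`` columns (+right) and ``dy`` rows (+down), zero fill."""
    out = np.zeros_like(image)
    h, w = image.shape[:2]
    xs0, xs1 = min(max(0, dx), w), max(min(w, w + dx), 0)
    ys0, ys1 = min(max(0, dy), h), max(min(h, h + dy), 0)
    if xs0 < xs1 and ys0 < ys1:
        out[ys0:ys1, xs0:xs1, ...] = image[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx, ...]
    return out


def rotate(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image centre by ``angle`` degrees (positive =
    clockwise in display orientation), bilinear resampling, zero fill,
    output size unchanged."""
    if angle == 0.0:
        return image.copy()
    out = ndimage.rotate(image, -angle, axes=(1, 0), reshape=False,
                         order=1, mode="constant", cval=0.0, prefilter=False)
    return np.clip(out, 0.0, 1.0).astype(image.dtype, copy=False)


# ---------------------------------------------------------------------------
# random operators
# ---------------------------------------------------------------------------

def random_translate(image: np.ndarray, shift_range: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Integer shifts dx, dy drawn independently, uniformly from
    [-shift_range, +shift_range]."""
    if shift_range < 0:
        raise ValueError("shift_range must be >= 0")
    dx = int(rng.integers(-shift_range, shift_range + 1))
    dy = int(rng.integers(-shift_range, shift_range + 1))
    if dx == 0 and dy == 0:
        return image.copy()
    return translate(image, dx, dy)


def random_rotate(image: np.ndarray, rotation_range: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Angle drawn uniformly from [-rotation_range, +rotation_range] degrees."""
    if rotation_range < 0:
        raise ValueError("rotation_range must be >= 0")
    angle = float(rng.uniform(-rotation_range, rotation_range))
    if rotation_range == 0.0:
        return image.copy()
    return rotate(image, angle)


def add_gaussian_noise(image: np.ndarray, mean: float, var: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. per-pixel N(mean, var) noise, clip to [0,1]."""
    if var < 0:
        raise ValueError("variance must be >= 0")
    if var == 0 and mean == 0:
        return image.copy()
    noise = rng.normal(mean, np.sqrt(var), size=image.shape)
    return np.clip(image + noise, 0.0, 1.0).astype(image.dtype, copy=False)


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Translation, then rotation, then Gaussian noise, in that order."""
    out = random_translate(image, config.shift_range, rng)
    out = random_rotate(out, config.rotation_range, rng)
    out = add_gaussian_noise(out, config.noise_mean, config.noise_var, rng)
    return out


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def balance_classes(items: list[LabeledImage], task: str, config: AugmentConfig,
                    rng: np.random.Generator,
                    n_classes: int | None = None) -> list[LabeledImage]:
    """Upsample every class to the maximum class count with augmented copies.

    Originals are retained unmodified and come first in the returned list.
    Copies carry the original's labels, an id suffixed ``_augK``, and no mask
    (the spatial transforms would invalidate it).
    """
    if not items:
        raise ValueError("dataset is empty")
    for it in items:
        if task not in it.labels:
            raise ValueError(f"sample {it.id!r} has no {task!r} label")
    by_class: dict[int, list[LabeledImage]] = {}
    for it in items:
        by_class.setdefault(it.labels[task], []).append(it)
    if n_classes is not None:
        missing = [c for c in range(n_classes) if c not in by_class]
        if missing:
            raise ValueError(f"classes with zero samples cannot be balanced: {missing}")
    target = max(len(v) for v in by_class.values())
    out = list(items)
    for class_id in sorted(by_class):
        members = by_class[class_id]
        for k in range(target - len(members)):
            src = members[int(rng.integers(len(members)))]
            out.append(replace(
                src,
                image=augment(src.image, config, rng),
                mask=None,
                labels=dict(src.labels),
                id=f"{src.id}_aug{k}",
                meta={"augmented_from": src.id},
            ))
    return out
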