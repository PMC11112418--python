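"""Attention-map heatmap overlays.

An attention map is bilinearly upsampled to the image grid, min-max
normalized per image, converted to an RGB heatmap through a fixed 256-entry
JET lookup table (0 -> blue, 0.5 -> green/yellow, 1 -> red), and alpha-blended
onto the input image.  The JET table is computed from the classic piecewise-
linear formula so output is identical across platforms:

    r(v) = clip(1.5 - |4v - 3|, 0, 1)
    g(v) = clip(1.5 - |4v - 2|, 0, 1)
    b(v) = clip(1.5 - |4v - 1|, 0, 1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import bilinear_resize


@dataclass(frozen=True)
class OverlayConfig:
    upsample_factor: int = 4    # 4 for the B2 map, 16 for the B4 map
    alpha: float = 0.5          # blend weight of the heatmap
    colormap: str = "jet"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.colormap != "jet":
            raise ValueError("only the 'jet' colormap is provided")


def _make_jet_lut() -> np.ndarray:
    v = np.linspace(0.0, 1.0, 256)
    r = np.clip(1.5 - np.abs(4 * v - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * v - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * v - 1), 0, 1)
    return np.stack([r, g, b], axis=1)


JET_LUT: np.ndarray = _make_jet_lut()


def upsample_map(attention: np.ndarray, factor: int) -> np.ndarray:
    """Bilinearly upsample an h x w map by an integer factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    a = np.asarray(attention, dtype=np.float32)
    if factor == 1:
        return a.copy()
    h, w = a.shape
    return bilinear_resize(a, (h * factor, w * factor))


def normalize_map(attention: np.ndarray) -> np.ndarray:
    """Affine rescale to [0,1]; a constant map maps to all 0.5."""
    a = np.asarray(attention, dtype=np.float64)
    if not np.isfinite(a).all():
        raise ValueError("attention map contains non-finite values")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)


def apply_colormap(attention: np.ndarray) -> np.ndarray:
    """Map a [0,1] h x w array to an h x w x 3 JET heatmap."""
    a = np.asarray(attention, dtype=np.float64)
    if a.min() < 0 or a.max() > 1:
        warnings.warn("attention values outside [0,1] were clipped", stacklevel=2)
        a = np.clip(a, 0, 1)
    idx = np.clip((a * 255.0 + 0.5).astype(int), 0, 255)
    return JET_LUT[idx]


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend: (1 - alpha) * image + alpha * heatmap, clipped to [0,1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if image.shape[:2] != heatmap.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and heatmap "
                         f"{heatmap.shape[:2]} sizes differ")
    return np.clip((1.0 - alpha) * image + alpha * heatmap, 0.0, 1.0)


def attention_overlay(image: np.ndarray, attention: np.ndarray,
                      config: OverlayConfig = OverlayConfig()) -> np.ndarray:
    """Full pipeline: upsample -> normalize -> JET -> blend onto the image."""
    up = upsample_map(attention, config.upsample_factor)
    if up.shape != image.shape[:2]:
        up = bilinear_resize(up.astype(np.float32), image.shape[:2])
    return overlay(image, apply_colormap(normalize_map(up)), config.alpha)


def panel(image: np.ndarray, attention_b2: np.ndarray, attention_b4: np.ndarray,
          alpha: float = 0.5) -> np.ndarray:
    """Side-by-side panel: original | B2 overlay | B4 overlay."""
    h, w = image.shape[:2]
    f2 = max(1, h // attention_b2.shape[0])
    f4 = max(1, h // attention_b4.shape[0])
    o2 = attention_overlay(image, attention_b2, OverlayConfig(upsample_factor=f2, alpha=alpha))
    o4 = attention_overlay(image, attention_b4, OverlayConfig(upsample_factor=f4, alpha=alpha))
    return np.concatenate([image, o2, o4], axis=1)
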