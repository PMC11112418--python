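"""Procedural generator of labeled tongue-like images with ground-truth masks.

Each rendered image contains a single ellipse-like "tongue" region on a
distractor background, with class-conditional appearance for one of three
tasks drawn from the standard TCM tongue-inspection vocabulary:

* ``color`` — 3 classes: Pale Red / Red / Dark Red (foreground hue/value);
* ``shape`` — 2 classes: Swollen / Non-Swollen (width-to-height ratio and
  boundary scalloping, i.e. tooth-mark-like indentations);
* ``coating`` — 4 classes: White Greasy / Thin White / Thin Yellow /
  Yellow Greasy (a textured film concentrated in the upper, tongue-root
  third of the tongue, whose whiteness/yellowness and density carry the
  class signal).

The generator is fully deterministic under its seed, emits the exact binary
mask of the painted tongue region, and records the analytic boundary geometry
so the raster can be reproduced independently.  Class-conditional colour
distributions are fixed constants with within-class jitter: classes overlap
slightly but remain linearly separable from simple foreground statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

TASKS: dict[str, list[str]] = {
    "color": ["Pale Red", "Red", "Dark Red"],
    "shape": ["Swollen", "Non-Swollen"],
    "coating": ["White Greasy", "Thin White", "Thin Yellow", "Yellow Greasy"],
}

# class-conditional mean RGB of the tongue body (colour task)
_COLOR_MEANS = {
    0: (0.87, 0.62, 0.62),   # Pale Red: high value, desaturated
    1: (0.78, 0.36, 0.40),   # Red: saturated mid red
    2: (0.50, 0.16, 0.24),   # Dark Red: low value, deep red
}
_GENERIC_BODY = (0.78, 0.42, 0.45)   # body colour for shape/coating tasks

# coating film: (RGB, coverage density, blend alpha) per coating class
_COATING_STYLE = {
    0: ((0.93, 0.91, 0.86), 0.85, 0.85),   # White Greasy: dense white film
    1: ((0.93, 0.91, 0.86), 0.30, 0.55),   # Thin White: sparse white film
    2: ((0.88, 0.80, 0.38), 0.30, 0.55),   # Thin Yellow: sparse yellow film
    3: ((0.88, 0.80, 0.38), 0.85, 0.85),   # Yellow Greasy: dense yellow film
}

_LIP_COLORS = [(0.72, 0.45, 0.45), (0.62, 0.38, 0.36), (0.82, 0.60, 0.55),
               (0.55, 0.42, 0.40), (0.75, 0.55, 0.50)]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic dataset draw."""

    image_size: tuple[int, int] = (224, 224)   # (H, W), both divisible by 32
    n_per_class: int = 10
    task: str = "coating"
    background_kind: str = "cluttered"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h % 32 or w % 32:
            raise ValueError(f"image_size must be divisible by 32, got {h}x{w}")
        if h < 64 or w < 64:
            raise ValueError(f"image_size must be at least 64x64, got {h}x{w}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {sorted(TASKS)}")
        if self.background_kind not in ("plain", "cluttered"):
            raise ValueError(f"background_kind must be 'plain' or 'cluttered'")

    @property
    def n_classes(self) -> int:
        return len(TASKS[self.task])


@dataclass
class LabeledImage:
    """An RGB image with optional mask and per-task integer labels."""

    image: np.ndarray                      # HxWx3 float32 in [0,1]
    mask: np.ndarray | None                # HxW uint8 in {0,1}, or None
    labels: dict[str, int]
    id: str
    meta: dict = field(default_factory=dict)


def scalloped_ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                           amp: float = 0.0, lobes: int = 0, phase: float = 0.0) -> np.ndarray:
    """Rasterize an ellipse whose boundary radius is modulated by a sinusoid.

    A point belongs to the region when its normalized elliptical radius
    ``r = sqrt(((x-cx)/a)^2 + ((y-cy)/b)^2)`` satisfies
    ``r <= 1 + amp * sin(lobes * theta + phase)``.  ``amp = 0`` gives the
    plain ellipse.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) / a
    dy = (yy - cy) / b
    r = np.sqrt(dx * dx + dy * dy)
    bound = 1.0 + amp * np.sin(lobes * np.arctan2(dy, dx) + phase)
    return (r <= bound).astype(np.uint8)


def _background(h: int, w: int, kind: str, rng: np.random.Generator) -> np.ndarray:
    base = np.array([0.32, 0.26, 0.27]) + rng.normal(0, 0.02, 3)
    img = np.empty((h, w, 3), dtype=np.float64)
    grad = np.linspace(0.85, 1.1, h)[:, None]
    for c in range(3):
        img[..., c] = base[c] * grad
    if kind == "cluttered":
        # random elliptical blobs mimicking lips / jaw / skin patches
        for _ in range(int(rng.integers(3, 8))):
            col = np.array(_LIP_COLORS[int(rng.integers(len(_LIP_COLORS)))])
            col = col + rng.normal(0, 0.03, 3)
            bc = scalloped_ellipse_mask(
                h, w,
                cx=float(rng.uniform(0, w)), cy=float(rng.uniform(0, h)),
                a=float(rng.uniform(0.08, 0.30) * w), b=float(rng.uniform(0.05, 0.18) * h),
            ).astype(bool)
            img[bc] = 0.6 * img[bc] + 0.4 * col
    img += rng.normal(0, 0.015, img.shape)
    return np.clip(img, 0, 1)


def render_tongue(spec: SyntheticSpec, class_id: int,
                  rng: np.random.Generator) -> LabeledImage:
    """Render one labeled tongue image with its exact binary mask.

    The class signal is painted strictly inside the emitted mask; the mask is
    the raster of an analytically defined (possibly scalloped) ellipse whose
    parameters are recorded in ``meta["geometry"]``.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} invalid for task {spec.task!r} "
                         f"({spec.n_classes} classes)")
    h, w = spec.image_size
    img = _background(h, w, spec.background_kind, rng)

    # --- tongue geometry ---------------------------------------------------
    cy = h * float(rng.uniform(0.48, 0.56))
    cx = w * float(rng.uniform(0.46, 0.54))
    b = h * float(rng.uniform(0.30, 0.36))          # vertical semi-axis
    amp, lobes, phase = 0.0, 0, 0.0
    if spec.task == "shape":
        if class_id == 0:                            # Swollen: wide, scalloped
            aspect = float(rng.normal(1.18, 0.05))
            amp = float(rng.uniform(0.05, 0.08))
            lobes = int(rng.integers(8, 12))
            phase = float(rng.uniform(0, 2 * np.pi))
        else:                                        # Non-Swollen: slim, smooth
            aspect = float(rng.normal(0.70, 0.05))
            amp = float(rng.uniform(0.0, 0.015))
            lobes = int(rng.integers(8, 12))
            phase = float(rng.uniform(0, 2 * np.pi))
    else:
        aspect = float(rng.normal(0.85, 0.06))
    a = min(b * aspect, 0.47 * w)                    # horizontal semi-axis
    mask = scalloped_ellipse_mask(h, w, cx, cy, a, b, amp, lobes, phase)
    inside = mask.astype(bool)

    # --- tongue body colour ------------------------------------------------
    if spec.task == "color":
        body = np.array(_COLOR_MEANS[class_id])
    else:
        body = np.array(_GENERIC_BODY)
    body = body + rng.normal(0, 0.025, 3)

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    shade = np.clip(1.0 - 0.22 * r, 0.6, 1.0)        # radial shading
    tongue = np.clip(body[None, None, :] * shade[..., None], 0, 1)
    img[inside] = tongue[inside]

    # --- coating film (coating task only) ----------------------------------
    coating_mask = np.zeros((h, w), dtype=np.uint8)
    if spec.task == "coating":
        color, density, alpha = _COATING_STYLE[class_id]
        color = np.array(color) + rng.normal(0, 0.02, 3)
        top = cy - b
        root_rows = yy < top + (2.0 * b) / 3.0       # upper third of the tongue
        region = inside & root_rows
        if region.any():
            field_ = gaussian_filter(rng.normal(size=(h, w)), 2.0)
            thr = np.quantile(field_[region], 1.0 - density)
            coat = region & (field_ >= thr)
            coating_mask[coat] = 1
            img[coat] = (1 - alpha) * img[coat] + alpha * color

    img += rng.normal(0, 0.01, img.shape)            # sensor noise
    img = np.clip(img, 0, 1).astype(np.float32)

    return LabeledImage(
        image=img,
        mask=mask,
        labels={spec.task: class_id},
        id="",
        meta={
            "geometry": {"cx": cx, "cy": cy, "a": a, "b": b,
                         "amp": amp, "lobes": lobes, "phase": phase},
            "coating_mask": coating_mask if spec.task == "coating" else None,
        },
    )


def generate_dataset(spec: SyntheticSpec,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate ``n_per_class`` images per class; optionally write PNG + CSV.

    The per-image RNG is seeded by ``(spec.seed, class_id, index)`` so output
    is bit-identical for identical specs and independent of generation order.
    """
    items: list[LabeledImage] = []
    rows = []
    for class_id in range(spec.n_classes):
        for i in range(spec.n_per_class):
            rng = np.random.default_rng([spec.seed, class_id, i])
            item = render_tongue(spec, class_id, rng)
            item.id = f"{spec.task}_{class_id}_{i:04d}"
            items.append(item)
            row = {"id": item.id, "color": "", "shape": "", "coating": ""}
            row[spec.task] = class_id
            rows.append(row)
    table = pd.DataFrame(rows, columns=["id", "color", "shape", "coating"])
    if out_dir is not None:
        write_dataset(items, table, out_dir)
    return items, table


def write_dataset(items: list[LabeledImage], table: pd.DataFrame,
                  out_dir: str | Path) -> None:
    """Write images/ and masks/ PNG trees plus labels.csv under ``out_dir``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for item in items:
        save_image(item.image, out / "images" / f"{item.id}.png")
        if item.mask is not None:
            save_mask(item.mask, out / "masks" / f"{item.id}.png")
    table.to_csv(out / "labels.csv", index=False)


# ---------------------------------------------------------------------------
# PNG round-tripping (8-bit RGB images, {0,255} single-channel masks)
# ---------------------------------------------------------------------------

def save_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def image_checksum(image: np.ndarray) -> str:
    """SHA-256 of the 8-bit quantized image; used for byte-identity checks."""
    arr = np.clip(np.asarray(image, dtype=np.float64) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    return hashlib.sha256(arr.tobytes()).hexdigest()
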