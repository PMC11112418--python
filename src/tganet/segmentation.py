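"""U-Net tongue segmentation and mask utilities.

The network is a standard encoder-decoder with skip connections: each encoder
level applies two 3x3 convolutions (ReLU) and a 2x2 max-pool, doubling the
channel count per level; the decoder mirrors it with nearest 2x upsampling
followed by a 3x3 convolution, concatenation of the matching encoder feature,
and two further convolutions.  "Same" padding is used throughout so skips
align without cropping.  A final 1x1 convolution plus sigmoid produces a
per-pixel tongue probability, trained with pixel-wise binary cross-entropy.

Defaults (depth 4, base width 32) are sized for CPU training; both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .nn import F32


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4            # number of encoder levels (pooling steps)
    base_channels: int = 32   # channels at the first level; doubles per level
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")


class _DoubleConv:
    """conv3x3-ReLU-conv3x3-ReLU block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.r2 = nn.ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x, cache=True):
        x = self.r1.forward(self.c1.forward(x, cache), cache)
        return self.r2.forward(self.c2.forward(x, cache), cache)

    def backward(self, g):
        g = self.c2.backward(self.r2.backward(g))
        return self.c1.backward(self.r1.backward(g))


class UNet:
    """Encoder-decoder segmentation network mapping HxWx3 to an HxW
    probability map, for any H, W divisible by 2**depth."""

    def __init__(self, config: UNetConfig = UNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, c0 = config.depth, config.base_channels
        chans = [c0 * 2 ** i for i in range(d)]
        self.enc = []
        cin = config.in_channels
        for c in chans:
            self.enc.append((_DoubleConv(cin, c, rng), nn.MaxPool2x2()))
            cin = c
        self.bottleneck = _DoubleConv(cin, c0 * 2 ** d, rng)
        self.dec = []
        cup = c0 * 2 ** d
        for c in reversed(chans):
            up = nn.Upsample2x()
            upconv = nn.Conv2d(cup, c, 3, rng)
            merge = _DoubleConv(2 * c, c, rng)
            self.dec.append((up, upconv, merge))
            cup = c
        self.head = nn.Conv2d(c0, config.out_channels, 1, rng)

    @property
    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for block, _ in self.enc:
            ps += block.params
        ps += self.bottleneck.params
        for _, upconv, merge in self.dec:
            ps += upconv.params + merge.params
        ps += self.head.params
        return ps

    def _check_size(self, h: int, w: int) -> None:
        f = 2 ** self.config.depth
        if h % f or w % f:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 2**depth = {f} "
                f"(each encoder level halves the resolution)")

    def forward_logits(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        """NCHW float input -> NCHW logits (C=1)."""
        self._check_size(x.shape[2], x.shape[3])
        skips = []
        for block, pool in self.enc:
            x = block.forward(x, cache)
            skips.append(x)
            x = pool.forward(x, cache)
        x = self.bottleneck.forward(x, cache)
        self._relu_dec = []
        for (up, upconv, merge), skip in zip(self.dec, reversed(skips)):
            x = upconv.forward(up.forward(x, cache), cache)
            r = nn.ReLU()
            x = r.forward(x, cache)
            self._relu_dec.append(r)
            x = merge.forward(np.concatenate([skip, x], axis=1), cache)
        return self.head.forward(x, cache)

    def backward(self, gy: np.ndarray) -> None:
        g = self.head.backward(gy)
        gskips: list[np.ndarray] = []
        for (up, upconv, merge), r in zip(reversed(self.dec), self._relu_dec[::-1]):
            g = merge.backward(g)
            c = g.shape[1] // 2
            gskips.append(g[:, :c])          # gradient into the skip connection
            g = up.backward(upconv.backward(r.backward(g[:, c:])))
        g = self.bottleneck.backward(g)
        # gskips was filled shallowest-first; encoder unwinds deepest-first
        for (block, pool), gskip in zip(reversed(self.enc), gskips[::-1]):
            g = pool.backward(g) + gskip
            g = block.backward(g)


def build_unet(config: UNetConfig = UNetConfig(), seed: int = 0) -> UNet:
    """Construct a Kaiming-initialized U-Net for the given configuration."""
    return UNet(config, seed)


# ---------------------------------------------------------------------------
# inference / mask post-processing
# ---------------------------------------------------------------------------

def predict_probs(model: UNet, image: np.ndarray) -> np.ndarray:
    """HxWx3 image in [0,1] -> HxW tongue probability map in [0,1]."""
    x = np.ascontiguousarray(image.transpose(2, 0, 1))[None].astype(F32)
    logits = model.forward_logits(x - 0.5, cache=False)
    return nn.sigmoid(logits[0, 0])


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map and keep only the largest connected
    component (exactly one tongue is expected per image)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    raw = probs >= threshold
    if not raw.any():
        return np.zeros(probs.shape, dtype=np.uint8)
    lab, n = ndimage.label(raw)
    if n == 1:
        return raw.astype(np.uint8)
    sizes = ndimage.sum_labels(raw, lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (lab == keep).astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out every pixel outside the mask (black background)."""
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} differ")
    m = (np.asarray(mask) > 0).astype(image.dtype)
    return image * (m[..., None] if image.ndim == 3 else m)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    for m in (a, b):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("masks must be binary (values in {0, 1})")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_unet(model: UNet, images: list[np.ndarray], masks: list[np.ndarray],
               epochs: int, lr: float, rng: np.random.Generator,
               batch_size: int = 4) -> tuple[UNet, list[float]]:
    """Optimize pixel-wise binary cross-entropy with Adam.

    ``images`` are HxWx3 arrays in [0,1] and ``masks`` the matching HxW
    binary ground truths.  Returns the model (trained in place) and the
    per-epoch mean loss history; ``epochs == 0`` returns the model unchanged
    with an empty history.
    """
    if len(images) != len(masks) or any(m is None for m in masks):
        raise ValueError("every training image needs a ground-truth mask")
    if len({im.shape for im in images}) > 1:
        raise ValueError("all training images must share one size")
    if epochs == 0:
        return model, []
    x = np.stack([im.transpose(2, 0, 1) for im in images]).astype(F32) - 0.5
    t = np.stack(masks).astype(F32)[:, None]
    opt = nn.Adam(model.params, lr=lr)
    history: list[float] = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            opt.zero_grad()
            logits = model.forward_logits(x[idx])
            loss, dz = nn.sigmoid_bce_with_logits(logits, t[idx])
            model.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    if not all(np.isfinite(history)):
        raise RuntimeError("training diverged: non-finite loss")
    return model, history


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_unet(model: UNet, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    cfg = model.config
    np.savez(path, __config__=np.array([cfg.depth, cfg.base_channels,
                                        cfg.in_channels, cfg.out_channels]),
             **arrays)


def load_unet(path: str | Path) -> UNet:
    data = np.load(path)
    d, c0, cin, cout = (int(v) for v in data["__config__"])
    model = UNet(UNetConfig(depth=d, base_channels=c0,
                            in_channels=cin, out_channels=cout))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
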