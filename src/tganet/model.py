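"""TGANet: attention-gated CNN for tongue feature classification.

The backbone is the first five convolutional blocks of VGG16 (layer plan
2,2,3,3,3 convolutions of kernel 3; channels 64,128,256,512,512; each block
ends in 2x2 max-pooling) with every fully connected layer removed.  Two
attention modules gate the intermediate features tapped from the pooling
layers of blocks B2 and B4 against the global feature G from B5's pooling
layer:

    U  = W_F * F + UP(W_G * G)          (1x1 projections to 256 channels;
                                         UP = bilinear upsampling to F's size)
    A  = sigmoid(conv(relu(U)))         (3x3 conv to a single-channel map)
    F' = A (.) proj(F)                  (pixel-wise gating, A broadcast)

Each attention feature F' is global-average-pooled to a 256-vector, G to a
512-vector; the concatenated 1024-vector feeds one linear layer and softmax.
A ``width_multiplier`` scales every channel count uniformly so the same
architecture trains at desk scale on a CPU; attention parameters are
Kaiming-initialized.  Loading ImageNet-pretrained backbone weights is an
explicit checkpoint-file load — the library never downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import F32

VGG_PLAN: list[tuple[int, int]] = [(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)]
ATTENTION_CHANNELS = 256


def _scaled(c: int, width_multiplier: float) -> int:
    return max(1, round(c * width_multiplier))


@dataclass
class FeatureBundle:
    """Backbone taps: F2 from B2's pool, F4 from B4's pool, G from B5's pool."""
    F2: np.ndarray   # (N, C2, H/4,  W/4)
    F4: np.ndarray   # (N, C4, H/16, W/16)
    G: np.ndarray    # (N, CG, H/32, W/32)


@dataclass
class AttentionResult:
    """One attention branch's output: map A in (0,1) and gated feature F'."""
    A: np.ndarray        # (N, 1, h, w)
    F_prime: np.ndarray  # (N, att_c, h, w)


@dataclass
class Prediction:
    logits: np.ndarray          # (N, n_classes)
    probs: np.ndarray           # softmax of logits, rows sum to 1
    attention_b2: np.ndarray    # (N, 1, H/4,  W/4)
    attention_b4: np.ndarray    # (N, 1, H/16, W/16)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class Backbone:
    """Truncated VGG16: blocks B1-B5, no fully connected layers."""

    def __init__(self, width_multiplier: float = 1.0, seed: int = 0,
                 in_channels: int = 3):
        if not 0.0 < width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        rng = np.random.default_rng(seed)
        self.width_multiplier = width_multiplier
        self.channels = [_scaled(c, width_multiplier) for _, c in VGG_PLAN]
        self.blocks: list[list[tuple[nn.Conv2d, nn.ReLU]]] = []
        self.pools: list[nn.MaxPool2x2] = []
        cin = in_channels
        for (n_convs, _), cout in zip(VGG_PLAN, self.channels):
            layers = []
            for _ in range(n_convs):
                layers.append((nn.Conv2d(cin, cout, 3, rng), nn.ReLU()))
                cin = cout
            self.blocks.append(layers)
            self.pools.append(nn.MaxPool2x2())

    @property
    def params(self) -> list[nn.Param]:
        return [p for block in self.blocks for conv, _ in block for p in conv.params]

    def _check_size(self, h: int, w: int) -> None:
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32 "
                             f"(five 2x pooling stages)")

    def forward(self, x: np.ndarray, cache: bool = True) -> FeatureBundle:
        """NCHW input -> pooled features from B2 (F2), B4 (F4) and B5 (G)."""
        self._check_size(x.shape[2], x.shape[3])
        taps: dict[int, np.ndarray] = {}
        for i, (block, pool) in enumerate(zip(self.blocks, self.pools)):
            for conv, relu in block:
                x = relu.forward(conv.forward(x, cache), cache)
            x = pool.forward(x, cache)
            if i in (1, 3, 4):
                taps[i] = x
        return FeatureBundle(F2=taps[1], F4=taps[3], G=taps[4])

    def backward(self, dF2: np.ndarray, dF4: np.ndarray, dG: np.ndarray) -> None:
        """Accumulate parameter gradients given gradients at the three taps."""
        g = dG
        for i in range(4, -1, -1):
            g = self.pools[i].backward(g)
            for conv, relu in reversed(self.blocks[i]):
                g = conv.backward(relu.backward(g))
            if i == 4:
                g = g + dF4   # arriving at B4's pool output
            elif i == 2:
                g = g + dF2   # arriving at B2's pool output


def build_backbone(pretrained: bool = False, width_multiplier: float = 1.0,
                   seed: int = 0, checkpoint: str | Path | None = None) -> Backbone:
    """Build B1-B5.  ``pretrained`` loads convolution weights from a local
    ``.npz`` checkpoint with keys ``conv{i}.weight`` / ``conv{i}.bias`` for the
    13 convolutions in order; otherwise weights are Kaiming-initialized.
    """
    if pretrained and width_multiplier != 1.0:
        raise ValueError("pretrained weights require width_multiplier == 1")
    model = Backbone(width_multiplier=width_multiplier, seed=seed)
    if pretrained:
        if checkpoint is None or not Path(checkpoint).exists():
            raise FileNotFoundError(
                "pretrained backbone weights were requested but no checkpoint "
                "file was provided; download an ImageNet-pretrained VGG16 "
                "checkpoint offline (npz with conv{i}.weight / conv{i}.bias) "
                "and pass its path — this library never downloads weights")
        data = np.load(checkpoint)
        convs = [conv for block in model.blocks for conv, _ in block]
        for i, conv in enumerate(convs):
            conv.weight.value[...] = data[f"conv{i}.weight"]
            conv.bias.value[...] = data[f"conv{i}.bias"]
    return model


def extract_features(backbone: Backbone, image: np.ndarray) -> FeatureBundle:
    """Run one HxWx3 [0,1] image (or an NCHW batch) through B1-B5."""
    if image.ndim == 3:
        x = image.transpose(2, 0, 1)[None].astype(F32) - 0.5
    else:
        x = image.astype(F32)
    return backbone.forward(x, cache=False)


# ---------------------------------------------------------------------------
# attention module
# ---------------------------------------------------------------------------

class AttentionModule:
    """Sigmoid attention gate between an intermediate feature and G."""

    def __init__(self, f_channels: int, g_channels: int, att_channels: int,
                 rng: np.random.Generator):
        self.w_f = nn.Conv2d(f_channels, att_channels, 1, rng)   # proj F
        self.w_g = nn.Conv2d(g_channels, att_channels, 1, rng)   # proj G
        self.w_a = nn.Conv2d(att_channels, 1, 3, rng)            # pre-sigmoid map
        self._cache: tuple | None = None

    @property
    def params(self) -> list[nn.Param]:
        return self.w_f.params + self.w_g.params + self.w_a.params

    def forward(self, f: np.ndarray, g: np.ndarray, cache: bool = True) -> AttentionResult:
        p = self.w_f.forward(f, cache)                       # proj(F)
        qs = self.w_g.forward(g, cache)                      # proj(G) at G's size
        q = nn.bilinear_resize(qs, p.shape[2:])              # UP(proj(G))
        u = p + q
        r = np.where(u > 0, u, 0.0).astype(F32)
        z = self.w_a.forward(r, cache)
        a = nn.sigmoid(z)
        f_prime = (a * p).astype(F32)
        assert p.shape[1] == q.shape[1], "projection channel mismatch"
        if cache:
            self._cache = (p, u > 0, a, g.shape[2:])
        return AttentionResult(A=a.astype(F32), F_prime=f_prime)

    def backward(self, d_f_prime: np.ndarray,
                 d_a: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Gradients w.r.t. the branch inputs F and G."""
        p, relu_mask, a, g_hw = self._cache
        self._cache = None
        da = (d_f_prime * p).sum(axis=1, keepdims=True)
        if d_a is not None:
            da = da + d_a
        dp = d_f_prime * a
        dz = da * a * (1.0 - a)
        du = self.w_a.backward(dz.astype(F32)) * relu_mask
        dp = (dp + du).astype(F32)
        dqs = nn.bilinear_resize_backward(du, g_hw).astype(F32)
        return self.w_f.backward(dp), self.w_g.backward(dqs)


def attention_forward(f: np.ndarray, g: np.ndarray,
                      module: AttentionModule) -> AttentionResult:
    """Functional wrapper: gate intermediate feature ``f`` with global ``g``."""
    return module.forward(f, g, cache=False)


# ---------------------------------------------------------------------------
# fusion head
# ---------------------------------------------------------------------------

def fuse_and_classify(f2_prime: np.ndarray, f4_prime: np.ndarray, g: np.ndarray,
                      head: nn.Linear) -> tuple[np.ndarray, np.ndarray]:
    """Global-average-pool each branch and G, concatenate, classify.

    Returns (logits, probs)."""
    vec = np.concatenate([f2_prime.mean(axis=(2, 3)),
                          f4_prime.mean(axis=(2, 3)),
                          g.mean(axis=(2, 3))], axis=1).astype(F32)
    logits = head.forward(vec, cache=False)
    return logits, nn.softmax(logits)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class TGANet:
    """End-to-end attention-gated classifier for one tongue feature task."""

    def __init__(self, n_classes: int, width_multiplier: float = 1.0,
                 seed: int = 0, pretrained: bool = False,
                 checkpoint: str | Path | None = None):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = n_classes
        self.width_multiplier = width_multiplier
        self.backbone = build_backbone(pretrained, width_multiplier,
                                       seed=seed, checkpoint=checkpoint)
        rng = np.random.default_rng((seed, 1))
        att_c = _scaled(ATTENTION_CHANNELS, width_multiplier)
        c2, c4, cg = (self.backbone.channels[i] for i in (1, 3, 4))
        self.att2 = AttentionModule(c2, cg, att_c, rng)
        self.att4 = AttentionModule(c4, cg, att_c, rng)
        self.head = nn.Linear(2 * att_c + cg, n_classes, rng)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[nn.Param]:
        return (self.backbone.params + self.att2.params + self.att4.params
                + self.head.params)

    def forward(self, images: np.ndarray, cache: bool = True) -> Prediction:
        """NCHW [0,1] batch (or one HxWx3 image) -> class prediction with
        both attention maps."""
        if images.ndim == 3:
            images = images.transpose(2, 0, 1)[None]
        x = images.astype(F32) - 0.5
        fb = self.backbone.forward(x, cache)
        r2 = self.att2.forward(fb.F2, fb.G, cache)
        r4 = self.att4.forward(fb.F4, fb.G, cache)
        vec = np.concatenate([r2.F_prime.mean(axis=(2, 3)),
                              r4.F_prime.mean(axis=(2, 3)),
                              fb.G.mean(axis=(2, 3))], axis=1).astype(F32)
        logits = self.head.forward(vec, cache)
        if cache:
            self._cache = (fb, r2, r4)
        return Prediction(logits=logits, probs=nn.softmax(logits),
                          attention_b2=r2.A, attention_b4=r4.A)

    def backward(self, dlogits: np.ndarray) -> None:
        fb, r2, r4 = self._cache
        self._cache = None
        dvec = self.head.backward(dlogits.astype(F32))
        c2 = r2.F_prime.shape[1]
        c4 = c2 + r4.F_prime.shape[1]

        def spread(dv: np.ndarray, like: np.ndarray) -> np.ndarray:
            h, w = like.shape[2:]
            return (np.broadcast_to(dv[:, :, None, None], like.shape)
                    / (h * w)).astype(F32)

        dF2p = spread(dvec[:, :c2], r2.F_prime)
        dF4p = spread(dvec[:, c2:c4], r4.F_prime)
        dG = spread(dvec[:, c4:], fb.G)
        dF2, dG2 = self.att2.backward(dF2p)
        dF4, dG4 = self.att4.backward(dF4p)
        self.backbone.backward(dF2, dF4, (dG + dG2 + dG4).astype(F32))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_tganet(model: TGANet, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path, __config__=np.array([model.n_classes, model.width_multiplier]),
             **arrays)


def load_tganet(path: str | Path) -> TGANet:
    data = np.load(path)
    n_classes, wm = data["__config__"]
    model = TGANet(n_classes=int(n_classes), width_multiplier=float(wm))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
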