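"""TGANet architecture contracts: attention algebra, shapes, gating, softmax."""

import numpy as np
import pytest

from tganet import (AttentionModule, TGANet, attention_forward, build_backbone,
                    extract_features, fuse_and_classify)
from tganet import nn as tnn
from tganet.nn import sigmoid


def _scalar_attention(pf=0.3, pg=0.2):
    """1x1-spatial attention module with hand-set weights: proj(F)=pf,
    UP(proj(G))=pg, gating conv = identity (centre weight 1, bias 0)."""
    rng = np.random.default_rng(0)
    mod = AttentionModule(1, 1, 1, rng)
    mod.w_f.weight.value[...] = pf          # F=1 -> proj(F)=pf
    mod.w_f.bias.value[...] = 0.0
    mod.w_g.weight.value[...] = pg
    mod.w_g.bias.value[...] = 0.0
    mod.w_a.weight.value[...] = 0.0
    mod.w_a.weight.value[0, 0, 1, 1] = 1.0  # 3x3 centre tap
    mod.w_a.bias.value[...] = 0.0
    return mod


def test_attention_scalar_closed_form():
    """Scalar case: U = 0.3 + 0.2 = 0.5, A = sigma(0.5), F' = A * 0.3."""
    mod = _scalar_attention()
    f = np.ones((1, 1, 1, 1), dtype=np.float32)
    g = np.ones((1, 1, 1, 1), dtype=np.float32)
    res = attention_forward(f, g, mod)
    expected_a = 1.0 / (1.0 + np.exp(-0.5))
    assert res.A[0, 0, 0, 0] == pytest.approx(expected_a, abs=1e-6)
    assert res.A[0, 0, 0, 0] == pytest.approx(0.62246, abs=1e-5)
    assert res.F_prime[0, 0, 0, 0] == pytest.approx(expected_a * 0.3, abs=1e-6)
    assert res.F_prime[0, 0, 0, 0] == pytest.approx(0.18674, abs=1e-5)


def test_attention_zero_logits_give_half():
    """Forcing the pre-sigmoid map to zero yields A = 0.5 everywhere and
    F' = 0.5 * proj(F)."""
    rng = np.random.default_rng(1)
    mod = AttentionModule(8, 16, 4, rng)
    mod.w_a.weight.value[...] = 0.0
    mod.w_a.bias.value[...] = 0.0
    f = rng.random((2, 8, 8, 8)).astype(np.float32)
    g = rng.random((2, 16, 2, 2)).astype(np.float32)
    res = mod.forward(f, g, cache=False)
    assert np.allclose(res.A, 0.5, atol=1e-7)
    proj = mod.w_f.forward(f, cache=False)
    assert np.allclose(res.F_prime, 0.5 * proj, atol=1e-6)


def test_attention_map_in_open_unit_interval(rng):
    mod = AttentionModule(4, 8, 4, np.random.default_rng(2))
    f = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    g = rng.normal(size=(1, 8, 2, 2)).astype(np.float32)
    res = mod.forward(f, g, cache=False)
    assert (res.A > 0).all() and (res.A < 1).all()


def test_monotone_gating_saturation():
    """Driving the pre-sigmoid map to +/-20 sends F' to proj(F) / 0."""
    rng = np.random.default_rng(3)
    mod = AttentionModule(4, 8, 4, rng)
    f = rng.random((1, 4, 6, 6)).astype(np.float32)
    g = rng.random((1, 8, 2, 2)).astype(np.float32)
    proj = mod.w_f.forward(f, cache=False)
    for forced, target in ((20.0, proj), (-20.0, np.zeros_like(proj))):
        mod.w_a.weight.value[...] = 0.0
        mod.w_a.bias.value[...] = forced
        res = mod.forward(f, g, cache=False)
        assert np.abs(res.F_prime - target).max() < 1e-6


def test_backbone_shapes_standard_plan():
    backbone = build_backbone(width_multiplier=1.0)
    x = np.zeros((1, 3, 224, 224), dtype=np.float32)
    fb = backbone.forward(x, cache=False)
    assert fb.F2.shape == (1, 128, 56, 56)
    assert fb.F4.shape == (1, 512, 14, 14)
    assert fb.G.shape == (1, 512, 7, 7)
    assert np.isfinite(fb.G).all()          # zero input stays finite


def test_backbone_has_no_fully_connected_layers():
    backbone = build_backbone(width_multiplier=0.1)
    # every parameter is a convolution weight or bias (<= 4-D, no dense matrices)
    for p in backbone.params:
        assert p.value.ndim in (1, 4)
    assert len(backbone.blocks) == 5
    assert [len(b) for b in backbone.blocks] == [2, 2, 3, 3, 3]


def test_backbone_halving_arithmetic():
    backbone = build_backbone(width_multiplier=0.125)
    fb = backbone.forward(np.zeros((1, 3, 64, 64), dtype=np.float32), cache=False)
    assert fb.F2.shape[2:] == (16, 16)
    assert fb.F4.shape[2:] == (4, 4)
    assert fb.G.shape[2:] == (2, 2)


def test_pretrained_requires_checkpoint(tmp_path):
    with pytest.raises(FileNotFoundError):
        build_backbone(pretrained=True)
    with pytest.raises(ValueError):
        build_backbone(pretrained=True, width_multiplier=0.5)


def test_attention_branch_shapes_full_width():
    """F: 128x56x56 with G: 512x7x7 -> A: 1x56x56, F': 256x56x56."""
    mod = AttentionModule(128, 512, 256, np.random.default_rng(4))
    f = np.random.default_rng(5).random((1, 128, 56, 56)).astype(np.float32)
    g = np.random.default_rng(6).random((1, 512, 7, 7)).astype(np.float32)
    res = mod.forward(f, g, cache=False)
    assert res.A.shape == (1, 1, 56, 56)
    assert res.F_prime.shape == (1, 256, 56, 56)


@pytest.mark.parametrize("n_classes", [2, 3, 4])
def test_softmax_head_normalized(n_classes, rng):
    model = TGANet(n_classes=n_classes, width_multiplier=0.1, seed=0)
    x = rng.random((3, 3, 64, 64)).astype(np.float32)
    pred = model.forward(x, cache=False)
    assert pred.probs.shape == (3, n_classes)
    assert np.abs(pred.probs.sum(axis=1) - 1.0).max() < 1e-6


def test_fuse_and_classify_uniform_on_equal_logits(rng):
    head = tnn.Linear(6, 4, np.random.default_rng(7))
    head.weight.value[...] = 0.0
    head.bias.value[...] = 0.0
    f2 = rng.random((2, 2, 4, 4)).astype(np.float32)
    f4 = rng.random((2, 2, 2, 2)).astype(np.float32)
    g = rng.random((2, 2, 2, 2)).astype(np.float32)
    logits, probs = fuse_and_classify(f2, f4, g, head)
    assert np.allclose(probs, 0.25, atol=1e-7)


def test_forward_shapes_random_sizes():
    """Shape contract across random spatial sizes divisible by 32."""
    rng = np.random.default_rng(8)
    model = TGANet(n_classes=4, width_multiplier=0.1, seed=1)
    for _ in range(3):
        h = 32 * int(rng.integers(2, 5))
        w = 32 * int(rng.integers(2, 5))
        x = rng.random((2, 3, h, w)).astype(np.float32)
        pred = model.forward(x, cache=False)
        assert pred.attention_b2.shape == (2, 1, h // 4, w // 4)
        assert pred.attention_b4.shape == (2, 1, h // 16, w // 16)
        assert pred.logits.shape == (2, 4)
    with pytest.raises(ValueError):
        model.forward(rng.random((1, 3, 100, 96)).astype(np.float32), cache=False)


def test_eval_determinism(rng):
    model = TGANet(n_classes=3, width_multiplier=0.1, seed=2)
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    p1 = model.forward(x, cache=False)
    p2 = model.forward(x, cache=False)
    assert np.array_equal(p1.logits, p2.logits)


def test_extract_features_accepts_hwc_image(rng):
    backbone = build_backbone(width_multiplier=0.1)
    fb = extract_features(backbone, rng.random((64, 64, 3)).astype(np.float32))
    assert fb.F2.shape[2:] == (16, 16) and fb.G.shape[2:] == (2, 2)


def test_end_to_end_gradients_nonzero(rng):
    """Loss gradients reach the attention parameters (end-to-end training)."""
    model = TGANet(n_classes=3, width_multiplier=0.1, seed=3)
    x = rng.random((4, 3, 64, 64)).astype(np.float32)
    y = np.array([0, 1, 2, 1])
    pred = model.forward(x)
    loss, dlogits = tnn.softmax_cross_entropy(pred.logits, y)
    for p in model.params:
        p.zero_grad()
    pred = model.forward(x)
    loss, dlogits = tnn.softmax_cross_entropy(pred.logits, y)
    model.backward(dlogits)
    att_grads = [np.abs(p.grad).max() for p in model.att2.params + model.att4.params]
    assert max(att_grads) > 0
    # finite-difference spot check on one attention projection weight
    p = model.att2.w_f.weight
    idx = (0, 0, 0, 0)
    eps = 1e-2
    old = p.value[idx]
    p.value[idx] = old + eps
    l1, _ = tnn.softmax_cross_entropy(model.forward(x, cache=False).logits, y)
    p.value[idx] = old - eps
    l2, _ = tnn.softmax_cross_entropy(model.forward(x, cache=False).logits, y)
    p.value[idx] = old
    numeric = (l1 - l2) / (2 * eps)
    assert numeric == pytest.approx(p.grad[idx], abs=max(1e-3, 0.15 * abs(numeric)))


def test_checkpoint_roundtrip(tmp_path, rng):
    from tganet import load_tganet, save_tganet
    model = TGANet(n_classes=4, width_multiplier=0.1, seed=4)
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    before = model.forward(x, cache=False).logits
    save_tganet(model, tmp_path / "m.npz")
    restored = load_tganet(tmp_path / "m.npz")
    after = restored.forward(x, cache=False).logits
    assert np.array_equal(before, after)
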