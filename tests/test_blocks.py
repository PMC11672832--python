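"""Star operation, star block, EMA attention and C2f composites."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcsyolo import nn
from bcsyolo.blocks import (star_product, implicit_monomial_count, StarBlock,
                            StarBlockParams, EMAGate, EMA, directional_pool,
                            ema_forward, C2f, make_c2f, Conv, default_ema_groups)
from bcsyolo.nn import Tensor


# --------------------------------------------------------------------------
# star product
# --------------------------------------------------------------------------

def test_star_product_identity_and_zero():
    rng = np.random.default_rng(0)
    b = rng.normal(size=(4, 5, 6))
    assert np.array_equal(star_product(np.ones_like(b), b), b)
    assert np.array_equal(star_product(np.zeros_like(b), b),
                          np.zeros_like(b))


def test_star_product_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape"):
        star_product(np.ones(3), np.ones(4))


def _expansion_oracle(w1, w2, x):
    """Brute-force double sum over all pairwise monomials."""
    total = 0.0
    d1 = len(x)
    for i in range(d1):
        for j in range(d1):
            total += w1[i] * w2[j] * x[i] * x[j]
    return total


@settings(deadline=None, max_examples=50)
@given(st.integers(min_value=1, max_value=8), st.integers(0, 2**32 - 1))
def test_star_expansion_identity(d, seed):
    """(w1.x)(w2.x) equals the explicit sum of all monomials x_i x_j."""
    rng = np.random.default_rng(seed)
    w1, w2, x = (rng.normal(size=d + 1) for _ in range(3))
    lhs = star_product(np.array([w1 @ x]), np.array([w2 @ x]))[0]
    assert lhs == pytest.approx(_expansion_oracle(w1, w2, x), rel=1e-9)


def test_star_expansion_identity_sweep():
    """200 random draws across d in 1..8 stay within 1e-9 relative."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        d = 1 + trial % 8
        w1, w2, x = (rng.normal(size=d + 1) for _ in range(3))
        lhs = (w1 @ x) * (w2 @ x)
        assert lhs == pytest.approx(_expansion_oracle(w1, w2, x), rel=1e-9)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**32 - 1), st.floats(-10, 10))
def test_star_product_commutative_bilinear(seed, scale):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(2, 3, 4)).astype(np.float64)
    assert np.allclose(star_product(a, b), star_product(b, a))
    assert np.allclose(star_product(scale * a, b),
                       scale * star_product(a, b))


@pytest.mark.parametrize("d,expected", [(0, 1), (1, 3), (3, 10)])
def test_implicit_monomial_count(d, expected):
    """Enumerated i <= j monomial counts over the bias-augmented input."""
    # independent enumeration oracle
    pairs = {(i, j) for i in range(d + 1) for j in range(i, d + 1)}
    assert len(pairs) == expected
    assert implicit_monomial_count(d) == expected


def test_implicit_monomial_count_negative_raises():
    with pytest.raises(ValueError):
        implicit_monomial_count(-1)


# --------------------------------------------------------------------------
# star block
# --------------------------------------------------------------------------

def test_star_block_residual_identity():
    """Zero projection weights + residual makes the block the identity."""
    nn.manual_seed(0)
    blk = StarBlock(8, residual=True)
    blk.eval()
    blk.g.weight.data[:] = 0.0
    blk.dw2.weight.data[:] = 0.0
    blk.dw2.bias.data[:] = 0.0
    x = Tensor(np.random.default_rng(1).normal(size=(2, 8, 5, 5)))
    out = blk(x)
    assert np.allclose(out.data, x.data, atol=1e-6)


@pytest.mark.parametrize("k", [3, 5, 7])
def test_star_block_preserves_spatial_dims(k):
    nn.manual_seed(0)
    blk = StarBlock(4, dw_kernel=k)
    blk.eval()
    x = Tensor(np.random.default_rng(0).normal(size=(1, 4, 9, 7)))
    assert blk(x).shape == x.shape


def test_star_block_scalar_path_oracle():
    """H=W=1 input: block output equals the hand-composed scalar chain."""
    nn.manual_seed(3)
    c, e = 3, 2.0
    blk = StarBlock(c, expand_ratio=e, residual=False)
    blk.eval()
    # mark the norms calibrated so eval uses their (0, 1) running stats,
    # which is what the hand-composed chain below assumes
    for bn in (blk.bn1, blk.bng):
        bn._set_buffer("num_batches", np.ones(1, dtype=np.float32))
    x = np.random.default_rng(7).normal(size=(1, c, 1, 1)).astype(np.float32)
    out = blk(Tensor(x)).data.ravel()

    def bn_eval(y, bn):
        return ((y - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
                * bn.weight.data + bn.bias.data)

    def silu(v):
        return v / (1.0 + np.exp(-v))

    xv = x.ravel()
    # depthwise conv with same-padding on a single pixel: only center tap
    kc = blk.params.dw_kernel // 2
    y = blk.dw1.weight.data[:, 0, kc, kc] * xv
    y = bn_eval(y, blk.bn1)
    f1 = blk.f1.weight.data[:, :, 0, 0] @ y + blk.f1.bias.data
    f2 = blk.f2.weight.data[:, :, 0, 0] @ y + blk.f2.bias.data
    y = silu(f1) * f2
    y = bn_eval(blk.g.weight.data[:, :, 0, 0] @ y, blk.bng)
    y = blk.dw2.weight.data[:, 0, kc, kc] * y + blk.dw2.bias.data
    assert np.allclose(out, y, rtol=1e-5, atol=1e-6)


def test_star_block_channel_mismatch_raises():
    blk = StarBlock(4)
    with pytest.raises(ValueError, match="channels"):
        blk(Tensor(np.zeros((1, 5, 3, 3))))


def test_star_block_params_validation():
    with pytest.raises(ValueError):
        StarBlockParams(8, expand_ratio=-1.0)
    with pytest.raises(ValueError):
        StarBlockParams(8, dw_kernel=4)


# --------------------------------------------------------------------------
# EMA
# --------------------------------------------------------------------------

def test_directional_pool_hand_example():
    """x of shape 1x2x2 with rows (1,3),(5,7): z^H=(2,6), z^W=(3,5)."""
    x = Tensor(np.array([[[[1.0, 3.0], [5.0, 7.0]]]]))
    z_h, z_w = directional_pool(x)
    assert np.allclose(z_h.data, [[[2.0, 6.0]]])
    assert np.allclose(z_w.data, [[[3.0, 5.0]]])


def test_ema_gate_constant_input_gives_uniform_gate():
    """Constant input pools to a constant map, so the modulation is
    spatially uniform and matches the directly evaluated gate."""
    nn.manual_seed(1)
    gate = EMAGate(8, groups=2)
    k = 1.7
    x = Tensor(np.full((1, 8, 4, 6), k, dtype=np.float32))
    out = gate(x)
    # spatial uniformity
    assert np.allclose(out.data, out.data[:, :, :1, :1], atol=1e-6)
    # evaluate the 1x1 conv on the constant pooled map by hand
    w = gate.gate_conv.weight.data[:, :, 0, 0]
    b = gate.gate_conv.bias.data
    gvec = 1.0 / (1.0 + np.exp(-(w @ (k * np.ones(4)) + b)))
    expected = (k * gvec * gvec).reshape(1, 4)
    got = out.data[0, :, 0, 0].reshape(2, 4)
    assert np.allclose(got, np.broadcast_to(expected, (2, 4)), atol=1e-5)


def test_ema_gate_attenuates_never_amplifies():
    """Both directional gates are sigmoids in (0, 1), so the modulated
    output is strictly smaller in magnitude than the input."""
    nn.manual_seed(2)
    gate = EMAGate(6, groups=3)
    x = Tensor(np.random.default_rng(0).normal(size=(2, 6, 5, 5)) * 10)
    out = gate(x)
    nonzero = np.abs(x.data) > 1e-6
    assert np.all(np.abs(out.data[nonzero]) < np.abs(x.data[nonzero]))


@pytest.mark.parametrize("c,g,h,w", [(4, 1, 3, 5), (8, 4, 2, 2),
                                     (12, 4, 7, 3), (16, 8, 4, 4)])
def test_ema_shape_preserved(c, g, h, w):
    nn.manual_seed(0)
    for mod in (EMAGate(c, g), EMA(c, g)):
        x = Tensor(np.random.default_rng(1).normal(size=(2, c, h, w)))
        assert mod(x).shape == x.shape


def test_ema_pooling_order_is_part_of_contract():
    """The gate splits its concatenated input H-first; feeding the pooled
    descriptors in the wrong (W-then-H) order therefore changes the
    output, i.e. the H-then-W order is part of the module contract."""
    nn.manual_seed(4)
    gate = EMAGate(4, groups=2)
    x = Tensor(np.random.default_rng(2).normal(size=(1, 4, 3, 5)))
    out = gate(x).data

    # caller concatenates W-then-H, module still splits at position h
    n, c, h, w = x.shape
    g = 2
    xg = x.reshape(n * g, c // g, h, w)
    z_h = xg.mean(axis=3, keepdims=True)
    z_w = xg.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)
    z = nn.concat([z_w, z_h], axis=2)            # wrong order on purpose
    gatemap = gate.gate_conv(z).sigmoid()
    g_h = gatemap[:, :, :h, :]                   # module's fixed H-first split
    g_w = gatemap[:, :, h:, :].transpose(0, 1, 3, 2)
    swapped = (xg * g_h * g_w).reshape(n, c, h, w).data
    assert not np.allclose(out, swapped)


def test_ema_invalid_grouping_raises():
    with pytest.raises(ValueError, match="divisible"):
        EMAGate(6, groups=4)


def test_default_ema_groups_largest_divisor():
    assert default_ema_groups(64, 4) == 4
    assert default_ema_groups(6, 4) == 3
    assert default_ema_groups(7, 4) == 1


def test_ema_forward_accepts_rank3():
    nn.manual_seed(0)
    gate = EMAGate(4, groups=2)
    x = np.random.default_rng(3).normal(size=(4, 5, 6)).astype(np.float32)
    out = ema_forward(x, gate)
    assert out.shape == (4, 5, 6)


# --------------------------------------------------------------------------
# C2f composites
# --------------------------------------------------------------------------

def test_c2f_skeleton_identity_inner_block():
    """With zeroed inner-block projections the composite reduces to the
    fuse conv applied to the concatenated split."""
    nn.manual_seed(5)
    blk = C2f(8, 8, n=1, inner="star")
    blk.eval()
    sb = blk.m[0]
    sb.g.weight.data[:] = 0.0
    sb.dw2.weight.data[:] = 0.0
    sb.dw2.bias.data[:] = 0.0
    x = Tensor(np.random.default_rng(4).normal(size=(1, 8, 6, 6)))
    out = blk(x).data
    y = blk.cv1(x)
    a, b = y[:, :4], y[:, 4:]
    expected = blk.attn(blk.cv2(nn.concat([a, b, b], axis=1))).data
    assert np.allclose(out, expected, atol=1e-6)


@pytest.mark.parametrize("variant", ["c2f_baseline", "c2f_star",
                                     "c2f_star_ema"])
def test_c2f_output_dims(variant):
    nn.manual_seed(0)
    blk = make_c2f(16, 24, 2, True, variant)
    blk.eval()
    x = Tensor(np.random.default_rng(0).normal(size=(2, 16, 8, 10)))
    out = blk(x)
    assert out.shape == (2, 24, 8, 10)


def test_c2f_invalid_n_raises():
    with pytest.raises(ValueError, match="inner block"):
        C2f(8, 8, n=0)


def test_c2f_star_ema_fewer_params_than_baseline():
    """At the detector's stage widths the star composite is smaller than
    the stock C2f, consistent with the reported size drop."""
    for c1, c2, n in [(32, 32, 1), (64, 64, 2), (128, 128, 2),
                      (256, 256, 1)]:
        nn.manual_seed(0)
        base = make_c2f(c1, c2, n, True, "c2f_baseline")
        star_ema = make_c2f(c1, c2, n, True, "c2f_star_ema")
        star = make_c2f(c1, c2, n, True, "c2f_star")
        assert star.num_parameters() < base.num_parameters()
        assert star_ema.num_parameters() < base.num_parameters()


def test_blocks_deterministic_and_finite():
    """Fixed weights give bit-identical repeat passes; bounded input
    never produces non-finite output."""
    nn.manual_seed(9)
    mods = [StarBlock(8), EMAGate(8, 4), EMA(8, 4),
            make_c2f(8, 8, 1, True, "c2f_star_ema"), Conv(8, 8, 3)]
    x = Tensor(np.random.default_rng(5).normal(size=(2, 8, 6, 6)) * 50)
    for mod in mods:
        mod.eval()
        a = mod(x).data
        b = mod(x).data
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))
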