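"""Window-attention oracles: brute-force attention, naive shifted windows,
cost formulas, block-pair algebra, hierarchical shapes."""

import numpy as np
import pytest

import maskdet.autodiff as ad
from maskdet.autodiff import Tensor
from maskdet.backbone import (
    BlockPair,
    HierarchicalBackbone,
    attention_cost,
    block_pair,
    hierarchical_forward,
    self_attention,
    sw_msa,
    w_msa,
    window_merge,
    window_partition,
)
from maskdet.nn import MultiHeadAttention
from maskdet.patching import patchify

from conftest import numeric_gradient


def brute_force_attention(x, attn, scale_mode="sqrt"):
    """Independent triple-loop evaluation of single-head self-attention:
    e_{t,i} = f(x_t)' g(x_i) / scale; rows softmaxed; z_t = W_v sum a h(x_i)."""
    n, d = x.shape
    f = x @ attn.w_q.weight.data + attn.w_q.bias.data
    g = x @ attn.w_k.weight.data + attn.w_k.bias.data
    h = x @ attn.w_v.weight.data + attn.w_v.bias.data
    scale = np.sqrt(d) if scale_mode == "sqrt" else d
    out = np.zeros_like(x)
    for t in range(n):
        e = np.array([f[t] @ g[i] / scale for i in range(n)])
        a = np.exp(e - e.max())
        a = a / a.sum()
        z = sum(a[i] * h[i] for i in range(n))
        out[t] = z @ attn.w_out.weight.data + attn.w_out.bias.data
    return out


@pytest.mark.parametrize("scale_mode", ["sqrt", "linear"])
def test_attention_matches_triple_loop_oracle(scale_mode, rng):
    for _ in range(20):
        attn = MultiHeadAttention(6, 1, rng, scale_mode)
        x = rng.normal(size=(3, 6))
        got = self_attention(x.reshape(1, 3, 6), attn).reshape(3, 6)
        ref = brute_force_attention(x, attn, scale_mode)
        assert np.abs(got - ref).max() < 1e-6


def test_attention_rows_sum_to_one(rng):
    """Softmax normalization observed through a constant-value probe: with
    h(x) == const the attention output is W_out(const) regardless of x."""
    attn = MultiHeadAttention(8, 2, rng)
    attn.w_v.weight.data[:] = 0.0
    attn.w_v.bias.data[:] = 1.0
    x = rng.normal(size=(2, 7, 8))
    out = attn(Tensor(x)).data
    expected = np.ones(8) @ attn.w_out.weight.data + attn.w_out.bias.data
    assert np.abs(out - expected).max() < 1e-9


def test_single_position_attention_degenerates(rng):
    attn = MultiHeadAttention(6, 1, rng)
    x = rng.normal(size=(1, 1, 6))
    out = attn(Tensor(x)).data
    v = x[0] @ attn.w_v.weight.data + attn.w_v.bias.data
    expected = v @ attn.w_out.weight.data + attn.w_out.bias.data
    assert np.abs(out[0] - expected).max() < 1e-9


def test_window_partition_counts_and_round_trip(rng):
    x = rng.normal(size=(8, 8, 3))
    windows, meta = window_partition(x, 4, shift=0)
    assert windows.shape == (4, 16, 3)  # an 8x8 map tiles into four 4x4 windows
    assert np.abs(window_merge(windows, meta) - x).max() == 0
    for shift in (0, 2):
        w, m = window_partition(x, 4, shift)
        assert np.abs(window_merge(w, m) - x).max() == 0
    one, _ = window_partition(rng.normal(size=(4, 4, 2)), 4, 0)
    assert one.shape == (1, 16, 2)


def test_wmsa_equals_global_attention_when_window_covers_grid(rng):
    attn = MultiHeadAttention(8, 2, rng)
    x = rng.normal(size=(4, 4, 8))
    assert np.abs(w_msa(x, 4, attn) - self_attention(x, attn)).max() < 1e-10


def test_wmsa_locality(rng):
    """Perturbing one window never changes another window's output."""
    attn = MultiHeadAttention(8, 2, rng)
    x = rng.normal(size=(8, 8, 8))
    base = w_msa(x, 4, attn)
    x2 = x.copy()
    x2[0, 0] += 10.0  # inside window (0,0)
    pert = w_msa(x2, 4, attn)
    assert np.array_equal(base[:, 4:], pert[:, 4:])
    assert np.array_equal(base[4:, :], pert[4:, :])
    assert np.abs(base[:4, :4] - pert[:4, :4]).max() > 1e-6


def test_wmsa_single_token_windows(rng):
    attn = MultiHeadAttention(6, 1, rng)
    x = rng.normal(size=(2, 2, 6))
    out = w_msa(x, 1, attn)
    for i in range(2):
        for j in range(2):
            v = x[i, j] @ attn.w_v.weight.data + attn.w_v.bias.data
            exp = v @ attn.w_out.weight.data + attn.w_out.bias.data
            assert np.abs(out[i, j] - exp).max() < 1e-9


def naive_shifted_attention(x, M, attn):
    """Oracle: roll the grid, run unmasked attention inside each contiguous
    sub-window (the regions that did not wrap), roll back."""
    h, w, _ = x.shape
    s = M // 2
    rolled = np.roll(x, (-s, -s), axis=(0, 1))
    out = np.zeros_like(rolled)
    bands = [(0, h - M), (h - M, h - s), (h - s, h)]
    wbands = [(0, w - M), (w - M, w - s), (w - s, w)]
    for r0, r1 in bands:
        for c0, c1 in wbands:
            for wr in range(h // M):
                for wc in range(w // M):
                    rr0, rr1 = max(r0, wr * M), min(r1, (wr + 1) * M)
                    cc0, cc1 = max(c0, wc * M), min(c1, (wc + 1) * M)
                    if rr0 >= rr1 or cc0 >= cc1:
                        continue
                    out[rr0:rr1, cc0:cc1] = self_attention(
                        rolled[rr0:rr1, cc0:cc1], attn)
    return np.roll(out, (s, s), axis=(0, 1))


def test_swmsa_matches_naive_shift_oracle(rng):
    attn = MultiHeadAttention(8, 2, rng)
    for _ in range(5):
        x = rng.normal(size=(8, 8, 8))
        got = sw_msa(x, 4, attn)
        ref = naive_shifted_attention(x, 4, attn)
        assert np.abs(got - ref).max() < 1e-6


def test_swmsa_masks_wrapped_pairs(rng):
    """A token that wrapped across the boundary must not influence tokens
    from the opposite edge sharing its window (weight < 1e-8 <=> outputs
    bit-identical under perturbation)."""
    attn = MultiHeadAttention(8, 2, rng)
    x = rng.normal(size=(8, 8, 8))
    base = sw_msa(x, 4, attn)
    x2 = x.copy()
    x2[0, 0] += 100.0  # wraps into the bottom-right window after the roll
    pert = sw_msa(x2, 4, attn)
    # interior tokens of that window (rows/cols 6,7 are the non-wrapped part)
    assert np.abs(base[6:, 6:] - pert[6:, 6:]).max() < 1e-8


def test_swmsa_with_window_one_degenerates_to_wmsa(rng):
    attn = MultiHeadAttention(6, 1, rng)
    x = rng.normal(size=(3, 3, 6))
    assert np.array_equal(sw_msa(x, 1, attn), w_msa(x, 1, attn))


def test_block_pair_connects_adjacent_windows(rng):
    """After W-MSA + SW-MSA, perturbing a token in one regular window changes
    boundary outputs in the neighbouring window."""
    pair = BlockPair(8, 2, 4, 2.0, rng)
    x = rng.normal(size=(8, 8, 8))
    base = block_pair(x, pair)
    x2 = x.copy()
    x2[3, 3, 0] += 5.0  # window (0,0), near the boundary, single channel
    pert = block_pair(x2, pair)
    assert np.abs(base[4, 4] - pert[4, 4]).max() > 1e-8


def test_block_pair_is_identity_with_zeroed_projections(rng):
    pair = BlockPair(8, 2, 4, 2.0, rng)
    for attn in (pair.attn_w, pair.attn_sw):
        attn.w_out.weight.data[:] = 0.0
        attn.w_out.bias.data[:] = 0.0
    for mlp in (pair.mlp1, pair.mlp2):
        mlp.fc2.weight.data[:] = 0.0
        mlp.fc2.bias.data[:] = 0.0
    x = rng.normal(size=(6, 6, 8))
    assert np.abs(block_pair(x, pair) - x).max() < 1e-12


def test_block_pair_preserves_shape_and_gradients(rng):
    pair = BlockPair(8, 2, 4, 2.0, rng)
    x = rng.normal(size=(4, 4, 8))
    assert block_pair(x, pair).shape == x.shape
    t = Tensor(x[None], requires_grad=True)
    (pair(t) ** 2).mean().backward()
    ng = numeric_gradient(
        lambda a: float((pair(Tensor(a[None])) ** 2).mean().data), x)
    rel = np.abs(t.grad[0] - ng).max() / np.abs(ng).max()
    assert rel < 1e-3


def test_attention_cost_closed_forms(rng):
    assert attention_cost(8, 8, 1, 4) == (8448, 2304)
    # one window covering the whole grid: both costs coincide
    for h, w in [(4, 4), (8, 2), (3, 12)]:
        m2 = h * w
        m = int(np.sqrt(m2))
        if m * m == m2:
            msa, wmsa = attention_cost(h, w, 5, m)
            assert msa == wmsa
    # independent re-evaluation on 1,000 random tuples
    for _ in range(1000):
        h, w, c, m = (int(v) for v in rng.integers(1, 40, size=4))
        msa, wmsa = attention_cost(h, w, c, m)
        assert msa == 4 * h * w * c * c + 2 * (h * w) ** 2 * c
        assert wmsa == 4 * h * w * c * c + 2 * m * m * h * w * c
    # linearity in hw at fixed C, M
    base = attention_cost(4, 4, 3, 2)[1] - 4 * 16 * 9
    double = attention_cost(8, 4, 3, 2)[1] - 4 * 32 * 9
    assert double == 2 * base


def test_window_permutation_invariance(rng):
    """Permuting windows before W-MSA and un-permuting after is a no-op."""
    attn = MultiHeadAttention(8, 2, rng)
    x = rng.normal(size=(8, 8, 8))
    base = w_msa(x, 4, attn)
    windows, meta = window_partition(x, 4, 0)
    perm = rng.permutation(len(windows))
    permuted = window_merge(windows[perm], meta)
    out_perm = w_msa(permuted, 4, attn)
    pw, _ = window_partition(out_perm, 4, 0)
    restored = window_merge(pw[np.argsort(perm)], meta)
    assert np.abs(restored - base).max() < 1e-12


def test_hierarchical_stage_shapes(rng):
    seq = patchify(rng.random((64, 64)), 16)
    bb = HierarchicalBackbone(256, seq.grid_shape, base_channels=16,
                              stage_depths=(1, 1, 1), n_heads=4,
                              window_size=4, rng=rng)
    maps = hierarchical_forward(seq, bb)
    assert [m.shape[:2] for m in maps] == [(4, 4), (2, 2), (1, 1)]
    assert [m.shape[2] for m in maps] == [16, 32, 64]
    again = hierarchical_forward(seq, bb)
    for a, b in zip(maps, again):
        assert np.array_equal(a, b)


def test_hierarchical_rejects_unmergeable_grid(rng):
    with pytest.raises(ValueError):
        HierarchicalBackbone(16, (1, 1), base_channels=8,
                             stage_depths=(1, 1), rng=rng)
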