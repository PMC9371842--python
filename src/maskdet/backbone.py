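"""Hierarchical window-attention backbone.

Attention comes in three flavours sharing one parameterisation (learned
query/key/value maps plus an output map):

* global self-attention over all grid positions,
* W-MSA: attention restricted to non-overlapping MxM windows,
* SW-MSA: the same windows after a cyclic shift of floor(M/2) in both grid
  axes, with pairs that wrapped across the original image boundary masked
  out of the softmax.

Blocks alternate W-MSA and SW-MSA (each with a pre-norm MLP sub-block and
residual connections) so information propagates across window boundaries.
Between stages a patch-merging step concatenates 2x2 neighbouring tokens and
linearly projects them, halving the spatial grid and doubling the channels;
each stage's (pre-merge) output feeds the detection neck.

The closed-form FLOP counts for global versus windowed attention over an
h x w grid with C channels are

    omega_MSA   = 4 h w C^2 + 2 (h w)^2 C
    omega_W-MSA = 4 h w C^2 + 2 M^2 h w C

so windowing turns the quadratic term in h*w linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import LayerNorm, Linear, Mlp, Module, MultiHeadAttention
from .patching import PatchSequence, sincos_position_table

__all__ = [
    "FeatureMap",
    "attention_cost",
    "self_attention",
    "window_partition",
    "window_merge",
    "w_msa",
    "sw_msa",
    "BlockPair",
    "PatchMerge",
    "HierarchicalBackbone",
    "hierarchical_forward",
]

_NEG_INF = -1e9


@dataclass
class FeatureMap:
    """A spatial grid of channel vectors (h, w, C)."""

    grid: np.ndarray

    def __post_init__(self):
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("feature map must be (h, w, C) with all dims >= 1")


def attention_cost(h: int, w: int, C: int, M: int) -> tuple[int, int]:
    """FLOPs of global MSA vs. window MSA on an h x w x C grid, window M."""
    if min(h, w, C, M) <= 0:
        raise ValueError("all arguments must be positive")
    hw = h * w
    omega_msa = 4 * hw * C**2 + 2 * hw**2 * C
    omega_wmsa = 4 * hw * C**2 + 2 * M**2 * hw * C
    return omega_msa, omega_wmsa


# -- window bookkeeping -------------------------------------------------------
def _pad_hw(h: int, w: int, M: int) -> tuple[int, int]:
    return h + (-h) % M, w + (-w) % M


def window_partition(x: np.ndarray, M: int, shift: int = 0):
    """Tile a (h, w, C) grid into non-overlapping MxM windows.

    With ``shift`` > 0 the grid is cyclically rolled by (-shift, -shift)
    first; the returned mask marks token pairs that wrapped across the
    original boundary (those must not attend to each other).  Returns
    ``(windows, meta)`` where windows has shape (n_windows, M*M, C).
    """
    if x.ndim != 3:
        raise ValueError("expected (h, w, C) feature map")
    h, w, c = x.shape
    hp, wp = _pad_hw(h, w, M)
    if M > hp or M > wp:
        raise ValueError(f"window size {M} exceeds padded grid {hp}x{wp}")
    arr = np.pad(x, ((0, hp - h), (0, wp - w), (0, 0)))
    if shift:
        arr = np.roll(arr, (-shift, -shift), axis=(0, 1))
    nwh, nww = hp // M, wp // M
    windows = (
        arr.reshape(nwh, M, nww, M, c).transpose(0, 2, 1, 3, 4)
        .reshape(nwh * nww, M * M, c)
    )
    mask = _window_pair_mask(h, w, M, shift)
    meta = {"orig_hw": (h, w), "padded_hw": (hp, wp), "M": M, "shift": shift,
            "pair_mask": mask}
    return windows, meta


def _region_ids(h: int, w: int, M: int, shift: int) -> np.ndarray:
    """Per-token region labels on the padded grid after the cyclic roll.

    Tokens in different regions either wrapped across the original image
    boundary or are padding; they must not attend to one another.
    """
    hp, wp = _pad_hw(h, w, M)
    ids = np.zeros((hp, wp), dtype=np.int64)
    if shift:
        # three bands per axis: interior, the strip that will wrap, then pad
        h_bands = [slice(0, hp - M), slice(hp - M, hp - shift), slice(hp - shift, hp)]
        w_bands = [slice(0, wp - M), slice(wp - M, wp - shift), slice(wp - shift, wp)]
        label = 0
        for hs in h_bands:
            for ws in w_bands:
                ids[hs, ws] = label
                label += 1
    pad_flag = np.zeros((hp, wp), dtype=bool)
    pad_flag[h:, :] = True
    pad_flag[:, w:] = True
    if shift:
        pad_flag = np.roll(pad_flag, (-shift, -shift), axis=(0, 1))
    ids = ids + 100 * np.cumsum(pad_flag.reshape(-1)).reshape(hp, wp) * pad_flag
    return ids


def _window_pair_mask(h: int, w: int, M: int, shift: int) -> np.ndarray | None:
    """Additive attention mask (n_windows, M*M, M*M); None if nothing masked."""
    hp, wp = _pad_hw(h, w, M)
    if shift == 0 and hp == h and wp == w:
        return None
    ids = _region_ids(h, w, M, shift)
    nwh, nww = hp // M, wp // M
    win_ids = (
        ids.reshape(nwh, M, nww, M).transpose(0, 2, 1, 3).reshape(nwh * nww, M * M)
    )
    diff = win_ids[:, :, None] != win_ids[:, None, :]
    return np.where(diff, _NEG_INF, 0.0)


def window_merge(windows: np.ndarray, meta: dict) -> np.ndarray:
    """Exact inverse of :func:`window_partition`."""
    h, w = meta["orig_hw"]
    hp, wp = meta["padded_hw"]
    M, shift = meta["M"], meta["shift"]
    c = windows.shape[-1]
    nwh, nww = hp // M, wp // M
    arr = (
        windows.reshape(nwh, nww, M, M, c).transpose(0, 2, 1, 3, 4)
        .reshape(hp, wp, c)
    )
    if shift:
        arr = np.roll(arr, (shift, shift), axis=(0, 1))
    return arr[:h, :w]


# -- attention application ----------------------------------------------------
def _window_attention_t(x: Tensor, attn: MultiHeadAttention, M: int,
                        shift: int) -> Tensor:
    """Windowed attention on a batched (B, h, w, C) tensor."""
    bsz, h, w, c = x.shape
    hp, wp = _pad_hw(h, w, M)
    if M > hp or M > wp:
        raise ValueError(f"window size {M} exceeds padded grid {hp}x{wp}")
    if hp != h or wp != w:
        x = x.pad2d(hp - h, wp - w)
    if shift:
        x = x.roll((-shift, -shift), axis=(1, 2))
    nwh, nww = hp // M, wp // M
    n_win = nwh * nww
    tokens = (
        x.reshape(bsz, nwh, M, nww, M, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(bsz * n_win, M * M, c)
    )
    pair_mask = _window_pair_mask(h, w, M, shift)
    attn_mask = None
    if pair_mask is not None:
        attn_mask = np.tile(pair_mask[None, :, None, :, :], (bsz, 1, 1, 1, 1))
        attn_mask = attn_mask.reshape(bsz * n_win, 1, M * M, M * M)
    out = attn(tokens, attn_mask)
    out = (
        out.reshape(bsz, nwh, nww, M, M, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(bsz, hp, wp, c)
    )
    if shift:
        out = out.roll((shift, shift), axis=(1, 2))
    return out[:, :h, :w, :]


def self_attention(x: np.ndarray, attn: MultiHeadAttention) -> np.ndarray:
    """Global self-attention over every position of a (h, w, C) feature map.

    Logits are scaled inner products of the learned query/key projections
    (1/sqrt(d) by default, 1/d with ``scale_mode='linear'``); each softmax
    row sums to one, and outputs are the learned output map applied to the
    attention-weighted values.
    """
    h, w, c = np.asarray(x).shape
    with ad.no_grad():
        out = attn(Tensor(np.asarray(x, dtype=float).reshape(1, h * w, c)))
    return out.data.reshape(h, w, c)


def w_msa(x: np.ndarray, M: int, attn: MultiHeadAttention) -> np.ndarray:
    """Window attention: global attention applied independently per window."""
    with ad.no_grad():
        out = _window_attention_t(Tensor(np.asarray(x, dtype=float)[None]),
                                  attn, M, 0)
    return out.data[0]


def sw_msa(x: np.ndarray, M: int, attn: MultiHeadAttention) -> np.ndarray:
    """Shifted-window attention: cyclic shift by floor(M/2), masked windows."""
    with ad.no_grad():
        out = _window_attention_t(Tensor(np.asarray(x, dtype=float)[None]),
                                  attn, M, M // 2)
    return out.data[0]


class BlockPair(Module):
    """One W-MSA block followed by one SW-MSA block (pre-norm, residual).

    Sub-block order: LN -> W-MSA -> +residual; LN -> MLP -> +residual;
    LN -> SW-MSA -> +residual; LN -> MLP -> +residual.
    """

    def __init__(self, dim: int, n_heads: int, M: int, mlp_ratio: float,
                 rng: np.random.Generator, scale_mode: str = "sqrt"):
        self.M = M
        self.norm1 = LayerNorm(dim)
        self.attn_w = MultiHeadAttention(dim, n_heads, rng, scale_mode)
        self.norm2 = LayerNorm(dim)
        self.mlp1 = Mlp(dim, int(dim * mlp_ratio), rng)
        self.norm3 = LayerNorm(dim)
        self.attn_sw = MultiHeadAttention(dim, n_heads, rng, scale_mode)
        self.norm4 = LayerNorm(dim)
        self.mlp2 = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor, drop: float = 0.0, rng=None,
                 training: bool = False) -> Tensor:
        from .nn import dropout

        shift = self.M // 2 if self.M > 1 else 0
        x = x + dropout(_window_attention_t(self.norm1(x), self.attn_w,
                                            self.M, 0), drop, rng, training)
        b, h, w, c = x.shape
        x = (x.reshape(b, h * w, c) + self.mlp1(self.norm2(x.reshape(b, h * w, c)),
                                                drop, rng, training)).reshape(b, h, w, c)
        x = x + dropout(_window_attention_t(self.norm3(x), self.attn_sw,
                                            self.M, shift), drop, rng, training)
        x = (x.reshape(b, h * w, c) + self.mlp2(self.norm4(x.reshape(b, h * w, c)),
                                                drop, rng, training)).reshape(b, h, w, c)
        return x


def block_pair(x: np.ndarray, pair: BlockPair) -> np.ndarray:
    """Apply one W-MSA + SW-MSA block pair to a (h, w, C) map."""
    with ad.no_grad():
        out = pair(Tensor(np.asarray(x, dtype=float)[None]))
    return out.data[0]


class PatchMerge(Module):
    """Concatenate 2x2 neighbouring tokens and project 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.proj = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h < 2 or w < 2 or h % 2 or w % 2:
            raise ValueError(f"grid {h}x{w} cannot be 2x2-merged")
        x = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4 * c)
        )
        return self.proj(self.norm(x))


class HierarchicalBackbone(Module):
    """Patch embedding + staged window-attention blocks + patch merging.

    Stage s runs ``stage_depths[s]`` block pairs at channel width
    ``base_channels * 2**s`` and emits its output map; a patch-merge sits
    between consecutive stages.  Channel widths must keep ``dim % n_heads
    == 0`` at every stage.
    """

    def __init__(
        self,
        patch_dim: int,
        grid_shape: tuple[int, int],
        base_channels: int = 64,
        stage_depths: tuple[int, ...] = (1, 1, 1),
        n_heads: int = 4,
        window_size: int = 4,
        mlp_ratio: float = 2.0,
        scale_mode: str = "sqrt",
        use_pos: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.grid_shape = tuple(grid_shape)
        self.window_size = window_size
        self.use_pos = use_pos
        self.embed = Linear(patch_dim, base_channels, rng)
        # absolute positions help reconstruction but encourage position
        # memorisation in detection; translation-equivariant mode skips them
        self.pos_table = Tensor(sincos_position_table(grid_shape, base_channels)
                                if use_pos else
                                np.zeros((grid_shape[0] * grid_shape[1],
                                          base_channels)))
        h, w = grid_shape
        self.stages: list[list[BlockPair]] = []
        self.merges: list[PatchMerge] = []
        dim = base_channels
        for s, depth in enumerate(stage_depths):
            m = min(window_size, h, w)
            self.stages.append(
                [BlockPair(dim, n_heads, m, mlp_ratio, rng, scale_mode)
                 for _ in range(depth)]
            )
            if s < len(stage_depths) - 1:
                if h < 2 or w < 2 or h % 2 or w % 2:
                    raise ValueError(
                        f"stage {s} grid {h}x{w} too small to merge further"
                    )
                self.merges.append(PatchMerge(dim, rng))
                h, w, dim = h // 2, w // 2, dim * 2
        self.out_channels = [base_channels * 2**s for s in range(len(stage_depths))]

    def __call__(self, tokens: Tensor, drop: float = 0.0, rng=None,
                 training: bool = False) -> list[Tensor]:
        """tokens (B, N, patch_dim) -> one (B, h_s, w_s, C_s) map per stage."""
        b = tokens.shape[0]
        h, w = self.grid_shape
        x = (self.embed(tokens) + self.pos_table).reshape(b, h, w, -1)
        outputs: list[Tensor] = []
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x, drop, rng, training)
            outputs.append(x)
            if s < len(self.merges):
                x = self.merges[s](x)
        return outputs

    def init_from_mae(self, mae) -> int:
        """Copy pretrained patch projection (and matching encoder blocks)
        into this backbone; returns the number of parameter arrays copied."""
        copied = 0
        if mae.patch_projection.weight.shape == self.embed.weight.shape:
            self.embed.weight.data = mae.patch_projection.weight.data.copy()
            self.embed.bias.data = mae.patch_projection.bias.data.copy()
            copied += 2
        # encoder blocks map onto the W-MSA half of stage-0 block pairs
        for enc_blk, pair in zip(mae.encoder, self.stages[0]):
            pairs = [
                (enc_blk.norm1, pair.norm1), (enc_blk.norm2, pair.norm2),
                (enc_blk.attn, pair.attn_w), (enc_blk.mlp, pair.mlp1),
            ]
            for src, dst in pairs:
                src_params = dict(src.named_parameters())
                dst_params = dict(dst.named_parameters())
                if any(src_params[k].shape != dst_params[k].shape
                       for k in src_params):
                    continue
                for k in src_params:
                    dst_params[k].data = src_params[k].data.copy()
                    copied += 1
        return copied


def hierarchical_forward(seq: PatchSequence, backbone: HierarchicalBackbone
                         ) -> list[np.ndarray]:
    """Run one patch sequence through the backbone; one (h, w, C) per stage."""
    with ad.no_grad():
        outs = backbone(Tensor(seq.tokens[None]))
    return [o.data[0] for o in outs]
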