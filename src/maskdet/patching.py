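"""Patch tokenisation, random mask sampling, and positional embeddings.

An image is cut into non-overlapping square patches (default 16x16), each
flattened to one token in row-major grid order.  Masking for self-supervised
pretraining draws a uniform random subset of patch indices without
replacement.  Positional information uses the fixed 2-D sine-cosine table
standard for vision transformers (a learnable table is available in the
models that consume these).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchSequence",
    "MaskPlan",
    "patchify",
    "unpatchify",
    "sample_mask",
    "sincos_position_table",
]


@dataclass
class PatchSequence:
    """Flattened patch tokens in row-major order over the patch grid."""

    tokens: np.ndarray           # (n_patches, patch_size^2 * channels)
    grid_shape: tuple[int, int]  # (rows, cols)
    patch_size: int
    channels: int
    orig_hw: tuple[int, int]     # pre-padding image size

    def __post_init__(self):
        rows, cols = self.grid_shape
        if self.tokens.shape[0] != rows * cols:
            raise ValueError("token count does not match grid shape")
        if self.tokens.shape[1] != self.patch_size**2 * self.channels:
            raise ValueError("token length does not match patch size")

    @property
    def n_patches(self) -> int:
        return self.tokens.shape[0]


@dataclass(frozen=True)
class MaskPlan:
    """Disjoint visible/masked index partition of a patch sequence."""

    visible_idx: np.ndarray
    masked_idx: np.ndarray
    mask_ratio: float
    seed: int

    def __post_init__(self):
        n = len(self.visible_idx) + len(self.masked_idx)
        union = np.union1d(self.visible_idx, self.masked_idx)
        if len(union) != n or union[0] != 0 or union[-1] != n - 1:
            raise ValueError("visible/masked indices must partition 0..n-1")

    @property
    def n_patches(self) -> int:
        return len(self.visible_idx) + len(self.masked_idx)


def pad_to_multiple(pixels: np.ndarray, patch_size: int) -> np.ndarray:
    """Zero-pad bottom/right so both spatial dims divide by patch_size."""
    h, w = pixels.shape[:2]
    ph = (-h) % patch_size
    pw = (-w) % patch_size
    if ph == 0 and pw == 0:
        return pixels
    widths = [(0, ph), (0, pw)] + [(0, 0)] * (pixels.ndim - 2)
    return np.pad(pixels, widths)


def patchify(pixels: np.ndarray, patch_size: int) -> PatchSequence:
    """Cut an image into flattened patch tokens (padding applied if needed)."""
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    orig_hw = pixels.shape[:2]
    arr = pad_to_multiple(np.asarray(pixels, dtype=float), patch_size)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w, c = arr.shape
    rows, cols = h // patch_size, w // patch_size
    tokens = (
        arr.reshape(rows, patch_size, cols, patch_size, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(rows * cols, patch_size * patch_size * c)
    )
    return PatchSequence(tokens, (rows, cols), patch_size, c, orig_hw)


def unpatchify(seq: PatchSequence, channels: int | None = None) -> np.ndarray:
    """Exact inverse of :func:`patchify` (cropped back to the original size)."""
    c = channels if channels is not None else seq.channels
    rows, cols = seq.grid_shape
    p = seq.patch_size
    if seq.tokens.shape != (rows * cols, p * p * c):
        raise ValueError("token array inconsistent with grid/patch shape")
    img = (
        seq.tokens.reshape(rows, cols, p, p, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(rows * p, cols * p, c)
    )
    h, w = seq.orig_hw
    img = img[:h, :w]
    return img[:, :, 0] if c == 1 else img


def mask_count(n_patches: int, mask_ratio: float) -> int:
    return int(round(mask_ratio * n_patches))


def sample_mask(n_patches: int, mask_ratio: float, seed: int) -> MaskPlan:
    """Uniform random mask over patch indices; both sides stay nonempty."""
    if n_patches < 2:
        raise ValueError("need at least 2 patches to mask")
    if not (0.0 < mask_ratio < 1.0):
        raise ValueError("mask_ratio must lie strictly in (0, 1)")
    n_masked = mask_count(n_patches, mask_ratio)
    if n_masked == 0 or n_masked == n_patches:
        raise ValueError(
            f"mask_ratio {mask_ratio} leaves an empty set at n={n_patches}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_patches)
    masked = np.sort(perm[:n_masked])
    visible = np.sort(perm[n_masked:])
    return MaskPlan(visible, masked, mask_ratio, seed)


def sincos_position_table(grid_shape: tuple[int, int], dim: int) -> np.ndarray:
    """Fixed 2-D sine-cosine positional table, one row per grid position.

    Half the channels encode the row coordinate, half the column, each with
    the usual geometric frequency ladder.  dim must be divisible by 4.
    """
    if dim % 4 != 0:
        raise ValueError("embedding dim must be divisible by 4")
    rows, cols = grid_shape

    def axis_embed(positions: np.ndarray, d: int) -> np.ndarray:
        omega = 1.0 / (10000 ** (np.arange(d // 2) / (d / 2.0)))
        ang = np.outer(positions, omega)
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    ys, xs = np.mgrid[0:rows, 0:cols]
    emb = np.concatenate(
        [axis_embed(ys.reshape(-1), dim // 2), axis_embed(xs.reshape(-1), dim // 2)],
        axis=1,
    )
    return emb
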