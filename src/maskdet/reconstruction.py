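"""Masked-autoencoder pretraining: encode visible patches, decode all.

The encoder is a ViT-style stack that sees only the visible (unmasked)
patches, each with its positional embedding.  The decoder re-assembles the
full-length sequence, filling every masked slot with a single shared
learnable mask token plus that slot's positional embedding, runs a second
(lighter) transformer stack, and projects back to pixel space.  Training
minimises the mean squared error between reconstructed and true pixel
intensities; by default the loss covers all pixels, with a masked-positions-
only option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam, LayerNorm, Linear, Module, TransformerBlock
from .patching import (
    MaskPlan,
    PatchSequence,
    mask_count,
    patchify,
    sincos_position_table,
    unpatchify,
)

__all__ = ["MaeModel", "ReconLoss", "mse_loss", "encode_visible", "decode_full",
           "MaskedAutoencoder"]


@dataclass(frozen=True)
class ReconLoss:
    """Mean squared reconstruction error and its per-pixel components."""

    value: float
    per_pixel: np.ndarray

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("MSE cannot be negative")


def mse_loss(pred: np.ndarray, target: np.ndarray) -> ReconLoss:
    """Pixelwise mean squared error: (1/N) sum_i (y_i - yhat_i)^2."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    per_pixel = (pred - target) ** 2
    return ReconLoss(value=float(per_pixel.mean()), per_pixel=per_pixel)


class MaeModel(Module):
    """Encoder/decoder pair with a shared learnable mask token."""

    def __init__(
        self,
        patch_dim: int,
        grid_shape: tuple[int, int],
        width: int = 128,
        depth: int = 4,
        heads: int = 4,
        dec_width: int = 64,
        dec_depth: int = 2,
        dec_heads: int = 4,
        mlp_ratio: float = 2.0,
        scale_mode: str = "sqrt",
        learnable_pos: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.patch_dim = patch_dim
        self.grid_shape = tuple(grid_shape)
        self.width = width
        n = grid_shape[0] * grid_shape[1]
        self.patch_projection = Linear(patch_dim, width, rng)
        enc_pos = sincos_position_table(grid_shape, width)
        dec_pos = sincos_position_table(grid_shape, dec_width)
        self.pos_table = Tensor(enc_pos, requires_grad=learnable_pos)
        self.dec_pos_table = Tensor(dec_pos, requires_grad=learnable_pos)
        self.encoder = [
            TransformerBlock(width, heads, mlp_ratio, rng, scale_mode)
            for _ in range(depth)
        ]
        self.enc_norm = LayerNorm(width)
        self.decoder_embed = Linear(width, dec_width, rng)
        self.mask_token = Tensor(rng.normal(0, 0.02, size=(dec_width,)),
                                 requires_grad=True)
        self.decoder = [
            TransformerBlock(dec_width, dec_heads, mlp_ratio, rng, scale_mode)
            for _ in range(dec_depth)
        ]
        self.dec_norm = LayerNorm(dec_width)
        self.output_projection = Linear(dec_width, patch_dim, rng)
        self._n_patches = n

    # -- forward pieces -------------------------------------------------------
    def encode_visible(self, tokens: Tensor, visible_idx: np.ndarray,
                       drop: float = 0.0, rng=None, training=False) -> Tensor:
        """tokens (B, N, patch_dim), visible_idx (B, K) -> latents (B, K, width)."""
        x = self.patch_projection(tokens) + self.pos_table
        x = ad.gather_tokens(x, visible_idx)
        for blk in self.encoder:
            x = blk(x, drop, rng, training)
        return self.enc_norm(x)

    def decode_full(self, latent: Tensor, visible_idx: np.ndarray,
                    drop: float = 0.0, rng=None, training=False) -> Tensor:
        """latents (B, K, width) -> reconstructed tokens (B, N, patch_dim)."""
        y = self.decoder_embed(latent)
        y = ad.scatter_tokens(y, visible_idx, self._n_patches, self.mask_token)
        y = y + self.dec_pos_table
        for blk in self.decoder:
            y = blk(y, drop, rng, training)
        return self.output_projection(self.dec_norm(y))

    def forward(self, tokens: Tensor, visible_idx: np.ndarray,
                drop: float = 0.0, rng=None, training=False) -> Tensor:
        latent = self.encode_visible(tokens, visible_idx, drop, rng, training)
        return self.decode_full(latent, visible_idx, drop, rng, training)

    def encoder_parameter_count(self) -> int:
        n = sum(p.size for blk in self.encoder for p in blk.parameters())
        return n + self.patch_projection.weight.size

    def decoder_parameter_count(self) -> int:
        n = sum(p.size for blk in self.decoder for p in blk.parameters())
        return n + self.output_projection.weight.size + self.mask_token.size


def encode_visible(seq: PatchSequence, plan: MaskPlan, model: MaeModel) -> np.ndarray:
    """Single-image wrapper: latent vectors for the visible patches only."""
    if plan.n_patches != seq.n_patches:
        raise ValueError("mask plan inconsistent with patch sequence")
    with ad.no_grad():
        out = model.encode_visible(
            Tensor(seq.tokens[None]), plan.visible_idx[None]
        )
    return out.data[0]


def decode_full(latent: np.ndarray, plan: MaskPlan, model: MaeModel,
                seq_template: PatchSequence) -> PatchSequence:
    """Single-image wrapper: full reconstructed patch sequence."""
    if latent.shape[0] != len(plan.visible_idx):
        raise ValueError("latent count must equal number of visible patches")
    with ad.no_grad():
        out = model.decode_full(Tensor(latent[None]), plan.visible_idx[None])
    return PatchSequence(
        out.data[0], seq_template.grid_shape, seq_template.patch_size,
        seq_template.channels, seq_template.orig_hw,
    )


class MaskedAutoencoder:
    """Scikit-learn style estimator for masked-patch reconstruction pretraining.

    ``fit`` runs the self-supervised objective on a list/array of images
    (values in [0,1]); ``transform`` reconstructs images by masking at the
    training ratio and inpainting the hidden patches (visible patches keep
    their original pixels).  ``loss_trace_`` records the mean training MSE
    per epoch.
    """

    def __init__(
        self,
        patch_size: int = 16,
        mask_ratio: float = 0.75,
        width: int = 128,
        depth: int = 4,
        heads: int = 4,
        dec_width: int = 64,
        dec_depth: int = 2,
        mlp_ratio: float = 2.0,
        loss_on: str = "all",
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-4,
        weight_decay: float = 5e-4,
        dropout: float = 0.0,
        scale_mode: str = "sqrt",
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.mask_ratio = mask_ratio
        self.width = width
        self.depth = depth
        self.heads = heads
        self.dec_width = dec_width
        self.dec_depth = dec_depth
        self.mlp_ratio = mlp_ratio
        self.loss_on = loss_on
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.scale_mode = scale_mode
        self.random_state = random_state

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self.__init__.__code__.co_varnames[1:]
                if hasattr(self, k)}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -------------------------------------------------------------------------
    def _tokenize(self, images) -> tuple[np.ndarray, PatchSequence]:
        seqs = [patchify(np.asarray(im, dtype=float), self.patch_size)
                for im in images]
        grid = seqs[0].grid_shape
        if any(s.grid_shape != grid for s in seqs):
            raise ValueError("all images must share one size")
        return np.stack([s.tokens for s in seqs]), seqs[0]

    def fit(self, X, y=None):
        if not (0.0 < self.mask_ratio < 1.0):
            raise ValueError("mask_ratio must lie in (0,1)")
        if len(X) == 0:
            raise ValueError("empty training set")
        if self.loss_on not in ("all", "masked"):
            raise ValueError("loss_on must be 'all' or 'masked'")
        tokens, template = self._tokenize(X)
        n_imgs, n_patches, patch_dim = tokens.shape
        rng = np.random.default_rng(self.random_state)
        self.model_ = MaeModel(
            patch_dim, template.grid_shape, self.width, self.depth, self.heads,
            self.dec_width, self.dec_depth, self.heads, self.mlp_ratio,
            self.scale_mode, rng=rng,
        )
        self.template_ = template
        opt = Adam(self.model_.parameters(), lr=self.lr,
                   weight_decay=self.weight_decay)
        n_vis = n_patches - mask_count(n_patches, self.mask_ratio)
        if n_vis == 0 or n_vis == n_patches:
            raise ValueError("mask_ratio leaves no visible or no masked patches")
        self.loss_trace_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n_imgs)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_imgs, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = tokens[idx]
                # fresh random mask per image per step
                vis = np.stack([
                    rng.permutation(n_patches)[: n_vis] for _ in idx
                ])
                vis.sort(axis=1)
                loss = self._step_loss(batch, vis, rng)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"pretraining diverged (loss={loss.item()}) at epoch {_epoch}"
                    )
            self.loss_trace_.append(epoch_loss / max(n_batches, 1))
        return self

    def _step_loss(self, batch: np.ndarray, vis: np.ndarray,
                   rng: np.random.Generator) -> Tensor:
        pred = self.model_.forward(Tensor(batch), vis, self.dropout, rng,
                                   training=True)
        diff = pred - Tensor(batch)
        if self.loss_on == "masked":
            mask = np.ones(batch.shape[:2], dtype=bool)
            mask[np.arange(len(vis))[:, None], vis] = False
            diff = diff * mask[:, :, None].astype(float)
            denom = float(mask.sum() * batch.shape[2])
            return (diff * diff).sum() / denom
        return (diff * diff).mean()

    def transform(self, X, seed: int = 0) -> list[np.ndarray]:
        """Reconstruct images through the trained encoder/decoder.

        A random mask at the training ratio is applied (the encoder never
        sees full sequences during fitting, so feeding one would be out of
        distribution); visible patches keep their original pixels and masked
        patches take the decoder's prediction."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        n = self.template_.n_patches
        n_vis = n - mask_count(n, self.mask_ratio)
        out = []
        with ad.no_grad():
            for im in X:
                seq = patchify(np.asarray(im, dtype=float), self.patch_size)
                vis = np.sort(rng.permutation(n)[:n_vis])[None]
                rec = self.model_.forward(Tensor(seq.tokens[None]), vis)
                tokens = rec.data[0]
                tokens[vis[0]] = seq.tokens[vis[0]]
                rec_seq = PatchSequence(tokens, seq.grid_shape,
                                        seq.patch_size, seq.channels, seq.orig_hw)
                out.append(np.clip(unpatchify(rec_seq), 0.0, 1.0))
        return out

    def reconstruction_loss(self, X, seed: int = 0) -> float:
        """Mean masked-reconstruction MSE over X at the configured ratio."""
        self._check_fitted()
        tokens, _ = self._tokenize(X)
        n_patches = tokens.shape[1]
        n_vis = n_patches - mask_count(n_patches, self.mask_ratio)
        rng = np.random.default_rng(seed)
        vis = np.stack([rng.permutation(n_patches)[:n_vis] for _ in tokens])
        vis.sort(axis=1)
        with ad.no_grad():
            pred = self.model_.forward(Tensor(tokens), vis)
        return mse_loss(pred.data, tokens).value

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
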