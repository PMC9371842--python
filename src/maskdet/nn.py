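"""Layer primitives and the Adam optimizer on top of the autodiff engine.

Everything is deterministic given the ``numpy.random.Generator`` passed at
construction / call time; no global RNG state is consulted.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, p in self.named_parameters():
            params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Linear(Module):
    """Affine map y = x W + b over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        std = scale if scale is not None else np.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / ((var + self.eps) ** 0.5)
        return normed * self.gamma + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


class Mlp(Module):
    """Two-layer GELU MLP used inside transformer blocks."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor, drop: float = 0.0,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        h = self.fc1(x).gelu()
        h = dropout(h, drop, rng, training)
        return self.fc2(h)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product self-attention over (B, N, C) tokens.

    ``scale_mode='sqrt'`` uses the conventional 1/sqrt(d_head) logit scaling;
    ``'linear'`` divides by d_head instead (the alternative form some papers
    print).  With ``n_heads=1`` this reduces to plain single-head attention
    with learned query/key/value maps and an output projection.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 scale_mode: str = "sqrt"):
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        if scale_mode not in ("sqrt", "linear"):
            raise ValueError(f"unknown scale_mode {scale_mode!r}")
        self.dim = dim
        self.n_heads = n_heads
        self.scale_mode = scale_mode
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        """attn_mask: additive logits mask broadcastable to (B, heads, N, N)."""
        bsz, n, _ = x.shape
        hd = self.dim // self.n_heads
        scale = 1.0 / np.sqrt(hd) if self.scale_mode == "sqrt" else 1.0 / hd

        def split(t: Tensor) -> Tensor:  # (B, N, C) -> (B, H, N, hd)
            return t.reshape(bsz, n, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * scale
        if attn_mask is not None:
            logits = logits + attn_mask
        attn = softmax(logits, axis=-1)
        ctx = attn @ v  # (B, H, N, hd)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(bsz, n, self.dim)
        return self.w_out(ctx)


class TransformerBlock(Module):
    """Pre-norm block: LN -> MHA -> residual; LN -> MLP -> residual."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator, scale_mode: str = "sqrt"):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng, scale_mode)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor, drop: float = 0.0,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        x = x + dropout(self.attn(self.norm1(x)), drop, rng, training)
        x = x + self.mlp(self.norm2(x), drop, rng, training)
        return x


class Adam:
    """Adam with decoupled-from-nothing classic L2 (added to gradients)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
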