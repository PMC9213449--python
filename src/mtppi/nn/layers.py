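"""Neural network layers built on the autodiff primitives.

All layers operate on (batch, time, channels) tensors and are padding
aware: attention masks padded key positions, and the bidirectional LSTM
reverses each sequence by its true length. Initialization is glorot
uniform throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .autodiff import (
    Adam,
    Parameter,
    Tensor,
    concat,
    glorot_uniform,
    reverse_padded,
    unfold1d,
)


@dataclass
class ForwardContext:
    """Per-call state threaded through the layer stack."""

    lengths: np.ndarray  # (B,) true sequence lengths
    step_mask: np.ndarray  # (B, T, 1) float, 1 inside the sequence
    train: bool = False
    rng: Optional[np.random.Generator] = None


class Module:
    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        seen = set()
        for value in vars(self).values():
            for p in self._collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    @staticmethod
    def _collect(value):
        if isinstance(value, Parameter):
            yield value
        elif isinstance(value, Module):
            yield from value.parameters()
        elif isinstance(value, (list, tuple)):
            for v in value:
                yield from Module._collect(v)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: List[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state, strict=True):
            p.data[...] = arr


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, name: str = "dense"):
        self.w = Parameter(glorot_uniform(rng, n_in, n_out), f"{name}.w")
        self.b = Parameter(np.zeros(n_out), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, name: str = "ln"):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        if not ctx.train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = ctx.rng.random(x.data.shape) < keep
        return x * (mask.astype(float) / keep)


class Conv1d(Module):
    """Same-padded 1-D convolution over the time axis (im2col matmul)."""

    def __init__(self, rng, n_in: int, n_out: int, kernel: int,
                 name: str = "conv"):
        fan_in = n_in * kernel
        self.w = Parameter(
            glorot_uniform(rng, fan_in, n_out), f"{name}.w"
        )
        self.b = Parameter(np.zeros(n_out), f"{name}.b")
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return unfold1d(x, self.kernel) @ self.w + self.b


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, d_model: int, n_heads: int, name: str = "mha"):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Dense(rng, d_model, 3 * d_model, f"{name}.qkv")
        self.out = Dense(rng, d_model, d_model, f"{name}.out")

    def __call__(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        B, T, D = x.data.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, H, dh).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, H, T, dh)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        # padded keys get a large negative bias before the softmax
        key_bias = np.where(
            ctx.step_mask[:, None, None, :, 0].astype(bool), 0.0, -1e9
        )
        attn = (scores + key_bias).softmax(axis=-1)
        ctxv = attn @ v  # (B, H, T, dh)
        merged = ctxv.transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.out(merged)


class TransformerLayer(Module):
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, name: str = "tf"):
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads, f"{name}.attn")
        self.ln1 = LayerNorm(d_model, name=f"{name}.ln1")
        self.ln2 = LayerNorm(d_model, name=f"{name}.ln2")
        self.ff1 = Dense(rng, d_model, d_ff, f"{name}.ff1")
        self.ff2 = Dense(rng, d_ff, d_model, f"{name}.ff2")
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, ctx), ctx))
        h = self.ff2(self.ff1(x).relu())
        x = self.ln2(x + self.drop(h, ctx))
        return x * ctx.step_mask


class LSTM(Module):
    """Unidirectional LSTM; gate order input, forget, cell, output."""

    def __init__(self, rng, n_in: int, n_hidden: int, name: str = "lstm"):
        self.n_hidden = n_hidden
        self.w = Parameter(
            glorot_uniform(rng, n_in + n_hidden, 4 * n_hidden),
            f"{name}.w",
        )
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b, f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        nh = self.n_hidden
        h = Tensor(np.zeros((B, nh)))
        c = Tensor(np.zeros((B, nh)))
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            z = concat([xt, h], axis=1) @ self.w + self.b
            i = z[:, :nh].sigmoid()
            f = z[:, nh:2 * nh].sigmoid()
            g = z[:, 2 * nh:3 * nh].tanh()
            o = z[:, 3 * nh:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, nh))
        return concat(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM; concatenates forward and backward passes.

    The backward pass runs on per-row length-reversed input so padding
    never leaks into real positions.
    """

    def __init__(self, rng, n_in: int, n_hidden: int, name: str = "bilstm"):
        self.fwd = LSTM(rng, n_in, n_hidden, f"{name}.fwd")
        self.bwd = LSTM(rng, n_in, n_hidden, f"{name}.bwd")

    def __call__(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        out_f = self.fwd(x)
        rev = reverse_padded(x, ctx.lengths)
        out_b = reverse_padded(self.bwd(rev), ctx.lengths)
        return concat([out_f, out_b], axis=2) * ctx.step_mask


__all__ = [
    "Adam",
    "BiLSTM",
    "Conv1d",
    "Dense",
    "Dropout",
    "ForwardContext",
    "LSTM",
    "LayerNorm",
    "Module",
    "MultiHeadSelfAttention",
    "TransformerLayer",
]
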