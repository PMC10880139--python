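"""Pre-norm transformer encoder with learnable [CLS] tokens.

The encoder follows the vision-transformer convention: the input sequence is
[CLS_1..CLS_n, s_1..s_N] plus a learnable positional embedding, then L
pre-norm blocks  z = MSA(LN(h)) + h,  h' = MLP(LN(z)) + z.  Per-layer,
per-head attention matrices (softmax(Q K^T / sqrt(d_k))) are retained for
interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["TransformerConfig", "EncoderState", "TransformerEncoder", "attention_map"]


@dataclass(frozen=True)
class TransformerConfig:
    depth: int = 2
    heads: int = 4
    width: int = 32
    mlp_ratio: float = 4.0
    n_cls: int = 1
    dropout: float = 0.0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.width % self.heads:
            raise ValueError(f"width {self.width} not divisible by heads {self.heads}")
        if self.n_cls < 0:
            raise ValueError("n_cls must be >= 0")


@dataclass
class EncoderState:
    """Final hidden sequence plus attention tensors of every layer.

    ``hidden``: (B, n_cls + N, C); ``attention``: one (B, H, S, S)
    row-stochastic tensor per layer.
    """

    hidden: nn.Tensor
    attention: list


class _Block(nn.Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        C = config.width
        self.heads = config.heads
        self.dk = C // config.heads
        self.ln1 = nn.LayerNorm(C)
        self.qkv = nn.Linear(C, 3 * C, rng)
        self.proj = nn.Linear(C, C, rng)
        self.ln2 = nn.LayerNorm(C)
        hidden = int(round(config.mlp_ratio * C))
        self.fc1 = nn.Linear(C, hidden, rng)
        self.fc2 = nn.Linear(hidden, C, rng)
        self.drop = nn.Dropout(config.dropout, rng)

    def attend(self, h: nn.Tensor):
        """Multi-head self-attention on the normalized input; returns (out, attn)."""
        B, S, C = h.shape
        H, dk = self.heads, self.dk
        qkv = self.qkv(h)  # (B, S, 3C)
        q = qkv[:, :, :C].reshape(B, S, H, dk).transpose(0, 2, 1, 3)
        k = qkv[:, :, C : 2 * C].reshape(B, S, H, dk).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * C :].reshape(B, S, H, dk).transpose(0, 2, 1, 3)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        attn = nn.softmax(logits, axis=-1)  # (B, H, S, S)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, S, C)
        return self.proj(out), attn

    def __call__(self, h: nn.Tensor):
        msa, attn = self.attend(self.ln1(h))
        z = self.drop(msa) + h
        mlp = self.fc2(nn.gelu(self.fc1(self.ln2(z))))
        return self.drop(mlp) + z, attn


class TransformerEncoder(nn.Module):
    """Stack of pre-norm self-attention blocks over a fixed-length sequence."""

    def __init__(self, config: TransformerConfig, n_tokens: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.n_tokens = n_tokens
        C = config.width
        self.cls = nn.Parameter(nn.trunc_normal(rng, (config.n_cls, C)))
        self.pos = nn.Parameter(nn.trunc_normal(rng, (config.n_cls + n_tokens, C)))
        self.blocks = [_Block(config, rng) for _ in range(config.depth)]

    def encode(self, tokens) -> EncoderState:
        """``tokens``: (B, N, C) with N = ``n_tokens``; returns the encoder state."""
        x = nn.astensor(tokens)
        B, N, C = x.shape
        if C != self.config.width:
            raise ValueError(f"token width {C} != model width {self.config.width}")
        if N != self.n_tokens:
            raise ValueError(f"expected {self.n_tokens} tokens, got {N}")
        if self.config.n_cls > 0:
            cls = self.cls.reshape(1, self.config.n_cls, C).broadcast_to(
                (B, self.config.n_cls, C)
            )
            h = nn.concat([cls, x], axis=1) + self.pos
        else:
            h = x + self.pos
        attns = []
        for block in self.blocks:
            h, attn = block(h)
            attns.append(attn)
        return EncoderState(hidden=h, attention=attns)

    __call__ = encode


def attention_map(state: EncoderState, layer: int, head: int) -> np.ndarray:
    """Row-stochastic attention matrix of one layer/head, shape (B, S, S)."""
    attn = state.attention[layer]  # IndexError if layer out of range
    if not -attn.shape[1] <= head < attn.shape[1]:
        raise IndexError(f"head {head} out of range for {attn.shape[1]} heads")
    return attn.data[:, head]
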