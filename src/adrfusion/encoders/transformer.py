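"""Transformer encoder over SMILES token sequences.

A standard post-norm encoder stack: token embedding + sinusoidal positional
encoding, then ``n_layers`` blocks of (masked multi-head self-attention,
position-wise feed-forward), each sublayer wrapped in a residual connection
and layer normalization.  The per-token outputs are reduced to one vector
per drug by masked mean pooling over non-padding positions, so padding can
never leak into the embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..autodiff import Tensor
from ..chem_io import TokenSequence
from .. import nn


@dataclass
class TransformerConfig:
    vocab_size: int = 64
    d_model: int = 512
    n_heads: int = 8
    d_ff: int = 2048
    dropout: float = 0.1
    n_layers: int = 2
    max_len: int = 128
    pooling: str = "mean"  # "mean" | "max" over non-pad positions

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional encodings."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class MultiHeadAttention(nn.Module):
    """Scaled dot-product self-attention with padding-key masking.

    Q, K, V are per-head linear projections of the input; attention scores
    softmax(QK^T / sqrt(d_k)) exclude masked (padding) key positions; head
    outputs are concatenated and projected by W_o.
    """

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.h = config.n_heads
        self.d_k = config.d_k
        self.Wq = nn.Linear(d, d, rng)
        self.Wk = nn.Linear(d, d, rng)
        self.Wv = nn.Linear(d, d, rng)
        self.Wo = nn.Linear(d, d, rng)

    def forward(self, H: Tensor, key_mask: np.ndarray) -> Tensor:
        """H: (B, L, d_model); key_mask: (B, L) bool, True = real token."""
        B, L, d = H.shape
        if not key_mask.any(axis=1).all():
            raise ValueError("a sequence with every position masked")

        def split(x: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, d_k)
            return x.reshape(B, L, self.h, self.d_k).swapaxes(1, 2)

        q, k, v = split(self.Wq(H)), split(self.Wk(H)), split(self.Wv(H))
        scores = (q @ k.T) / math.sqrt(self.d_k)  # (B, h, L, L)
        mask = np.broadcast_to(key_mask[:, None, None, :], scores.shape)
        attn = scores.softmax(axis=-1, mask=mask)
        out = (attn @ v).swapaxes(1, 2).reshape(B, L, d)
        return self.Wo(out)


class FeedForward(nn.Module):
    """Position-wise FFN: max(0, xW1 + b1) W2 + b2."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.lin1 = nn.Linear(config.d_model, config.d_ff, rng)
        self.lin2 = nn.Linear(config.d_ff, config.d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(nn.Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(config, rng)
        self.ffn = FeedForward(config, rng)
        self.norm1 = nn.LayerNorm(config.d_model)
        self.norm2 = nn.LayerNorm(config.d_model)
        self.drop1 = nn.Dropout(config.dropout, rng)
        self.drop2 = nn.Dropout(config.dropout, rng)

    def forward(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, key_mask)))
        x = self.norm2(x + self.drop2(self.ffn(x)))
        return x


class SequenceEncoder(nn.Module):
    """Full sequence branch: tokens -> d_model embedding per drug."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.embed = nn.Embedding(config.vocab_size, config.d_model, rng)
        self.pos = sinusoidal_positions(config.max_len, config.d_model)
        self.layers = [EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.drop = nn.Dropout(config.dropout, rng)

    @property
    def output_dim(self) -> int:
        return self.config.d_model

    def forward(self, token_ids: np.ndarray, n_real: np.ndarray) -> Tensor:
        """token_ids: (B, L) int; n_real: (B,) real-token counts."""
        token_ids = np.atleast_2d(token_ids)
        n_real = np.atleast_1d(n_real)
        if (n_real < 1).any():
            raise ValueError("sequence with zero real tokens")
        B, L = token_ids.shape
        key_mask = np.arange(L)[None, :] < n_real[:, None]
        x = self.embed(token_ids) + Tensor(self.pos[:L])
        x = self.drop(x)
        for layer in self.layers:
            x = layer(x, key_mask)
        # masked pooling over non-pad positions
        m = Tensor(key_mask.astype(float)[:, :, None])
        if self.config.pooling == "mean":
            pooled = (x * m).sum(axis=1) / Tensor(n_real[:, None].astype(float))
        elif self.config.pooling == "max":
            neg = Tensor(np.where(key_mask, 0.0, -1e30)[:, :, None])
            pooled = (x + neg).max(axis=1)
        else:
            raise ValueError(f"unknown pooling {self.config.pooling!r}")
        return pooled


# -- functional surface ------------------------------------------------------

def multi_head_attention(H: Tensor | np.ndarray, params: MultiHeadAttention,
                         key_mask: np.ndarray) -> Tensor:
    """Single-sequence functional wrapper: H is (L, d_model)."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    out = params(H.reshape(1, *H.shape), np.atleast_2d(key_mask))
    return out.reshape(*out.shape[1:])


def feed_forward(x: Tensor | np.ndarray, params: FeedForward) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    return params(x)


def encode_sequence(tokens: TokenSequence, encoder: SequenceEncoder) -> Tensor:
    """Encode one tokenized drug to its branch embedding (length d_model)."""
    out = encoder(tokens.ids[None, :], np.array([tokens.n_real]))
    return out.reshape(-1)
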