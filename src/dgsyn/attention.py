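"""Fine-granularity module: interaction-aware cross- and self-attention.

Each drug contributes a small set of substructure tokens (one per
message-passing layer, from the pooled readouts) and the cell line
contributes a single token (its embedding projected to token width). Three
token-set pairs — drug A ↔ drug B, drug A ↔ cell, drug B ↔ cell — each run
through four-head scaled dot-product cross-attention in both query/key
directions, and each direction is pooled by the mean over query positions,
yielding six interaction vectors in the fixed order

    (A←B, B←A, A←cell, cell←A, B←cell, cell←B).

Self-attention over the six vectors followed by one linear layer whose
weights are shared across the six positions produces the fine-level
representation (the flattened concatenation of the six post-linear tokens).
One cross-attention parameter set serves all six directions, which makes
the bundle exactly swap-equivariant in the two drugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import Linear, Module, softmax


@dataclass
class InteractionBundle:
    vectors: Tensor          # [batch, 6, d] ordered as documented above
    fine_embedding: Tensor   # [batch, 6·d]
    attention_maps: dict[str, np.ndarray]  # row-stochastic, per direction/stage


class MultiHeadAttention(Module):
    """Scaled dot-product attention with concatenated heads."""

    def __init__(self, d_model: int, heads: int, rng):
        super().__init__()
        if d_model % heads:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.heads = heads
        self.d_h = d_model // heads
        self.wq = Linear(d_model, d_model, rng, bias=False)
        self.wk = Linear(d_model, d_model, rng, bias=False)
        self.wv = Linear(d_model, d_model, rng, bias=False)
        self.wo = Linear(d_model, d_model, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.d_h).transpose(0, 2, 1, 3)  # [B,H,T,dh]

    def __call__(self, queries: Tensor, keys: Tensor) -> tuple[Tensor, np.ndarray]:
        """Attend ``queries`` over ``keys`` (values = keys side).

        Returns attended tokens [B, Tq, d] and the attention map
        [B, heads, Tq, Tk] (each row sums to 1).
        """
        if keys.shape[-2] == 0:
            raise ValueError("empty key set")
        q = self._split(self.wq(queries))
        k = self._split(self.wk(keys))
        v = self._split(self.wv(keys))
        scores = (q @ k.swap_last()) * (1.0 / np.sqrt(self.d_h))
        attn = softmax(scores, axis=-1)
        out = attn @ v  # [B,H,Tq,dh]
        b, _, tq, _ = out.shape
        merged = out.transpose(0, 2, 1, 3).reshape(b, tq, self.heads * self.d_h)
        return self.wo(merged), attn.data.copy()


def cross_attend(attention: MultiHeadAttention, queries: Tensor, keys: Tensor
                 ) -> tuple[Tensor, np.ndarray]:
    """Cross-attention pooled to one vector per sample (mean over queries)."""
    attended, maps = attention(queries, keys)
    return attended.mean(axis=-2), maps


class FineInteraction(Module):
    """The full fine-granularity block over (drug A, drug B, cell) token sets."""

    DIRECTIONS = ("a_from_b", "b_from_a", "a_from_cell", "cell_from_a",
                  "b_from_cell", "cell_from_b")

    def __init__(self, token_dim: int, cell_dim: int, heads: int, rng):
        super().__init__()
        self.token_dim = token_dim
        self.cell_proj = Linear(cell_dim, token_dim, rng)
        self.cross = MultiHeadAttention(token_dim, heads, rng)
        self.self_attn = MultiHeadAttention(token_dim, heads, rng)
        self.shared_linear = Linear(token_dim, token_dim, rng)

    def __call__(self, tokens_a: Tensor, tokens_b: Tensor, cell: Tensor
                 ) -> InteractionBundle:
        """``tokens_a``/``tokens_b``: [B, T, d]; ``cell``: [B, d_cell]."""
        b = tokens_a.shape[0]
        cell_tok = self.cell_proj(cell).reshape(b, 1, self.token_dim)
        pairs = {
            "a_from_b": (tokens_a, tokens_b),
            "b_from_a": (tokens_b, tokens_a),
            "a_from_cell": (tokens_a, cell_tok),
            "cell_from_a": (cell_tok, tokens_a),
            "b_from_cell": (tokens_b, cell_tok),
            "cell_from_b": (cell_tok, tokens_b),
        }
        pooled, maps = [], {}
        for name in self.DIRECTIONS:
            q, k = pairs[name]
            vec, attn = cross_attend(self.cross, q, k)
            pooled.append(vec)
            maps[name] = attn
        six = stack(pooled, axis=1)  # [B, 6, d]
        attended, self_map = self.self_attn(six, six)
        maps["self"] = self_map
        post = self.shared_linear(attended)  # same weights for each of the 6 tokens
        fine = post.reshape(b, 6 * self.token_dim)
        return InteractionBundle(vectors=six, fine_embedding=fine, attention_maps=maps)
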