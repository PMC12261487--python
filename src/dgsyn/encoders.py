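"""Initialization encoders: molecular-graph networks and the cell-line MLP.

A drug graph passes through three message-passing layers (GIN by default;
GCN or multi-head GAT as ablation variants). After every layer a
self-attention pooling step scores atoms with a one-layer graph
convolution, keeps the top ``ceil(ratio · n)`` atoms gated by tanh of
their score, and reads the retained atoms out (mean by default) into one
substructure token per layer. Jumping-knowledge concatenation of the layer
tokens followed by a linear projection yields the molecular-level
embedding. Cell lines are encoded by a two-layer perceptron over their
expression row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .chem import MolecularGraph
from .nn import MLP, Linear, Module, dropout

READOUTS = ("sagpool", "add", "max", "mean")
ENCODER_TYPES = ("gin", "gcn", "gat")


@dataclass
class DrugEncoding:
    """Per-drug output of the initialization module."""

    drug_id: str
    per_layer_substructure: list  # retained-node feature Tensors, one per layer
    substructure_tokens: Tensor   # [n_layers, token_dim] per-layer readout tokens
    molecular_embedding: Tensor   # [d_mol]
    atom_importance: list = field(default_factory=list)  # per layer, np arrays [n_atoms]


def _sym_norm_adjacency(adj: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} used by the scoring GCN and the GCN variant."""
    a_hat = adj + np.eye(adj.shape[0])
    deg = a_hat.sum(axis=1)
    d = 1.0 / np.sqrt(deg)
    return a_hat * d[:, None] * d[None, :]


class GINLayer(Module):
    """h' = MLP((1 + ε)·h + Σ_neighbors h), 2-layer MLP with ReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng, eps: float = 0.0):
        super().__init__()
        self.eps = eps
        self.mlp = MLP([in_dim, out_dim, out_dim], rng, final_activation=True)

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        agg = Tensor(adj + (1.0 + self.eps) * np.eye(adj.shape[0]))
        return self.mlp(agg @ h)


class GCNLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng, **_):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        return self.lin(Tensor(_sym_norm_adjacency(adj)) @ h).relu()


class GATLayer(Module):
    """Multi-head graph attention with additive (LeakyReLU) scores."""

    def __init__(self, in_dim: int, out_dim: int, rng, heads: int = 1, **_):
        super().__init__()
        if out_dim % heads:
            raise ValueError("out_dim must be divisible by heads")
        self.heads = heads
        self.d_h = out_dim // heads
        self.lin = Linear(in_dim, out_dim, rng, bias=False)
        self.att_src = Tensor(rng.normal(0, 0.1, (heads, self.d_h)), requires_grad=True)
        self.att_dst = Tensor(rng.normal(0, 0.1, (heads, self.d_h)), requires_grad=True)

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        n = adj.shape[0]
        hw = self.lin(h).reshape(n, self.heads, self.d_h).transpose(1, 0, 2)  # [H,n,d]
        a_src = (hw * self.att_src.reshape(self.heads, 1, self.d_h)).sum(axis=-1, keepdims=True)
        a_dst = (hw * self.att_dst.reshape(self.heads, 1, self.d_h)).sum(axis=-1, keepdims=True)
        scores = (a_src + a_dst.swap_last()).leaky_relu(0.2)  # [H,n,n]
        mask = adj + np.eye(n)  # attend over neighbors and self
        neg = Tensor(np.where(mask > 0, 0.0, -1e9))
        scores = scores + neg
        shift = Tensor(scores.data.max(axis=-1, keepdims=True))
        e = (scores - shift).exp() * Tensor(mask > 0)
        alpha = e / (e.sum(axis=-1, keepdims=True) + 1e-12)
        out = (alpha @ hw).transpose(1, 0, 2).reshape(n, self.heads * self.d_h)
        return out.relu()


_LAYER_TYPES = {"gin": GINLayer, "gcn": GCNLayer, "gat": GATLayer}


class SAGPool(Module):
    """Self-attention pooling: one-layer GCN scores, top-⌈ratio·n⌉ retained.

    Ties in the scores break toward lower atom indices (stable argsort on
    the negated scores), and a single-atom graph always retains its atom.
    """

    def __init__(self, dim: int, rng, ratio: float = 0.5):
        super().__init__()
        self.ratio = ratio
        self.score_weight = Tensor(rng.normal(0, math.sqrt(1.0 / dim), (dim, 1)),
                                   requires_grad=True)

    def scores(self, h: Tensor, adj: np.ndarray) -> Tensor:
        return Tensor(_sym_norm_adjacency(adj)) @ h @ self.score_weight  # [n,1]

    def __call__(self, h: Tensor, adj: np.ndarray) -> tuple[np.ndarray, Tensor, Tensor]:
        s = self.scores(h, adj)
        flat = s.data.ravel()
        k = max(1, math.ceil(self.ratio * len(flat)))
        retained = np.sort(np.argsort(-flat, kind="stable")[:k])
        gated = h.gather(retained) * s.gather(retained).tanh()
        return retained, s, gated


def graph_readout(node_features: Tensor, kind: str) -> Tensor:
    if kind in ("mean", "sagpool"):  # sagpool readout = mean over retained nodes
        return node_features.mean(axis=0)
    if kind == "add":
        return node_features.sum(axis=0)
    if kind == "max":
        return node_features.amax(axis=0)
    raise ValueError(f"unknown readout {kind!r}; choose one of {READOUTS}")


class DrugEncoder(Module):
    """GIN/GCN/GAT stack with per-layer pooled readout tokens and JK concat."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...],
        rng,
        encoder: str = "gin",
        readout: str = "sagpool",
        pool_ratio: float = 0.5,
        heads: int = 1,
        gin_eps: float = 0.0,
        d_mol: int | None = None,
        dropout_rate: float = 0.0,
    ):
        super().__init__()
        if encoder not in _LAYER_TYPES:
            raise ValueError(f"unknown encoder {encoder!r}; choose one of {ENCODER_TYPES}")
        if readout not in READOUTS:
            raise ValueError(f"unknown readout {readout!r}; choose one of {READOUTS}")
        self.readout = readout
        self.dropout_rate = dropout_rate
        self._rng = rng
        dims = [in_dim, *hidden]
        cls = _LAYER_TYPES[encoder]
        self.layers = [cls(a, b, rng, eps=gin_eps) if encoder == "gin"
                       else cls(a, b, rng, heads=heads)
                       for a, b in zip(dims[:-1], dims[1:])]
        self.pools = [SAGPool(d, rng, pool_ratio) for d in hidden] if readout == "sagpool" else []
        self.d_mol = d_mol or sum(hidden)
        self.jk_proj = Linear(sum(hidden), self.d_mol, rng)

    def __call__(self, graph: MolecularGraph) -> DrugEncoding:
        adj = graph.adjacency()
        h = Tensor(graph.atom_features)
        tokens, retained_sets, importances = [], [], []
        for i, layer in enumerate(self.layers):
            h = layer(h, adj)
            h = dropout(h, self.dropout_rate, self._rng, self.training)
            if self.readout == "sagpool":
                retained, scores, gated = self.pools[i](h, adj)
                tokens.append(graph_readout(gated, "mean"))
                retained_sets.append(gated)
                importances.append(scores.data.ravel().copy())
            else:
                tokens.append(graph_readout(h, self.readout))
                retained_sets.append(h)
                importances.append(np.full(graph.n_atoms, 1.0 / graph.n_atoms))
        from .autodiff import stack as _stack
        jk = concat(tokens, axis=0).reshape(1, -1)
        molecular = self.jk_proj(jk).reshape(self.d_mol)
        return DrugEncoding(
            drug_id=graph.drug_id,
            per_layer_substructure=retained_sets,
            substructure_tokens=_stack(tokens, axis=0),
            molecular_embedding=molecular,
            atom_importance=importances,
        )


class CellEncoder(Module):
    """Two affine+ReLU layers over a z-scored expression row."""

    def __init__(self, n_genes: int, hidden: tuple[int, int], rng,
                 dropout_rate: float = 0.0):
        super().__init__()
        self.n_genes = n_genes
        self.mlp = MLP([n_genes, *hidden], rng, final_activation=True,
                       dropout_rate=dropout_rate)

    def __call__(self, rows: Tensor) -> Tensor:
        if rows.shape[-1] != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {rows.shape[-1]}")
        return self.mlp(rows)
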