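"""Coarse-granularity module: hypergraph convolution over triples.

Nodes are drugs followed by cell lines; each hyperedge connects the two
drugs and the cell line of one training triple (its column of the incidence
matrix H sums to exactly 3). Propagation uses the standard spectral
hypergraph rule

    X' = σ( D_v^{-1/2} H W D_e^{-1} Hᵀ D_v^{-1/2} X Θ )

with identity hyperedge weights W. Nodes that touch no hyperedge (unseen
entities in leave-out evaluation) self-propagate: their row of the
normalized operator is the identity row, so they pass through each layer as
a plain affine map of their own features. The four-layer stack is
[768, 384, 384, 384] by default, and the final layer convolves the sum of
the projected input features and the third layer's output (a residual
connection placed before the last convolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import Linear, Module, dropout

logger = logging.getLogger(__name__)


@dataclass
class HypergraphIncidence:
    node_index: dict[str, int]  # drugs first, then cell lines
    H: np.ndarray               # [n_nodes, n_hyperedges] binary
    node_degrees: np.ndarray
    edge_degrees: np.ndarray
    hyperedge_keys: list[tuple[str, str, str]]

    @property
    def n_nodes(self) -> int:
        return self.H.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.H.shape[1]

    def export_triplets(self, path: str | Path) -> None:
        rows, cols = np.nonzero(self.H)
        names = list(self.node_index)
        frame = pd.DataFrame({"node_id": [names[r] for r in rows], "hyperedge_id": cols})
        frame.to_csv(path, index=False)


def build_incidence(
    samples: pd.DataFrame,
    drugs: list[str],
    cells: list[str],
    mode: str = "all",
) -> HypergraphIncidence:
    """Incidence matrix from TRAINING samples only.

    ``mode`` selects which triples become hyperedges: ``"all"`` training
    triples (default, maximizes connectivity) or ``"positive_only"`` the
    synergistic ones. Mirrored duplicates collapse onto one hyperedge via
    the unordered key. Isolated nodes are allowed and logged.
    """
    if mode not in ("all", "positive_only"):
        raise ValueError(f"unknown hyperedge mode {mode!r}")
    node_index = {d: i for i, d in enumerate(drugs)}
    node_index.update({c: len(drugs) + i for i, c in enumerate(cells)})

    keys: list[tuple[str, str, str]] = []
    seen = set()
    for row in samples.itertuples():
        if mode == "positive_only" and int(row.label) != 1:
            continue
        a, b = sorted((str(row.drug1), str(row.drug2)))
        key = (a, b, str(row.cell_line))
        if key not in seen:
            seen.add(key)
            keys.append(key)
    if not keys:
        raise ValueError("no hyperedges: no usable training triples")

    H = np.zeros((len(node_index), len(keys)))
    for e, (d1, d2, cell) in enumerate(keys):
        H[node_index[d1], e] = 1.0
        H[node_index[d2], e] = 1.0
        H[node_index[cell], e] = 1.0
    node_deg = H.sum(axis=1)
    n_isolated = int((node_deg == 0).sum())
    if n_isolated:
        logger.info("incidence has %d isolated node(s) (self-propagating)", n_isolated)
    return HypergraphIncidence(
        node_index=node_index,
        H=H,
        node_degrees=node_deg.astype(int),
        edge_degrees=H.sum(axis=0).astype(int),
        hyperedge_keys=keys,
    )


def propagation_operator(H: np.ndarray) -> np.ndarray:
    """Dense D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2}, identity rows for isolated nodes."""
    dv = H.sum(axis=1)
    de = H.sum(axis=0)
    inv_sqrt_dv = np.where(dv > 0, 1.0 / np.sqrt(np.maximum(dv, 1e-12)), 0.0)
    inv_de = np.where(de > 0, 1.0 / np.maximum(de, 1e-12), 0.0)
    op = (inv_sqrt_dv[:, None] * H) @ (inv_de[:, None] * H.T) @ np.diag(inv_sqrt_dv)
    isolated = dv == 0
    op[isolated, isolated] = 1.0  # degree-safe self-propagation
    return op


def hypergraph_conv(X: Tensor, operator: np.ndarray, theta: Linear,
                    activation: bool = True) -> Tensor:
    """One propagation step; ``operator`` is precomputed from H."""
    if X.shape[0] != operator.shape[0]:
        raise ValueError("node feature rows do not align with the incidence matrix")
    out = theta(Tensor(operator) @ X)
    out = out.relu() if activation else out
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite output of hypergraph convolution")
    return out


class CoarseHypergraph(Module):
    """Four-layer hypergraph stack with a residual into the final convolution."""

    def __init__(self, dims: tuple[int, int, int, int], rng, dropout_rate: float = 0.0,
                 use_residual: bool = True):
        super().__init__()
        if len(dims) != 4:
            raise ValueError("coarse module expects 4 dims: [input, h1, h2, out]")
        self.dims = tuple(dims)
        self.use_residual = use_residual
        d_in, d1, d2, d_out = dims
        self.theta1 = Linear(d_in, d1, rng)
        self.theta2 = Linear(d1, d2, rng)
        self.theta3 = Linear(d2, d_out, rng)
        self.theta4 = Linear(d_out, d_out, rng)
        self.residual_proj = Linear(d_in, d_out, rng, bias=False)
        self.dropout_rate = dropout_rate
        self._rng = rng

    def __call__(self, X: Tensor, operator: np.ndarray) -> Tensor:
        if X.shape[1] != self.dims[0]:
            raise ValueError(f"expected input width {self.dims[0]}, got {X.shape[1]}")
        h = X
        for theta in (self.theta1, self.theta2, self.theta3):
            h = hypergraph_conv(h, operator, theta)
            h = dropout(h, self.dropout_rate, self._rng, self.training)
        # residual: projected input joins layer-3 output before the last convolution
        if self.use_residual:
            h = self.residual_proj(X) + h
        return hypergraph_conv(h, operator, self.theta4)
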