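"""Prediction head and training objectives.

Coarse and fine representations are concatenated and adaptively fused by a
highway layer, y = T(x)⊙G(x) + (1−T(x))⊙x, where the transformation gate
T = sigmoid(W_T x + b_T) decides how much of the nonlinear transform
G = ReLU(W_G x + b_G) replaces the carried input. A two-layer MLP with a
2-way softmax produces the synergy probability.

The training loss is the weighted sum of three terms:

* classification — cross-entropy of the softmax against the binary label;
* reconstruction — mean squared difference between pairwise cosine
  similarities of the hypergraph node embeddings and of the original
  descriptors (ECFP6 bits for drugs, expression rows for cell lines),
  computed separately on the drug block and the cell block;
* contrastive — a margin hinge in the hypergraph embedding space: positive
  samples are pulled to their centroid while an equal number of randomly
  sampled negatives is pushed beyond the margin, with distance 1 − cosine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import MLP, Linear, Module, cosine_similarity_matrix, cross_entropy, softmax

logger = logging.getLogger(__name__)


@dataclass
class LossBreakdown:
    total: float
    classification: float
    reconstruction: float
    contrastive: float
    weights: tuple[float, float, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "classification": self.classification,
            "reconstruction": self.reconstruction,
            "contrastive": self.contrastive,
            "w_cls": self.weights[0],
            "w_rec": self.weights[1],
            "w_con": self.weights[2],
        }


class Highway(Module):
    def __init__(self, dim: int, rng):
        super().__init__()
        self.transform_gate = Linear(dim, dim, rng)
        self.transform = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        t = self.transform_gate(x).sigmoid()
        g = self.transform(x).relu()
        return t * g + (1.0 - t) * x

    def gates(self, x: Tensor) -> np.ndarray:
        return self.transform_gate(x).sigmoid().data


class PredictionHead(Module):
    """Optional highway fusion followed by a two-layer MLP → 2 logits."""

    def __init__(self, in_dim: int, hidden: int, rng, use_highway: bool = True,
                 dropout_rate: float = 0.0):
        super().__init__()
        self.use_highway = use_highway
        if use_highway:
            self.highway = Highway(in_dim, rng)
        self.mlp = MLP([in_dim, hidden, 2], rng, dropout_rate=dropout_rate)

    def fused(self, x: Tensor) -> Tensor:
        return self.highway(x) if self.use_highway else x

    def logits(self, x: Tensor) -> Tensor:
        return self.mlp(self.fused(x))

    def __call__(self, x: Tensor) -> Tensor:
        """Positive-class probability per sample."""
        return softmax(self.logits(x), axis=-1)


def classification_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    return cross_entropy(logits, labels)


def reconstruction_loss(
    node_embeddings: Tensor,
    fingerprints: np.ndarray,
    expression: np.ndarray,
    n_drugs: int,
) -> Tensor:
    """Drug-block + cell-block cosine-similarity reconstruction error.

    ``node_embeddings`` rows follow the incidence ordering (drugs first).
    Rows with zero norm get a zero cosine row on the target side (logged).
    """
    def target_cosine(x: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(x, axis=1)
        zero = norms == 0
        if zero.any():
            logger.warning("%d zero-norm descriptor row(s); cosine set to 0", int(zero.sum()))
        safe = np.where(zero, 1.0, norms)
        unit = x / safe[:, None]
        sims = unit @ unit.T
        sims[zero, :] = 0.0
        sims[:, zero] = 0.0
        return sims

    drug_emb = node_embeddings.gather(np.arange(n_drugs))
    cell_emb = node_embeddings.gather(np.arange(n_drugs, node_embeddings.shape[0]))
    drug_term = ((cosine_similarity_matrix(drug_emb) - Tensor(target_cosine(fingerprints)))
                 .pow(2.0).mean())
    cell_term = ((cosine_similarity_matrix(cell_emb) - Tensor(target_cosine(expression)))
                 .pow(2.0).mean())
    return (drug_term + cell_term) * 0.5


def contrastive_loss(
    sample_embeddings: Tensor,
    labels: np.ndarray,
    rng: np.random.Generator,
    margin: float = 0.5,
) -> Tensor | None:
    """Margin contrastive term over hypergraph-space sample embeddings.

    Positives are pulled toward the positive centroid; for each positive
    anchor one negative is sampled (equal count, with replacement if there
    are fewer negatives) and pushed beyond the margin in 1 − cosine
    distance. Returns ``None`` for single-class batches (skipped, logged).
    """
    labels = np.asarray(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        logger.warning("single-class batch: contrastive term skipped")
        return None
    sampled_neg = rng.choice(neg_idx, size=len(pos_idx), replace=len(neg_idx) < len(pos_idx))

    norms = (sample_embeddings * sample_embeddings).sum(axis=1, keepdims=True).pow(0.5) + 1e-8
    unit = sample_embeddings / norms
    pos = unit.gather(pos_idx)
    centroid = pos.mean(axis=0, keepdims=True)
    c_norm = (centroid * centroid).sum(axis=1, keepdims=True).pow(0.5) + 1e-8
    centroid = centroid / c_norm
    pull = (1.0 - (pos * centroid).sum(axis=1)).mean()
    neg = unit.gather(sampled_neg)
    push = (Tensor(np.full(len(pos_idx), margin)) - (1.0 - (pos * neg).sum(axis=1))).relu().mean()
    return pull + push


def total_loss(
    cls_term: Tensor,
    rec_term: Tensor | None,
    con_term: Tensor | None,
    weights: tuple[float, float, float],
) -> tuple[Tensor, LossBreakdown]:
    w_cls, w_rec, w_con = weights
    total = cls_term * w_cls
    rec_val = con_val = 0.0
    if rec_term is not None and w_rec != 0.0:
        total = total + rec_term * w_rec
        rec_val = float(rec_term.data)
    if con_term is not None and w_con != 0.0:
        total = total + con_term * w_con
        con_val = float(con_term.data)
    breakdown = LossBreakdown(
        total=float(total.data),
        classification=float(cls_term.data),
        reconstruction=rec_val,
        contrastive=con_val,
        weights=weights,
    )
    return total, breakdown
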