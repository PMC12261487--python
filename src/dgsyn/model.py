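"""The dual-granularity synergy classifier as a scikit-learn estimator.

``DualGranularitySynergyClassifier`` predicts whether a (drug 1, drug 2,
cell line) triple is synergistic. It couples

* a coarse view — molecular- and cell-level embeddings propagated through a
  four-layer hypergraph whose hyperedges are the training triples — with
* a fine view — cross/self-attention over per-layer drug substructure
  tokens and the cell-line token,

fuses the two through a highway layer and classifies with a two-layer MLP.
Training minimizes a weighted sum of cross-entropy, a cosine-similarity
reconstruction term, and a margin contrastive term, with Adam and early
stopping on validation loss. Hyperedges come from the fit data only, so
evaluation never alters the hypergraph (transductive-leakage guard);
entities unseen at fit time are isolated, self-propagating nodes.

X is a DataFrame with columns ``drug1, drug2, cell_line``; y is the 0/1
label vector. Drug structures and cell-line expression are estimator
parameters (``drug_smiles``, ``expression``), as they are fixed side
information rather than per-sample features.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import chem
from .attention import FineInteraction
from .autodiff import Tensor, concat, no_grad, stack
from .encoders import CellEncoder, DrugEncoder
from .head import (PredictionHead, classification_loss, contrastive_loss,
                   reconstruction_loss, total_loss)
from .hypergraph import CoarseHypergraph, build_incidence, propagation_operator
from .nn import Adam, Linear, Module

logger = logging.getLogger(__name__)

TRIPLE_COLUMNS = ("drug1", "drug2", "cell_line")


class _Network(Module):
    """The assembled model graph (everything trainable lives here)."""

    def __init__(self, n_genes: int, cfg: dict, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        gin_hidden = tuple(cfg["gin_hidden"])
        if cfg["use_fine"] and len(set(gin_hidden)) != 1:
            raise ValueError("fine module needs equal per-layer widths to stack tokens")
        self.drug_encoder = DrugEncoder(
            chem.N_ATOM_FEATURES, gin_hidden, rng,
            encoder=cfg["encoder"], readout=cfg["readout"],
            pool_ratio=cfg["pool_ratio"], heads=cfg["heads"],
            gin_eps=cfg["gin_eps"], d_mol=cfg["d_mol"],
            dropout_rate=cfg["dropout"],
        )
        self.cell_encoder = CellEncoder(n_genes, tuple(cfg["cell_hidden"]), rng,
                                        dropout_rate=cfg["dropout"])
        d_cell = cfg["cell_hidden"][-1]
        coarse_dims = tuple(cfg["coarse_dims"])
        if cfg["use_coarse"]:
            self.drug_to_node = Linear(cfg["d_mol"], coarse_dims[0], rng)
            self.cell_to_node = Linear(d_cell, coarse_dims[0], rng)
            self.coarse = CoarseHypergraph(coarse_dims, rng, dropout_rate=cfg["dropout"],
                                           use_residual=cfg["use_residual"])
        if cfg["use_fine"]:
            self.fine = FineInteraction(gin_hidden[0], d_cell, cfg["heads"], rng)
        fused = 0
        if cfg["use_coarse"]:
            fused += 3 * coarse_dims[-1]
        if cfg["use_fine"]:
            fused += 6 * gin_hidden[0]
        self.fused_dim = fused
        self.head = PredictionHead(fused, cfg["mlp_hidden"], rng,
                                   use_highway=cfg["use_highway"],
                                   dropout_rate=cfg["dropout"])

    # -- shared entity encodings ------------------------------------------------
    def encode_entities(self, graphs: list, expr: np.ndarray, operator: np.ndarray):
        encodings = [self.drug_encoder(g) for g in graphs]
        mol = stack([e.molecular_embedding for e in encodings], axis=0)
        tokens = stack([e.substructure_tokens for e in encodings], axis=0)
        cell = self.cell_encoder(Tensor(expr))
        coarse_nodes = None
        if self.cfg["use_coarse"]:
            node_feats = concat([self.drug_to_node(mol), self.cell_to_node(cell)], axis=0)
            coarse_nodes = self.coarse(node_feats, operator)
        return {"encodings": encodings, "mol": mol, "tokens": tokens,
                "cell": cell, "coarse_nodes": coarse_nodes}

    def sample_forward(self, ent: dict, d1: np.ndarray, d2: np.ndarray,
                       cell_rows: np.ndarray, n_drugs: int):
        parts = []
        coarse_rep = None
        if self.cfg["use_coarse"]:
            nodes = ent["coarse_nodes"]
            coarse_rep = concat(
                [nodes.gather(d1), nodes.gather(d2), nodes.gather(n_drugs + cell_rows)],
                axis=1,
            )
            parts.append(coarse_rep)
        bundle = None
        if self.cfg["use_fine"]:
            bundle = self.fine(ent["tokens"].gather(d1), ent["tokens"].gather(d2),
                               ent["cell"].gather(cell_rows))
            parts.append(bundle.fine_embedding)
        fused_in = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        fused = self.head.fused(fused_in)
        logits = self.head.mlp(fused)
        return {"fused_in": fused_in, "fused": fused, "logits": logits,
                "coarse_rep": coarse_rep, "bundle": bundle}


class DualGranularitySynergyClassifier(BaseEstimator, ClassifierMixin):
    """Dual-granularity (hypergraph + substructure attention) synergy classifier.

    Parameters follow the published configuration by default: three GIN
    layers [128, 128, 128] with self-attention pooling, cell MLP [512, 384],
    coarse hypergraph [768, 384, 384, 384], 4 attention heads, dropout 0.3,
    Adam at 4e-4 for up to 2000 epochs with early stopping.
    """

    def __init__(
        self,
        drug_smiles: Mapping[str, str] | None = None,
        expression: pd.DataFrame | None = None,
        gin_hidden: tuple[int, ...] = (128, 128, 128),
        cell_hidden: tuple[int, int] = (512, 384),
        coarse_dims: tuple[int, int, int, int] = (768, 384, 384, 384),
        d_mol: int | None = None,
        mlp_hidden: int = 256,
        heads: int = 4,
        pool_ratio: float = 0.5,
        encoder: str = "gin",
        readout: str = "sagpool",
        gin_eps: float = 0.0,
        dropout: float = 0.3,
        learning_rate: float = 4e-4,
        max_epochs: int = 2000,
        patience: int = 50,
        min_delta: float = 1e-4,
        w_cls: float = 1.0,
        w_rec: float = 0.1,
        w_con: float = 0.1,
        margin: float = 0.5,
        hyperedges: str = "all",
        use_coarse: bool = True,
        use_fine: bool = True,
        use_highway: bool = True,
        use_residual: bool = True,
        fp_radius: int = 3,
        threshold: float = 0.5,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.drug_smiles = drug_smiles
        self.expression = expression
        self.gin_hidden = gin_hidden
        self.cell_hidden = cell_hidden
        self.coarse_dims = coarse_dims
        self.d_mol = d_mol
        self.mlp_hidden = mlp_hidden
        self.heads = heads
        self.pool_ratio = pool_ratio
        self.encoder = encoder
        self.readout = readout
        self.gin_eps = gin_eps
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.w_cls = w_cls
        self.w_rec = w_rec
        self.w_con = w_con
        self.margin = margin
        self.hyperedges = hyperedges
        self.use_coarse = use_coarse
        self.use_fine = use_fine
        self.use_highway = use_highway
        self.use_residual = use_residual
        self.fp_radius = fp_radius
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ------------------------------------------------------------------
    def _resolve_triples(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        missing_cols = set(TRIPLE_COLUMNS) - set(X.columns)
        if missing_cols:
            raise ValueError(f"X lacks columns {sorted(missing_cols)}")
        for col, index, what in (
            ("drug1", self.drug_index_, "drug"),
            ("drug2", self.drug_index_, "drug"),
            ("cell_line", self.cell_index_, "cell line"),
        ):
            unknown = sorted(set(X[col].astype(str)) - set(index))
            if unknown:
                raise ValueError(f"unknown {what} id(s) in column {col}: {unknown[:5]}")
        d1 = np.array([self.drug_index_[d] for d in X["drug1"].astype(str)], dtype=np.intp)
        d2 = np.array([self.drug_index_[d] for d in X["drug2"].astype(str)], dtype=np.intp)
        c = np.array([self.cell_index_[c] for c in X["cell_line"].astype(str)], dtype=np.intp)
        return d1, d2, c

    def _config(self) -> dict:
        d_mol = self.d_mol or sum(self.gin_hidden)
        return {
            "gin_hidden": tuple(self.gin_hidden),
            "cell_hidden": tuple(self.cell_hidden),
            "coarse_dims": tuple(self.coarse_dims),
            "d_mol": d_mol,
            "mlp_hidden": self.mlp_hidden,
            "heads": self.heads,
            "pool_ratio": self.pool_ratio,
            "encoder": self.encoder,
            "readout": self.readout,
            "gin_eps": self.gin_eps,
            "dropout": self.dropout,
            "use_coarse": self.use_coarse,
            "use_fine": self.use_fine,
            "use_highway": self.use_highway,
            "use_residual": self.use_residual,
        }

    # -- fitting ---------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, eval_set: tuple[pd.DataFrame, np.ndarray] | None = None):
        if self.drug_smiles is None or self.expression is None:
            raise ValueError("drug_smiles and expression must be provided")
        if not (self.use_coarse or self.use_fine):
            raise ValueError("at least one of use_coarse/use_fine must be on")
        y = np.asarray(y, dtype=np.intp)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        expr_frame = (self.expression.to_frame()
                      if hasattr(self.expression, "to_frame") and not isinstance(
                          self.expression, pd.DataFrame)
                      else pd.DataFrame(self.expression))
        if isinstance(self.drug_smiles, pd.DataFrame):
            smiles = dict(zip(self.drug_smiles["drug_id"].astype(str),
                              self.drug_smiles["smiles"]))
        else:
            smiles = {str(k): v for k, v in dict(self.drug_smiles).items()}
        self.drug_ids_ = sorted(smiles)
        self.cell_ids_ = [str(c) for c in expr_frame.index]
        self.drug_index_ = {d: i for i, d in enumerate(self.drug_ids_)}
        self.cell_index_ = {c: i for i, c in enumerate(self.cell_ids_)}
        self.expr_values_ = expr_frame.to_numpy(dtype=np.float64)
        self.graphs_ = [chem.parse_smiles(str(smiles[d]), drug_id=d) for d in self.drug_ids_]
        self.fingerprints_ = np.stack([
            chem.compute_ecfp6(str(smiles[d]), drug_id=d, fp_radius=self.fp_radius).bits
            for d in self.drug_ids_
        ])

        d1, d2, cell_rows = self._resolve_triples(X)
        train_frame = X.reset_index(drop=True).copy()
        train_frame["label"] = y
        self.train_triples_ = {
            (*sorted((a, b)), c) for a, b, c in zip(
                X["drug1"].astype(str), X["drug2"].astype(str), X["cell_line"].astype(str))
        }
        self.incidence_ = build_incidence(train_frame, self.drug_ids_, self.cell_ids_,
                                          mode=self.hyperedges)
        self.operator_ = propagation_operator(self.incidence_.H)
        self._h_checksum = float(self.incidence_.H.sum())

        rng = np.random.default_rng(self.random_state)
        self.network_ = _Network(self.expr_values_.shape[1], self._config(), rng)
        optimizer = Adam(self.network_.parameters(), lr=self.learning_rate)

        has_val = eval_set is not None
        if has_val:
            Xv, yv = eval_set
            yv = np.asarray(yv, dtype=np.intp)
            v1, v2, vcell = self._resolve_triples(Xv)

        n_drugs = len(self.drug_ids_)
        best = np.inf
        best_state = self.network_.state_dict()
        best_epoch = 0
        log_rows = []
        for epoch in range(self.max_epochs):
            self.network_.train()
            ent = self.network_.encode_entities(self.graphs_, self.expr_values_,
                                                self.operator_)
            out = self.network_.sample_forward(ent, d1, d2, cell_rows, n_drugs)
            cls_term = classification_loss(out["logits"], y)
            rec_term = con_term = None
            if self.use_coarse and self.w_rec != 0.0:
                rec_term = reconstruction_loss(ent["coarse_nodes"], self.fingerprints_,
                                               self.expr_values_, n_drugs)
            if self.use_coarse and self.w_con != 0.0:
                con_term = contrastive_loss(out["coarse_rep"], y, rng, margin=self.margin)
            loss, breakdown = total_loss(cls_term, rec_term, con_term,
                                         (self.w_cls, self.w_rec, self.w_con))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {breakdown.as_dict()}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

            row = breakdown.as_dict()
            row["epoch"] = epoch
            monitor = row["classification"]
            if has_val:
                with no_grad():
                    self.network_.eval()
                    vent = self.network_.encode_entities(self.graphs_, self.expr_values_,
                                                         self.operator_)
                    vout = self.network_.sample_forward(vent, v1, v2, vcell, n_drugs)
                    vloss = classification_loss(vout["logits"], yv)
                row["val_loss"] = monitor = float(vloss.data)
            log_rows.append(row)
            if self.verbose and epoch % 20 == 0:
                logger.info("epoch %d: %s", epoch, row)
            if monitor < best - self.min_delta:
                best = monitor
                best_state = self.network_.state_dict()
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break

        self.network_.load_state_dict(best_state)
        self.network_.eval()
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(log_rows)
        self.history_ = pd.DataFrame(log_rows)
        assert float(self.incidence_.H.sum()) == self._h_checksum
        return self

    # -- inference ---------------------------------------------------------------------
    def _forward_eval(self, X: pd.DataFrame) -> dict:
        check_is_fitted(self, "network_")
        d1, d2, cell_rows = self._resolve_triples(X)
        h_before = float(self.incidence_.H.sum())
        with no_grad():
            self.network_.eval()
            ent = self.network_.encode_entities(self.graphs_, self.expr_values_,
                                                self.operator_)
            out = self.network_.sample_forward(ent, d1, d2, cell_rows,
                                               len(self.drug_ids_))
        # evaluation must never add hyperedges
        assert float(self.incidence_.H.sum()) == h_before == self._h_checksum
        out["ent"] = ent
        out["indices"] = (d1, d2, cell_rows)
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        logits = self._forward_eval(X)["logits"].data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    # -- interpretability / export -------------------------------------------------------
    def embeddings(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Per-sample representations from each stage: init, coarse, fine, final."""
        out = self._forward_eval(X)
        ent = out["ent"]
        d1, d2, cell_rows = out["indices"]
        init = np.concatenate([
            ent["mol"].data[d1], ent["mol"].data[d2], ent["cell"].data[cell_rows]
        ], axis=1)
        result = {"init": init, "final": out["fused"].data}
        if self.use_coarse:
            result["coarse"] = out["coarse_rep"].data
        if self.use_fine:
            result["fine"] = out["bundle"].fine_embedding.data
        return result

    def export_embeddings(self, X: pd.DataFrame) -> pd.DataFrame:
        """Long-form frame (one row per sample × module) for t-SNE and the like."""
        frames = []
        for tag, arr in self.embeddings(X).items():
            base = X[list(TRIPLE_COLUMNS)].reset_index(drop=True).copy()
            base["module"] = tag
            values = pd.DataFrame(arr, columns=[f"e{j}" for j in range(arr.shape[1])])
            frames.append(pd.concat([base, values], axis=1))
        return pd.concat(frames, ignore_index=True)

    def explain(self, drug_id: str) -> list[dict[int, float]]:
        """Per-layer atom importance, min-max normalized to [0, 1]."""
        check_is_fitted(self, "network_")
        if str(drug_id) not in self.drug_index_:
            raise ValueError(f"unknown drug id {drug_id!r}")
        graph = self.graphs_[self.drug_index_[str(drug_id)]]
        with no_grad():
            self.network_.eval()
            encoding = self.network_.drug_encoder(graph)
        maps = []
        for scores in encoding.atom_importance:
            lo, hi = scores.min(), scores.max()
            norm = np.ones_like(scores) if hi - lo < 1e-12 else (scores - lo) / (hi - lo)
            maps.append({int(i): float(v) for i, v in enumerate(norm)})
        return maps

    def attention_maps(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        out = self._forward_eval(X)
        if out["bundle"] is None:
            raise ValueError("fine module disabled; no attention maps")
        return out["bundle"].attention_maps

    def screen(self, drugs: list[str] | None = None, cell_lines: list[str] | None = None
               ) -> pd.DataFrame:
        """Rank candidate triples absent from training by predicted probability
        (averaged over both drug input orders), descending."""
        check_is_fitted(self, "network_")
        drugs = [str(d) for d in (drugs if drugs is not None else self.drug_ids_)]
        cell_lines = [str(c) for c in
                      (cell_lines if cell_lines is not None else self.cell_ids_)]
        rows = []
        for i, a in enumerate(drugs):
            for b in drugs[i + 1:]:
                lo, hi = sorted((a, b))
                for c in cell_lines:
                    if (lo, hi, c) not in self.train_triples_:
                        rows.append((lo, hi, c))
        if not rows:
            raise ValueError("no novel candidate triples to screen")
        cand = pd.DataFrame(rows, columns=list(TRIPLE_COLUMNS))
        fwd = self.predict_proba(cand)[:, 1]
        rev = self.predict_proba(
            cand.rename(columns={"drug1": "drug2", "drug2": "drug1"}))[:, 1]
        cand["prob"] = (fwd + rev) / 2
        return cand.sort_values("prob", ascending=False, ignore_index=True)
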