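"""Cell-line expression profiles: landmark-gene selection and z-scoring.

Expression is a cell-line × gene matrix of log-scale values. Preprocessing
restricts columns to a landmark gene list (the LINCS L1000 convention of a
small representative gene panel) and standardizes each gene column to zero
mean / unit population standard deviation. When a training-row subset is
supplied the statistics come from those rows only, so held-out cell lines
never leak into normalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    cell_lines: list[str]
    genes: list[str]
    values: np.ndarray  # [n_cell_lines, n_genes]
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_lines), len(self.genes)):
            raise ValueError("values shape does not match cell_lines × genes")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = False) -> "ExpressionMatrix":
        return cls(
            cell_lines=[str(c) for c in frame.index],
            genes=[str(g) for g in frame.columns],
            values=frame.to_numpy(dtype=np.float64),
            normalized=normalized,
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ExpressionMatrix":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_lines, columns=self.genes)

    def row(self, cell_line: str) -> np.ndarray:
        return self.values[self.cell_lines.index(cell_line)]


def read_landmark_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def select_landmark_genes(matrix: ExpressionMatrix, landmark: Sequence[str]) -> ExpressionMatrix:
    """Restrict columns to the landmark list (kept in the list's order)."""
    present = set(matrix.genes)
    kept = [g for g in landmark if g in present]
    missing = len(landmark) - len(kept)
    if not kept:
        raise ValueError("no landmark genes found in the expression matrix")
    if missing:
        logger.warning("%d landmark gene(s) missing from the expression matrix", missing)
    col_idx = [matrix.genes.index(g) for g in kept]
    return replace(matrix, genes=kept, values=matrix.values[:, col_idx])


def zscore_normalize(
    matrix: ExpressionMatrix,
    train_rows: Sequence[int] | None = None,
    tol: float = 1e-6,
) -> tuple[ExpressionMatrix, dict]:
    """Per-gene standardization, (x − μ)/σ with population σ (ddof=0).

    Zero-variance columns are dropped and logged; missing values are imputed
    with the (training) column mean first. Returns the matrix plus a stats
    sidecar recording μ, σ, dropped columns and which rows defined the
    statistics.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    values = matrix.values.copy()
    rows = np.arange(values.shape[0]) if train_rows is None else np.asarray(train_rows)
    ref = values[rows]
    col_mean = np.nanmean(ref, axis=0)
    n_imputed = int(np.isnan(values).sum())
    if n_imputed:
        logger.warning("imputed %d missing value(s) with training column means", n_imputed)
        values = np.where(np.isnan(values), col_mean[None, :], values)
        ref = values[rows]
    mu = ref.mean(axis=0)
    sigma = ref.std(axis=0, ddof=0)
    keep = sigma > tol
    dropped = [g for g, k in zip(matrix.genes, keep) if not k]
    if dropped:
        logger.warning("dropped %d zero-variance gene column(s): %s", len(dropped), dropped[:10])
    if not keep.any():
        raise ValueError("all gene columns have zero variance")
    normalized = (values[:, keep] - mu[keep]) / sigma[keep]
    stats = {
        "mean": dict(zip(np.array(matrix.genes)[keep].tolist(), mu[keep].tolist())),
        "std": dict(zip(np.array(matrix.genes)[keep].tolist(), sigma[keep].tolist())),
        "dropped": dropped,
        "n_imputed": n_imputed,
        "train_rows": None if train_rows is None else [int(r) for r in rows],
    }
    out = ExpressionMatrix(
        cell_lines=list(matrix.cell_lines),
        genes=[g for g, k in zip(matrix.genes, keep) if k],
        values=normalized,
        normalized=True,
    )
    return out, stats


def write_normalized(matrix: ExpressionMatrix, stats: dict,
                     out_csv: str | Path, out_json: str | Path) -> None:
    matrix.to_frame().to_csv(out_csv)
    Path(out_json).write_text(json.dumps(stats, indent=1))
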