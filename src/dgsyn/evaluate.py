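"""Evaluation utilities: fold training, order independence, ablation harness.

These are thin orchestration helpers over the estimator — they train on a
split manifest's train partition with early stopping on the validation
partition, score the test partition with the eight metrics, quantify
insensitivity to drug input order, and sweep component toggles for the
ablation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .metrics import MetricReport, compute_metrics
from .model import DualGranularitySynergyClassifier
from .splits import SplitManifest

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Run-level knobs, mapped onto estimator parameters."""

    learning_rate: float = 4e-4
    max_epochs: int = 2000
    patience: int = 50
    min_delta: float = 1e-4
    dropout: float = 0.3
    seed: int = 0
    ablation_flags: dict = field(default_factory=dict)  # estimator kwargs overrides

    def estimator_kwargs(self) -> dict:
        kwargs = {
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "min_delta": self.min_delta,
            "dropout": self.dropout,
            "random_state": self.seed,
        }
        kwargs.update(self.ablation_flags)
        return kwargs


def train_fold(
    estimator: DualGranularitySynergyClassifier,
    samples: pd.DataFrame,
    manifest: SplitManifest,
) -> tuple[DualGranularitySynergyClassifier, MetricReport, pd.DataFrame]:
    """Fit on the manifest's train partition, early-stop on val, score test.

    Returns the fitted estimator, the test MetricReport, and a per-sample
    prediction frame (drug1, drug2, cell_line, label, prob).
    """
    cols = ["drug1", "drug2", "cell_line"]
    train = samples.iloc[manifest.train]
    val = samples.iloc[manifest.val]
    test = samples.iloc[manifest.test]
    estimator.fit(train[cols], train["label"].to_numpy(),
                  eval_set=(val[cols], val["label"].to_numpy()))
    probs = estimator.predict_proba(test[cols])[:, 1]
    report = compute_metrics(probs, test["label"].to_numpy(), threshold=estimator.threshold)
    predictions = test[cols].reset_index(drop=True).copy()
    predictions["label"] = test["label"].to_numpy()
    predictions["prob"] = probs
    return estimator, report, predictions


def order_independence(model: DualGranularitySynergyClassifier, X: pd.DataFrame
                       ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between predictions under the two drug orders."""
    if len(X) < 2:
        raise ValueError("order independence needs at least 2 samples")
    forward = model.predict_proba(X[["drug1", "drug2", "cell_line"]])[:, 1]
    swapped = X.rename(columns={"drug1": "drug2", "drug2": "drug1"})
    backward = model.predict_proba(swapped[["drug1", "drug2", "cell_line"]])[:, 1]
    pcc = float(pearsonr(forward, backward)[0])
    scatter = pd.DataFrame({"prob_d1_d2": forward, "prob_d2_d1": backward})
    return pcc, scatter


ABLATION_TOGGLES = {
    "no_coarse": {"use_coarse": False},
    "no_residual": {"use_residual": False},
    "no_fine": {"use_fine": False},
    "no_highway": {"use_highway": False},
    "no_reconstruction": {"w_rec": 0.0},
    "no_contrastive": {"w_con": 0.0},
    "classification_only": {"w_rec": 0.0, "w_con": 0.0},
}


def run_ablations(
    base_params: dict,
    samples: pd.DataFrame,
    manifest: SplitManifest,
    toggles: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Metric table for the full model and each single-component removal.

    Rows: full model first, then one row per toggle; columns: the eight
    metrics plus their deltas against the full model.
    """
    toggles = ABLATION_TOGGLES if toggles is None else toggles
    rows = []
    _, full_report, _ = train_fold(
        DualGranularitySynergyClassifier(**base_params), samples, manifest)
    full = full_report.as_dict()
    rows.append({"variant": "full", **full})
    for name, overrides in toggles.items():
        params = dict(base_params)
        params.update(overrides)
        _, report, _ = train_fold(
            DualGranularitySynergyClassifier(**params), samples, manifest)
        row = {"variant": name, **report.as_dict()}
        for metric, value in report.as_dict().items():
            if value is not None and full[metric] is not None:
                row[f"delta_{metric}"] = value - full[metric]
        rows.append(row)
    return pd.DataFrame(rows)
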