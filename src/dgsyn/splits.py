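"""Leakage-aware cross-validation splits for synergy triples.

Three scenarios, all five-fold with a 3:1:1 train/validation/test layout:

* ``random`` — folds over unordered (drug1, drug2, cell line) triples, so a
  sample and its mirrored twin always land in the same partition;
* ``leave_drug_pair_out`` — folds over unordered drug pairs: every sample of
  a pair lives in exactly one fold, so no pair in validation/test is ever
  seen in training;
* ``leave_cell_line_out`` — folds over cell lines, testing on entirely
  unseen cell lines.

For fold k, test = fold k, validation = fold (k+1) mod n_folds, and the
remaining folds train. Validation groups are held out at the group level
too, so early stopping cannot leak.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCENARIOS = ("random", "leave_drug_pair_out", "leave_cell_line_out")


@dataclass
class SplitManifest:
    scenario: str
    fold_index: int
    seed: int
    assignment: dict[int, str] = field(default_factory=dict)  # sample index -> partition

    def indices(self, partition: str) -> np.ndarray:
        return np.array(sorted(i for i, p in self.assignment.items() if p == partition),
                        dtype=np.intp)

    @property
    def train(self) -> np.ndarray:
        return self.indices("train")

    @property
    def val(self) -> np.ndarray:
        return self.indices("val")

    @property
    def test(self) -> np.ndarray:
        return self.indices("test")

    def to_json(self, path: str | Path) -> None:
        record = asdict(self)
        record["assignment"] = {str(k): v for k, v in self.assignment.items()}
        Path(path).write_text(json.dumps(record))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        record = json.loads(Path(path).read_text())
        record["assignment"] = {int(k): v for k, v in record["assignment"].items()}
        return cls(**record)


def _group_keys(samples: pd.DataFrame, scenario: str) -> list:
    d1, d2 = samples["drug1"].astype(str), samples["drug2"].astype(str)
    lo = np.minimum(d1, d2)
    hi = np.maximum(d1, d2)
    if scenario == "random":
        return list(zip(lo, hi, samples["cell_line"].astype(str)))
    if scenario == "leave_drug_pair_out":
        return list(zip(lo, hi))
    if scenario == "leave_cell_line_out":
        return list(samples["cell_line"].astype(str))
    raise ValueError(f"unknown scenario {scenario!r}; choose one of {SCENARIOS}")


def make_splits(
    samples: pd.DataFrame,
    scenario: str,
    n_folds: int = 5,
    seed: int = 0,
) -> list[SplitManifest]:
    """Grouped n-fold 3:1:1 manifests for one scenario.

    ``samples`` is the symmetrized frame with columns drug1, drug2,
    cell_line (row position is the sample index the manifests refer to).
    """
    keys = _group_keys(samples, scenario)
    unique = sorted(set(keys))
    if len(unique) < n_folds:
        raise ValueError(
            f"{scenario}: only {len(unique)} group(s) for {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    folds = np.array_split(np.arange(len(order)), n_folds)
    group_fold = {}
    for f, idx in enumerate(folds):
        for i in idx:
            group_fold[order[i]] = f

    manifests = []
    for k in range(n_folds):
        val_fold = (k + 1) % n_folds
        assignment = {}
        for i, key in enumerate(keys):
            f = group_fold[key]
            assignment[i] = "test" if f == k else ("val" if f == val_fold else "train")
        manifests.append(SplitManifest(scenario=scenario, fold_index=k, seed=seed,
                                       assignment=assignment))
    return manifests


def split_random(samples: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> list[SplitManifest]:
    return make_splits(samples, "random", n_folds, seed)


def split_leave_drug_pair_out(samples: pd.DataFrame, n_folds: int = 5,
                              seed: int = 0) -> list[SplitManifest]:
    return make_splits(samples, "leave_drug_pair_out", n_folds, seed)


def split_leave_cell_line_out(samples: pd.DataFrame, n_folds: int = 5,
                              seed: int = 0) -> list[SplitManifest]:
    return make_splits(samples, "leave_cell_line_out", n_folds, seed)


def check_leakage(samples: pd.DataFrame, manifest: SplitManifest) -> dict[str, int]:
    """Count leaked groups between train and val∪test (should all be zero)."""
    train = set(manifest.train.tolist())
    held = set(manifest.val.tolist()) | set(manifest.test.tolist())

    def groups(rows: set[int], scenario: str) -> set:
        sub = samples.iloc[sorted(rows)]
        return set(_group_keys(sub, scenario))

    report = {}
    if manifest.scenario in ("leave_drug_pair_out", "random"):
        report["shared_pairs"] = len(
            groups(train, "leave_drug_pair_out") & groups(held, "leave_drug_pair_out")
        ) if manifest.scenario == "leave_drug_pair_out" else 0
    if manifest.scenario == "leave_cell_line_out":
        report["shared_cell_lines"] = len(
            groups(train, "leave_cell_line_out") & groups(held, "leave_cell_line_out")
        )
    report["shared_triples"] = len(groups(train, "random") & groups(held, "random"))
    return report
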