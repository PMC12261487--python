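"""Synergy tables → binary-labeled, symmetrized (drug1, drug2, cell line) samples.

Raw screening tables score each combination under several additive reference
models (Bliss, Loewe, HSA, ZIP). A combination counts as synergistic under a
model when its score exceeds zero; the binary label is the majority vote of
the available model votes, with 2–2 ties broken by the sign of the mean score
(an exactly zero mean drops the row). Datasets are then symmetrized — every
unordered combination appears in both drug orders with the same label — and
duplicate measurements of one unordered triple are merged by majority vote
over their labels (ties dropped and logged).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SCORE_COLUMNS = ("bliss", "loewe", "hsa", "zip")


@dataclass
class SynergySample:
    drug1: str
    drug2: str
    cell_line: str
    scores: dict[str, float]
    label: int
    origin: str = "observed"  # "observed" | "mirrored"

    @property
    def unordered_key(self) -> tuple[str, str, str]:
        a, b = sorted((self.drug1, self.drug2))
        return (a, b, self.cell_line)


@dataclass
class DatasetManifest:
    n_raw: int
    n_after_filtering: int
    n_after_symmetrization: int
    n_positive: int
    n_negative: int
    label_rule: str = "majority vote over per-model sign(score > 0); 2-2 ties by sign of mean"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def vote_label(scores: Mapping[str, float]) -> int | None:
    """Majority vote over the available reference-model scores.

    Returns 0/1, or ``None`` when the vote ties and the mean score is
    exactly zero (the row is uninformative). Raises when no score is
    available at all.
    """
    available = {k: float(v) for k, v in scores.items()
                 if v is not None and not (isinstance(v, float) and math.isnan(v))}
    if not available:
        raise ValueError("no reference-model score available for sample")
    votes = [1 if v > 0 else 0 for v in available.values()]
    pos, neg = sum(votes), len(votes) - sum(votes)
    if pos > neg:
        return 1
    if neg > pos:
        return 0
    mean = float(np.mean(list(available.values())))
    if mean > 0:
        return 1
    if mean < 0:
        return 0
    return None


def symmetrize(samples: Sequence[SynergySample]) -> list[SynergySample]:
    """Emit every ordered permutation exactly once, merging duplicates.

    Duplicate observations of one unordered triple are merged by majority
    vote over their labels; exact ties are dropped and logged.
    """
    groups: dict[tuple[str, str, str], list[SynergySample]] = {}
    for s in samples:
        groups.setdefault(s.unordered_key, []).append(s)
    out: list[SynergySample] = []
    n_tied = 0
    for (d1, d2, cell), members in groups.items():
        labels = [m.label for m in members]
        pos, neg = sum(labels), len(labels) - sum(labels)
        if pos == neg:
            n_tied += 1
            continue
        label = 1 if pos > neg else 0
        scores = members[0].scores
        out.append(SynergySample(d1, d2, cell, scores, label, origin="observed"))
        if d1 != d2:
            out.append(SynergySample(d2, d1, cell, scores, label, origin="mirrored"))
    if n_tied:
        logger.warning("dropped %d duplicate triple(s) with tied labels", n_tied)
    return out


def build_dataset(
    synergy: pd.DataFrame,
    drug_ids: Iterable[str],
    cell_lines: Iterable[str],
    score_columns: Sequence[str] = DEFAULT_SCORE_COLUMNS,
    keep_self_pairs: bool = False,
) -> tuple[list[SynergySample], DatasetManifest]:
    """Filter, label, and symmetrize a raw synergy table.

    ``synergy`` needs columns drug1, drug2, cell_line plus at least one of
    ``score_columns``. Rows whose entities do not resolve against the drug
    table / expression matrix are dropped and counted.
    """
    cols = [c for c in score_columns if c in synergy.columns]
    if not cols:
        raise ValueError(f"synergy table has none of the score columns {list(score_columns)}")
    drugs = set(map(str, drug_ids))
    cells = set(map(str, cell_lines))
    n_raw = len(synergy)

    kept: list[SynergySample] = []
    n_unresolvable = n_self = n_dropped_label = 0
    for row in synergy.itertuples():
        d1, d2, cell = str(row.drug1), str(row.drug2), str(row.cell_line)
        if d1 not in drugs or d2 not in drugs or cell not in cells:
            n_unresolvable += 1
            continue
        if d1 == d2 and not keep_self_pairs:
            n_self += 1
            continue
        scores = {c: getattr(row, c) for c in cols}
        try:
            label = vote_label(scores)
        except ValueError:
            n_dropped_label += 1
            continue
        if label is None:
            n_dropped_label += 1
            continue
        kept.append(SynergySample(d1, d2, cell, {k: float(v) for k, v in scores.items()
                                                 if not math.isnan(float(v))}, label))
    if n_unresolvable:
        logger.warning("filtered %d row(s) with unresolvable drug or cell-line ids",
                       n_unresolvable)
    if n_self:
        logger.info("excluded %d self-combination row(s)", n_self)
    if not kept:
        raise ValueError(
            "no usable samples: "
            f"{n_unresolvable} unresolvable, {n_self} self-pairs, "
            f"{n_dropped_label} dropped by the label rule, out of {n_raw} rows"
        )
    n_after_filtering = len(kept)
    symmetric = symmetrize(kept)
    n_pos = sum(s.label for s in symmetric)
    manifest = DatasetManifest(
        n_raw=n_raw,
        n_after_filtering=n_after_filtering,
        n_after_symmetrization=len(symmetric),
        n_positive=n_pos,
        n_negative=len(symmetric) - n_pos,
    )
    return symmetric, manifest


def samples_to_frame(samples: Sequence[SynergySample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug1": [s.drug1 for s in samples],
            "drug2": [s.drug2 for s in samples],
            "cell_line": [s.cell_line for s in samples],
            "label": [s.label for s in samples],
            "origin": [s.origin for s in samples],
        }
    )
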