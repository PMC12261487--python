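"""Self-contained synthetic universe for end-to-end testing without downloads.

The generator emits the three raw inputs the pipeline consumes — a drug
table of valid SMILES, a cell-line × gene expression matrix, and a synergy
table with four reference-model score columns — plus a ground-truth record.

A decision rule is planted so learnability can be verified: a triple is
truly synergistic iff both drugs carry an "active motif" (a pyridine ring)
AND the cell line is intrinsically sensitive. Sensitivity is a latent
per-cell-line attribute drawn independently of the expression clusters, so
a model can memorize it for cell lines seen in training but cannot read it
off the expression profile of an unseen cell line — which makes the
leave-cell-line-out scenario genuinely harder than random cross-validation,
the way real leave-out evaluations are. Expression rows come from a few
latent clusters (cluster mean + unit Gaussian noise) purely as realistic
covariance structure.

Reference-model scores are the latent sign times |N(2, 1)| plus per-model
disagreement noise, so majority voting is exercised (including occasional
2–2 ties).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DEFAULT_SCORE_COLUMNS

# SMILES fragments: chemically valid building blocks.
ACTIVE_MOTIF = "c1ccncc1"  # pyridine
ALKYL = ["C", "CC", "CCC", "CCCC"]
INACTIVE_CORES = ["c1ccccc1", "C1CCCCC1", "CC(=O)N", "CCO", "CC(C)O", "CCS"]
# terminal groups prefixed to the alkyl chain (keeps every assembly valid)
DECORATIONS = ["", "O", "N", "Cl", "F", "NC(=O)"]


@dataclass
class FixtureSpec:
    n_drugs: int = 30
    n_cell_lines: int = 12
    n_genes: int = 64
    n_triples: int = 600
    seed: int = 7
    positive_rate_target: float = 0.3
    motif_fraction: float = 0.95
    sensitive_fraction: float = 1 / 3
    n_clusters: int = 3
    score_scale: float = 2.0
    disagreement_sd: float = 1.5

    def __post_init__(self):
        if self.n_drugs < 6 or self.n_cell_lines < 5:
            raise ValueError("need at least 6 drugs and 5 cell lines for cross-validation")


def generate_drugs(spec: FixtureSpec, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Drug table with a controlled fraction of motif-bearing molecules."""
    rng = rng or np.random.default_rng(spec.seed)
    n_motif = round(spec.motif_fraction * spec.n_drugs)
    rows, motif_flags = [], {}
    for i in range(spec.n_drugs):
        drug_id = f"D{i:03d}"
        has_motif = i < n_motif
        core = ACTIVE_MOTIF if has_motif else str(rng.choice(INACTIVE_CORES))
        chain = str(rng.choice(ALKYL))
        deco = str(rng.choice(DECORATIONS))
        smiles = deco + chain + core
        rows.append({"drug_id": drug_id, "smiles": smiles})
        motif_flags[drug_id] = bool(has_motif)
    return pd.DataFrame(rows), motif_flags


def generate_expression(spec: FixtureSpec, rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cell-line expression from latent clusters: cluster mean + unit noise."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    centers = rng.normal(0.0, 1.0, size=(spec.n_clusters, spec.n_genes))
    cells = [f"CL{i:02d}" for i in range(spec.n_cell_lines)]
    assignment = {c: int(i % spec.n_clusters) for i, c in enumerate(cells)}
    values = np.stack([
        centers[assignment[c]] + rng.normal(0.0, 1.0, spec.n_genes) for c in cells
    ])
    genes = [f"G{j:03d}" for j in range(spec.n_genes)]
    return pd.DataFrame(values, index=cells, columns=genes), assignment


def generate_synergy(
    spec: FixtureSpec,
    motif_flags: dict[str, bool],
    cells: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Synergy table with four score columns realizing the planted rule."""
    rng = rng or np.random.default_rng(spec.seed + 2)
    drugs = sorted(motif_flags)
    n_sensitive = max(1, round(spec.sensitive_fraction * len(cells)))
    sensitive = set(map(str, rng.choice(cells, size=n_sensitive, replace=False)))

    pairs = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]]
    triples = [(a, b, c) for a, b in pairs for c in cells]
    if spec.n_triples > len(triples):
        raise ValueError(f"n_triples={spec.n_triples} exceeds {len(triples)} possible triples")
    chosen = [triples[i] for i in rng.choice(len(triples), size=spec.n_triples, replace=False)]

    rows = []
    latent = {}
    for d1, d2, cell in chosen:
        synergistic = motif_flags[d1] and motif_flags[d2] and cell in sensitive
        sign = 1.0 if synergistic else -1.0
        base = sign * abs(rng.normal(spec.score_scale, 1.0))
        scores = {m: base + rng.normal(0.0, spec.disagreement_sd)
                  for m in DEFAULT_SCORE_COLUMNS}
        rows.append({"drug1": d1, "drug2": d2, "cell_line": cell, **scores})
        latent[f"{d1}|{d2}|{cell}"] = int(synergistic)
    truth = {
        "sensitive_cell_lines": sorted(sensitive),
        "motif_drugs": sorted(d for d, f in motif_flags.items() if f),
        "latent_labels": latent,
        "active_motif_smarts": ACTIVE_MOTIF,
    }
    return pd.DataFrame(rows), truth


def generate_fixture(spec: FixtureSpec | None = None, out_dir: str | Path | None = None
                     ) -> dict:
    """Generate the full toy universe; optionally write it to ``out_dir``.

    Returns a dict with keys drugs, expression, landmark, synergy,
    ground_truth. Deterministic given ``spec.seed``.
    """
    spec = spec or FixtureSpec()
    rng_drugs = np.random.default_rng(spec.seed)
    rng_expr = np.random.default_rng(spec.seed + 1)
    rng_syn = np.random.default_rng(spec.seed + 2)
    drugs, motif_flags = generate_drugs(spec, rng_drugs)
    expression, clusters = generate_expression(spec, rng_expr)
    synergy, truth = generate_synergy(spec, motif_flags, list(expression.index), rng_syn)
    truth["expression_clusters"] = clusters
    truth["spec"] = asdict(spec)
    landmark = list(expression.columns)  # toy landmark list = all generated genes
    bundle = {
        "drugs": drugs,
        "expression": expression,
        "landmark": landmark,
        "synergy": synergy,
        "ground_truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        drugs.to_csv(out / "drugs.csv", index=False)
        expression.to_csv(out / "expression.csv")
        (out / "landmark.txt").write_text("\n".join(landmark) + "\n")
        synergy.to_csv(out / "synergy.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return bundle
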