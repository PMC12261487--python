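"""SMILES parsing, atom featurization and circular fingerprints.

Drugs are represented two ways:

* a molecular graph (heavy atoms as nodes, bonds as undirected edges) whose
  atoms carry a 78-dimensional binary feature vector — one-hot atom type
  (43 named elements + an "other" bucket = 44), one-hot heavy-atom degree
  (0–10), one-hot total hydrogen count (0–10), one-hot implicit valence
  (0–10), and a single aromaticity flag;
* a 1024-bit extended-connectivity fingerprint of diameter 6 (Morgan
  radius 3; ``fp_radius`` overrides for a literal radius-6 reading), used
  by the reconstruction objective.

SMILES are canonicalized first so equivalent writings of one molecule map
to identical features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

# 43 named element symbols (anything else falls into the trailing bucket).
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
N_ATOM_TYPES = len(ATOM_SYMBOLS) + 1  # + "other" bucket = 44
N_ATOM_FEATURES = N_ATOM_TYPES + 11 + 11 + 11 + 1  # = 78
FINGERPRINT_BITS = 1024


@dataclass
class MolecularGraph:
    """One drug as an attributed graph over heavy atoms."""

    drug_id: str
    n_atoms: int
    atom_features: np.ndarray  # [n_atoms, 78], binary
    edges: list[tuple[int, int]] = field(default_factory=list)  # i < j, one per bond
    smiles_canonical: str = ""

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass
class Fingerprint:
    drug_id: str
    bits: np.ndarray  # [1024], binary


def _one_hot(value: int, size: int) -> np.ndarray:
    vec = np.zeros(size)
    vec[min(value, size - 1)] = 1.0  # values past the range clamp to the last bucket
    return vec


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    symbol = atom.GetSymbol()
    type_idx = ATOM_SYMBOLS.index(symbol) if symbol in ATOM_SYMBOLS else N_ATOM_TYPES - 1
    parts = [
        _one_hot(type_idx, N_ATOM_TYPES),
        _one_hot(atom.GetDegree(), 11),
        _one_hot(atom.GetTotalNumHs(), 11),
        _one_hot(atom.GetImplicitValence(), 11),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
    ]
    return np.concatenate(parts)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"empty molecule: {smiles!r}")
    return mol


def parse_smiles(smiles: str, drug_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a featurized molecular graph."""
    mol = _mol_from_smiles(smiles)
    feats = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
    return MolecularGraph(
        drug_id=drug_id,
        n_atoms=mol.GetNumAtoms(),
        atom_features=feats,
        edges=sorted(edges),
        smiles_canonical=Chem.MolToSmiles(mol),
    )


def compute_ecfp6(smiles: str, drug_id: str = "", fp_radius: int = 3,
                  n_bits: int = FINGERPRINT_BITS) -> Fingerprint:
    """Hashed circular fingerprint (default Morgan radius 3 = diameter 6)."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=n_bits)
    bits = np.array(gen.GetFingerprint(mol), dtype=np.float64)
    return Fingerprint(drug_id=drug_id, bits=bits)


def load_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a `drug_id,smiles` CSV, canonicalizing and validating every entry."""
    table = pd.read_csv(path, dtype=str)
    missing = {"drug_id", "smiles"} - set(table.columns)
    if missing:
        raise ValueError(f"drug table lacks columns: {sorted(missing)}")
    table = table[["drug_id", "smiles"]].copy()
    table["smiles"] = [parse_smiles(s).smiles_canonical for s in table["smiles"]]
    if table["drug_id"].duplicated().any():
        dupes = table.loc[table["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"duplicate drug ids: {dupes}")
    return table


def featurize_drugs(table: pd.DataFrame, fp_radius: int = 3) -> tuple[
        dict[str, MolecularGraph], dict[str, np.ndarray]]:
    """Graphs and fingerprint vectors for every drug in the table."""
    graphs = {
        row.drug_id: parse_smiles(row.smiles, drug_id=row.drug_id)
        for row in table.itertuples()
    }
    fps = {
        row.drug_id: compute_ecfp6(row.smiles, drug_id=row.drug_id, fp_radius=fp_radius).bits
        for row in table.itertuples()
    }
    return graphs, fps


def export_graph_store(graphs: dict[str, MolecularGraph], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for drug_id, g in graphs.items():
        record = {
            "drug_id": g.drug_id,
            "n_atoms": g.n_atoms,
            "smiles_canonical": g.smiles_canonical,
            "atom_features": g.atom_features.astype(int).tolist(),
            "edges": [list(e) for e in g.edges],
        }
        (out / f"{drug_id}.json").write_text(json.dumps(record))


def export_fingerprints(fps: dict[str, np.ndarray], out_csv: str | Path) -> None:
    frame = pd.DataFrame.from_dict(
        {k: v.astype(int) for k, v in fps.items()}, orient="index",
        columns=[f"bit_{i}" for i in range(FINGERPRINT_BITS)],
    )
    frame.index.name = "drug_id"
    frame.to_csv(out_csv)
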