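"""SMILES → attributed molecular graphs.

Each heavy atom becomes a node carrying a binary feature vector with five
blocks: one-hot element symbol (with an ``other`` bucket), one-hot degree,
one-hot count of neighbouring hydrogens, one-hot implicit valence, and a
single aromaticity flag.  Bonds become featureless undirected edges.
Hydrogens are implicit: they appear only through the num-Hs block.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit is chatty about odd-but-parseable SMILES

logger = logging.getLogger(__name__)

# The 44-element vocabulary of the DeepChem-style atom featurizer, plus a
# terminal "other" bucket for anything outside it.
DEFAULT_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg",
    "Na", "Ca", "Fe", "As", "Al", "I", "B", "V", "K", "Tl",
    "Yb", "Sb", "Sn", "Ag", "Pd", "Co", "Se", "Ti", "Zn", "H",
    "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn", "Zr", "Cr",
    "Pt", "Hg", "Pb", "other",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a non-empty molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Fixed layout of the binary atom feature vector.

    Categorical values above a cap are clamped onto the cap position, so
    featurization is total on any parseable molecule.
    """

    symbol_vocabulary: tuple[str, ...] = DEFAULT_SYMBOLS
    max_degree: int = 10
    max_num_hs: int = 10
    max_implicit_valence: int = 10

    def __post_init__(self):
        if not self.symbol_vocabulary:
            raise ValueError("symbol vocabulary must be non-empty")
        if len(set(self.symbol_vocabulary)) != len(self.symbol_vocabulary):
            raise ValueError("duplicate symbols in vocabulary")
        if min(self.max_degree, self.max_num_hs, self.max_implicit_valence) < 0:
            raise ValueError("categorical caps must be >= 0")

    @property
    def total_dim(self) -> int:
        return (
            len(self.symbol_vocabulary)
            + (self.max_degree + 1)
            + (self.max_num_hs + 1)
            + (self.max_implicit_valence + 1)
            + 1  # aromatic flag
        )

    def fingerprint(self) -> str:
        """Stable hash used to check checkpoint/featurizer compatibility."""
        import hashlib

        payload = json.dumps(
            [list(self.symbol_vocabulary), self.max_degree, self.max_num_hs,
             self.max_implicit_valence],
            separators=(",", ":"),
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_atom_schema(
    symbols: tuple[str, ...] | list[str] | None = None,
    max_degree: int = 10,
    max_num_hs: int = 10,
    max_implicit_valence: int = 10,
) -> AtomFeatureSchema:
    """Build a feature schema; defaults give the documented 78-dim layout."""
    vocab = tuple(symbols) if symbols is not None else DEFAULT_SYMBOLS
    if "other" not in vocab:
        vocab = vocab + ("other",)
    return AtomFeatureSchema(vocab, max_degree, max_num_hs, max_implicit_valence)


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph with binary node features."""

    node_features: np.ndarray  # (n_atoms, total_dim), {0,1}
    edges: list[tuple[int, int]]  # unordered pairs, i < j
    smiles: str
    schema: AtomFeatureSchema = field(repr=False, default_factory=AtomFeatureSchema)

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def directed_arcs(self) -> tuple[np.ndarray, np.ndarray]:
        """Both orientations of every bond, for message passing."""
        if not self.edges:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        e = np.asarray(self.edges, dtype=np.intp)
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        return src, dst

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "n_atoms": self.n_atoms,
                "edges": [list(e) for e in self.edges],
                "feature_dim": self.node_features.shape[1],
            }
        )


def _one_hot(value: int | str, choices, clamp: bool) -> np.ndarray:
    v = np.zeros(len(choices))
    if isinstance(value, str):
        idx = choices.index(value) if value in choices else len(choices) - 1
    else:
        idx = min(value, len(choices) - 1) if clamp else value
    v[idx] = 1.0
    return v


def featurize_atom(
    symbol: str,
    degree: int,
    num_hs: int,
    implicit_valence: int,
    is_aromatic: bool,
    schema: AtomFeatureSchema,
) -> np.ndarray:
    """Binary feature vector for one atom: four one-hot blocks + aromatic flag.

    Unknown symbols fall in the ``other`` bucket; counts above a cap clamp
    onto the cap slot.
    """
    if min(degree, num_hs, implicit_valence) < 0:
        raise ValueError("atom attribute counts must be >= 0")
    sym = _one_hot(symbol, list(schema.symbol_vocabulary), clamp=False)
    deg = _one_hot(degree, range(schema.max_degree + 1), clamp=True)
    nhs = _one_hot(num_hs, range(schema.max_num_hs + 1), clamp=True)
    val = _one_hot(implicit_valence, range(schema.max_implicit_valence + 1), clamp=True)
    return np.concatenate([sym, deg, nhs, val, [1.0 if is_aromatic else 0.0]])


def smiles_to_graph(smiles: str, schema: AtomFeatureSchema | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Multi-fragment inputs (salts, ``.``-separated) keep the largest fragment,
    with a warning.  Hydrogens stay implicit.
    """
    schema = schema or AtomFeatureSchema()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        warnings.warn(f"multi-fragment SMILES {smiles!r}: keeping largest fragment")
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles, "empty molecule")

    feats = np.stack(
        [
            featurize_atom(
                a.GetSymbol(),
                a.GetDegree(),
                a.GetTotalNumHs(),
                a.GetImplicitValence(),
                a.GetIsAromatic(),
                schema,
            )
            for a in mol.GetAtoms()
        ]
    )
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(node_features=feats, edges=edges, smiles=smiles, schema=schema)


def read_drug_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a drug table (columns ``drug_id``, ``smiles``), order preserved."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"drug table missing required column {col!r}")
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate drug ids: {sorted(dup.unique())}")
    return list(zip(df["drug_id"], df["smiles"]))


def write_graph_dump(graphs: list[MolecularGraph], path: str | Path) -> None:
    """One JSON object per molecule, for debugging graph construction."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(g.to_json() + "\n")
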