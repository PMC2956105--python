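"""Molecular structures and per-atom property weighting schemes.

A :class:`MolecularStructure` wraps a hydrogen-explicit RDKit molecule,
optionally carrying one force-field-minimized 3D conformer.  Topological
descriptors work on the hydrogen-depleted heavy-atom subgraph; geometrical
descriptors use all atoms of the embedded conformer.

The weighting schemes (u = unit, m = atomic mass, e = Sanderson
electronegativity, p = atomic polarizability, v = van der Waals volume) are
tabulated per element in ``data/atom_properties.csv`` and used as
carbon-relative ratios, the convention of the descriptor literature: the
value for carbon is exactly 1 in every scheme.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import DomainError, UsageError

__all__ = [
    "MolecularStructure",
    "atom_property",
    "atom_weights",
    "embed_conformer",
    "DEFAULT_EMBED_SEED",
]

# single reference conformer per compound; one fixed default seed
DEFAULT_EMBED_SEED = 20100920

WEIGHT_SCHEMES = ("u", "m", "e", "p", "v")
_SCHEME_COLUMN = {
    "m": "mass",
    "e": "sanderson_en",
    "p": "polarizability",
    "v": "vdw_volume",
}


@lru_cache(maxsize=1)
def _property_table() -> pd.DataFrame:
    with importlib.resources.files("erqsar.data").joinpath("atom_properties.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("element")


def atom_property(symbol: str, scheme: str) -> float:
    """Carbon-relative atomic property for one element under one scheme."""
    if scheme == "u":
        return 1.0
    if scheme not in _SCHEME_COLUMN:
        raise UsageError(f"unknown weighting scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    tab = _property_table()
    col = _SCHEME_COLUMN[scheme]
    if symbol not in tab.index:
        raise DomainError(f"element {symbol!r} not in the atomic property table")
    return float(tab.loc[symbol, col] / tab.loc["C", col])


@dataclass
class MolecularStructure:
    """Hydrogen-explicit molecular graph plus optional 3D conformer."""

    mol: Chem.Mol
    embed_seed: int | None = None
    embed_failed: bool = field(default=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularStructure":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DomainError(f"unparsable SMILES {smiles!r}")
        return cls(mol=Chem.AddHs(mol))

    # ------------------------------------------------------------------ views
    @property
    def has_coords(self) -> bool:
        return self.mol.GetNumConformers() > 0

    @property
    def coords(self) -> np.ndarray:
        """All-atom 3D coordinates in Angstrom (atoms x 3)."""
        if not self.has_coords:
            raise DomainError("structure has no 3D coordinates; run embed_conformer first")
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def heavy_mol(self) -> Chem.Mol:
        """Hydrogen-depleted view of the molecule."""
        return Chem.RemoveHs(self.mol)

    def heavy_adjacency(self) -> np.ndarray:
        return np.asarray(Chem.GetAdjacencyMatrix(self.heavy_mol), dtype=float)

    def heavy_distance_matrix(self) -> np.ndarray:
        """Topological (bond-count) distances between heavy atoms."""
        return np.asarray(Chem.GetDistanceMatrix(self.heavy_mol), dtype=float)

    def weights(self, scheme: str, heavy_only: bool = True) -> np.ndarray:
        mol = self.heavy_mol if heavy_only else self.mol
        return np.array([atom_property(a.GetSymbol(), scheme) for a in mol.GetAtoms()])


def atom_weights(mol: Chem.Mol, scheme: str) -> np.ndarray:
    """Carbon-relative weights for every atom of an RDKit molecule."""
    return np.array([atom_property(a.GetSymbol(), scheme) for a in mol.GetAtoms()])


def embed_conformer(structure: MolecularStructure, seed: int = DEFAULT_EMBED_SEED) -> MolecularStructure:
    """Generate one energy-minimized 3D conformer, deterministically.

    Distance-geometry embedding (ETKDG) with a fixed random seed followed by
    MMFF94 minimization (UFF fallback for atoms outside the MMFF
    parameterization).  Running twice with the same seed yields identical
    coordinates.  On embedding failure the structure is returned flagged, so
    callers can mark 3D descriptors unavailable for that compound.
    """
    mol = Chem.Mol(structure.mol)
    mol.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        return MolecularStructure(mol=structure.mol, embed_seed=seed, embed_failed=True)
    try:
        ok = AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
        if ok == -1:  # MMFF setup failed for this molecule
            AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    return MolecularStructure(mol=mol, embed_seed=seed)
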