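"""Study dataset: parsing, validation and serialization of compound tables.

The packaged fixture is the 82-ligand estrogen-receptor study set
(2-arylnaphthalenes and 2-arylquinolines with pIC50 measured against both
ER subtypes).  Generic CSV/SDF round-tripping for arbitrary compound tables
lives here as well.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from .errors import EmptyInputError, FixtureIntegrityError, SchemaError

__all__ = [
    "CompoundRecord",
    "CompoundTable",
    "load_fixture",
    "read_compound_csv",
    "write_compound_csv",
    "write_sdf",
]

_FIXTURE_NAME = "er_ligands.csv"
_REQUIRED_COLUMNS = ("compound_id", "smiles", "pic50_alpha", "pic50_beta")


@dataclass(frozen=True)
class CompoundRecord:
    """One ligand: identifier, structure and measured endpoints.

    ``s_value`` is the printed selectivity index and is ``None`` for the one
    compound that binds both receptor subtypes equally (the selectivity
    statistic is undefined there).
    """

    compound_id: str
    smiles: str
    pic50_alpha: float
    pic50_beta: float
    s_value: float | None = None


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with provenance.

    ``rejected`` collects rows that could not be parsed (index, raw SMILES,
    reason) so malformed input is reported rather than silently dropped.
    """

    records: list[CompoundRecord]
    source: str = ""
    rejected: list[tuple[int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "pic50_alpha": [r.pic50_alpha for r in self.records],
                "pic50_beta": [r.pic50_beta for r in self.records],
                "s": [r.s_value for r in self.records],
            }
        )


def _validate_smiles(smiles: str) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 2:
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return mol


def load_fixture() -> CompoundTable:
    """Load the packaged 82-ligand study dataset.

    The fixture is validated on every load: 82 unique records, parsable
    connected SMILES, pIC50 within the assay's printed range, and the
    selectivity value absent exactly when the two affinities are equal.
    """
    with importlib.resources.files("erqsar.data").joinpath(_FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh)
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        smiles = str(row["smiles"])
        if _validate_smiles(smiles) is None:
            raise FixtureIntegrityError(f"fixture record {cid}: invalid SMILES {smiles!r}")
        a, b = float(row["pic50_alpha"]), float(row["pic50_beta"])
        if not (3.0 <= a <= 9.0 and 3.0 <= b <= 9.0):
            raise FixtureIntegrityError(f"fixture record {cid}: pIC50 outside [3, 9]")
        s = None if pd.isna(row["s"]) else float(row["s"])
        if (s is None) != (a == b):
            raise FixtureIntegrityError(
                f"fixture record {cid}: S must be absent exactly when pIC50s are equal"
            )
        records.append(CompoundRecord(cid, smiles, a, b, s))
    if len(records) != 82:
        raise FixtureIntegrityError(f"expected 82 fixture records, found {len(records)}")
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise FixtureIntegrityError("duplicate compound_id in fixture")
    return CompoundTable(records, source=f"package fixture {_FIXTURE_NAME}")


def read_compound_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> CompoundTable:
    """Read a compound table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row; UTF-8, comma separated, ``.`` decimals.
    dialect
        Optional map from the canonical column names (``compound_id``,
        ``smiles``, ``pic50_alpha``, ``pic50_beta``, ``s``) to the names used
        in the file.

    Rows whose SMILES does not parse to a connected molecule with at least
    two heavy atoms are collected in ``table.rejected`` instead of being
    silently dropped.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    colmap = {canon: dialect.get(canon, canon) for canon in (*_REQUIRED_COLUMNS, "s")}
    missing = [colmap[c] for c in _REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_s = colmap["s"] in df.columns

    records: list[CompoundRecord] = []
    rejected: list[tuple[int, str, str]] = []
    for i, row in df.iterrows():
        smiles = str(row[colmap["smiles"]])
        if _validate_smiles(smiles) is None:
            rejected.append((int(i), smiles, "unparsable or disconnected SMILES"))
            continue
        s_raw = row[colmap["s"]] if has_s else None
        records.append(
            CompoundRecord(
                compound_id=str(row[colmap["compound_id"]]),
                smiles=smiles,
                pic50_alpha=float(row[colmap["pic50_alpha"]]),
                pic50_beta=float(row[colmap["pic50_beta"]]),
                s_value=None if s_raw is None or pd.isna(s_raw) else float(s_raw),
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no valid rows")
    return CompoundTable(records, source=str(path), rejected=rejected)


def write_compound_csv(table: CompoundTable, path: str | Path) -> None:
    """Write a compound table as canonical CSV (inverse of read_compound_csv)."""
    table.to_frame().to_csv(path, index=False)


def write_sdf(
    table: CompoundTable,
    structures: Mapping[str, "object"],
    path: str | Path,
) -> int:
    """Write an SDF (V2000) with pIC50 and S as data fields.

    ``structures`` maps compound_id to a :class:`~erqsar.structures.MolecularStructure`
    carrying 3D coordinates.  Returns the number of records written.
    """
    writer = Chem.SDWriter(str(path))
    count = 0
    try:
        for rec in table:
            struct = structures[rec.compound_id]
            mol = struct.mol
            if mol.GetNumConformers() == 0:
                raise ValueError(f"{rec.compound_id}: structure lacks 3D coordinates")
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", rec.compound_id)
            mol.SetProp("pIC50_alpha", f"{rec.pic50_alpha:.2f}")
            mol.SetProp("pIC50_beta", f"{rec.pic50_beta:.2f}")
            if rec.s_value is not None:
                mol.SetProp("S", f"{rec.s_value:.2f}")
            writer.write(mol)
            count += 1
    finally:
        writer.close()
    return count
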