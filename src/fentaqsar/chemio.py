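"""Molecule table IO, structure standardization and affinity conversion.

The modelling workflow operates on tables of compounds carrying a canonical
SMILES and a binding affinity expressed as pKi = -log10(Ki in molar).  Ki
values supplied in nanomolar are converted via pKi = 9 - log10(Ki_nM).
Structures are standardized on read: the largest organic fragment is kept
(salt stripping) and the explicit-H-free canonical SMILES is stored.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "MoleculeRecord",
    "MoleculeTable",
    "RejectedRecord",
    "ki_to_pki",
    "pki_to_ki",
    "standardize_smiles",
    "read_molecules",
    "write_molecules",
    "split_train_test",
    "default_n_test",
]

logger = logging.getLogger(__name__)

TRAIN = "train"
TEST = "test"
UNASSIGNED = "unassigned"


def ki_to_pki(ki_nM: float) -> float:
    """Convert an inhibition constant in nanomolar to pKi.

    pKi = -log10(Ki [M]) = 9 - log10(Ki [nM]).  Raises ValueError for
    non-positive Ki.
    """
    if not ki_nM > 0:
        raise ValueError(f"Ki must be positive, got {ki_nM!r}")
    return 9.0 - math.log10(ki_nM)


def pki_to_ki(pki: float) -> float:
    """Inverse of :func:`ki_to_pki`: pKi back to Ki in nanomolar."""
    return 10.0 ** (9.0 - pki)


def standardize_smiles(smiles: str) -> str:
    """Canonicalize a SMILES, keeping only the largest fragment.

    Returns the canonical isomeric SMILES of the largest fragment (by heavy
    atom count, ties broken by molecular weight), or raises ValueError if
    the input does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical structure and affinity."""

    id: str
    smiles: str
    pki: float
    ki_nM: float | None = None
    partition: str = UNASSIGNED

    def __post_init__(self):
        if self.partition not in (TRAIN, TEST, UNASSIGNED):
            raise ValueError(f"bad partition label {self.partition!r}")
        if self.ki_nM is not None:
            expected = ki_to_pki(self.ki_nM)
            if abs(expected - self.pki) > 1e-9:
                raise ValueError(
                    f"inconsistent Ki/pKi for {self.id}: "
                    f"ki_nM={self.ki_nM} implies pKi={expected}, got {self.pki}"
                )

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - standardized SMILES always parse
            raise ValueError(f"stored SMILES failed to parse for {self.id}")
        return m


@dataclass(frozen=True)
class RejectedRecord:
    id: str
    reason: str


@dataclass
class MoleculeTable:
    """Ordered collection of molecule records with unique ids."""

    records: list[MoleculeRecord] = field(default_factory=list)
    provenance: str = ""
    rejects: list[RejectedRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> MoleculeRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def pki(self) -> np.ndarray:
        return np.array([r.pki for r in self.records], dtype=float)

    def subset(self, partition: str) -> "MoleculeTable":
        return MoleculeTable(
            [r for r in self.records if r.partition == partition],
            provenance=f"{self.provenance} [{partition}]".strip(),
        )

    @property
    def train(self) -> "MoleculeTable":
        return self.subset(TRAIN)

    @property
    def test(self) -> "MoleculeTable":
        return self.subset(TEST)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": [r.smiles for r in self.records],
                "ki_nM": [r.ki_nM for r in self.records],
                "pki": [r.pki for r in self.records],
                "partition": [r.partition for r in self.records],
            }
        )


def _build_record(
    mol_id: str, smiles: str, ki_nM: float | None, pki: float | None
) -> MoleculeRecord:
    canonical = standardize_smiles(smiles)
    if pki is None:
        if ki_nM is None:
            raise ValueError("no affinity (need ki_nM or pki)")
        pki = ki_to_pki(ki_nM)
    elif ki_nM is not None and abs(ki_to_pki(ki_nM) - pki) > 1e-9:
        raise ValueError(f"ki_nM={ki_nM} and pki={pki} disagree")
    return MoleculeRecord(id=mol_id, smiles=canonical, pki=float(pki), ki_nM=ki_nM)


def _parse_optional_float(text: str | None) -> float | None:
    if text is None or str(text).strip() == "":
        return None
    return float(text)


def read_molecules(
    path: str | Path,
    format: str | None = None,
    pki_tag: str = "pKi",
    ki_tag: str = "Ki_nM",
) -> MoleculeTable:
    """Read a molecule table from CSV, SDF or SMILES file.

    CSV needs columns ``id``, ``smiles`` and at least one of ``ki_nM`` /
    ``pki``.  SDF reads the affinity from a named property tag.  Unparsable
    or affinity-less entries are rejected (logged and listed in
    ``table.rejects``); duplicate ids are an error.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".sdf": "sdf", ".smi": "smi"}.get(
            path.suffix.lower(), "csv"
        )
    if format not in ("csv", "sdf", "smi"):
        raise ValueError(f"unknown format {format!r}")

    records: list[MoleculeRecord] = []
    rejects: list[RejectedRecord] = []

    def attempt(mol_id, smiles, ki, pki, partition=UNASSIGNED):
        try:
            rec = _build_record(mol_id, smiles, ki, pki)
            if partition in (TRAIN, TEST):
                rec = replace(rec, partition=partition)
            records.append(rec)
        except ValueError as exc:
            logger.warning("rejected %s: %s", mol_id, exc)
            rejects.append(RejectedRecord(id=str(mol_id), reason=str(exc)))

    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = set(reader.fieldnames or ())
            if not {"id", "smiles"} <= cols:
                raise ValueError("CSV must have 'id' and 'smiles' columns")
            if not ({"ki_nM", "pki"} & cols):
                raise ValueError("CSV must have a 'ki_nM' or 'pki' column")
            for row in reader:
                attempt(
                    row["id"],
                    row["smiles"],
                    _parse_optional_float(row.get("ki_nM")),
                    _parse_optional_float(row.get("pki")),
                    row.get("partition", UNASSIGNED) or UNASSIGNED,
                )
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                rejects.append(RejectedRecord(id=f"sdf_{i}", reason="unparsable record"))
                continue
            mol_id = mol.GetProp("_Name") if mol.GetProp("_Name") else f"sdf_{i}"
            pki = (
                float(mol.GetProp(pki_tag)) if mol.HasProp(pki_tag) else None
            )
            ki = float(mol.GetProp(ki_tag)) if mol.HasProp(ki_tag) else None
            part = mol.GetProp("partition") if mol.HasProp("partition") else UNASSIGNED
            attempt(mol_id, Chem.MolToSmiles(mol), ki, pki, part)
    else:  # smi: "SMILES id pki" whitespace separated
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"smi_{i}"
                pki = float(parts[2]) if len(parts) > 2 else None
                attempt(mol_id, smiles, None, pki)

    table = MoleculeTable(records, provenance=str(path), rejects=rejects)
    return table


def write_molecules(table: MoleculeTable, path: str | Path, format: str | None = None):
    """Write a table to CSV or SDF (affinity in the ``pKi`` property tag)."""
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "ki_nM", "pki", "partition"])
            for r in table:
                writer.writerow(
                    [
                        r.id,
                        r.smiles,
                        "" if r.ki_nM is None else repr(r.ki_nM),
                        repr(r.pki),
                        r.partition,
                    ]
                )
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in table:
                mol = r.mol()
                mol.SetProp("_Name", r.id)
                mol.SetProp("pKi", repr(r.pki))
                if r.ki_nM is not None:
                    mol.SetProp("Ki_nM", repr(r.ki_nM))
                mol.SetProp("partition", r.partition)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {format!r}")


def default_n_test(n: int) -> int:
    """Protocol held-out size: 21 of 115, else round(0.18 n)."""
    return 21 if n == 115 else max(1, round(0.18 * n))


def split_train_test(
    table: MoleculeTable, n_test: int | None = None, seed: int = 0
) -> MoleculeTable:
    """Randomly assign train/test partition labels.

    Exactly ``n_test`` records become the external test set, the remainder
    the training set.  The same seed always yields the same partition.
    """
    n = len(table)
    if n_test is None:
        n_test = default_n_test(n)
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n}), got {n_test}")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    records = [
        replace(r, partition=TEST if i in test_idx else TRAIN)
        for i, r in enumerate(table.records)
    ]
    return MoleculeTable(records, provenance=table.provenance)
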