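"""Hashed circular fingerprints (ECFP6/FCFP6 style) and Tanimoto similarity.

ECFP6 hashes circular atom environments of radius 0..3 (diameter 6) built
on connectivity invariants; FCFP6 uses pharmacophoric feature invariants
(donor, acceptor, positive/negative ionizable, aromatic, halogen) in the
Rogers-Hahn convention.  Identifiers are folded into a fixed-length bit
space (default 2048) and similarity is the Tanimoto coefficient on the
resulting bit sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = ["Fingerprint", "fingerprint", "tanimoto", "distance", "FLAVORS"]

FLAVORS = ("ECFP6", "FCFP6")
DEFAULT_LENGTH = 2048
RADIUS = 3  # diameter 6


@dataclass(frozen=True)
class Fingerprint:
    """Sparse folded circular fingerprint: a set of on-bit indices."""

    bits: frozenset[int]
    length: int = DEFAULT_LENGTH
    flavor: str = "ECFP6"

    def __post_init__(self):
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.length < 1:
            raise ValueError("length must be positive")
        if any(b < 0 or b >= self.length for b in self.bits):
            raise ValueError("bit identifier outside fold length")
        if not self.bits:
            raise ValueError("empty fingerprint (every molecule has atoms)")

    @property
    def sorted_bits(self) -> tuple[int, ...]:
        return tuple(sorted(self.bits))


_GENERATOR_CACHE: dict[tuple[str, int], object] = {}


def _generator(flavor: str, length: int):
    key = (flavor, length)
    gen = _GENERATOR_CACHE.get(key)
    if gen is None:
        inv = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            if flavor == "FCFP6"
            else None
        )
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=RADIUS, fpSize=length, atomInvariantsGenerator=inv
        )
        _GENERATOR_CACHE[key] = gen
    return gen


def fingerprint(
    mol: "Chem.Mol | str", flavor: str = "ECFP6", length: int = DEFAULT_LENGTH
) -> Fingerprint:
    """Compute the folded circular fingerprint of a molecule.

    ``mol`` may be an RDKit molecule, a SMILES string, or any object with a
    ``mol()`` method returning an RDKit molecule (e.g. a MoleculeRecord).
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}")
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"unparsable SMILES: {mol!r}")
    elif hasattr(mol, "mol"):
        m = mol.mol()
    else:
        m = mol
    fp = _generator(flavor, length).GetFingerprint(m)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), length=length, flavor=flavor)


def _check_compatible(a: Fingerprint, b: Fingerprint):
    if a.flavor != b.flavor or a.length != b.length:
        raise ValueError(
            f"incompatible fingerprints: {a.flavor}/{a.length} vs {b.flavor}/{b.length}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| in [0, 1]."""
    _check_compatible(a, b)
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Soergel) distance, 1 - tanimoto."""
    return 1.0 - tanimoto(a, b)


def write_fingerprints(fps: dict[str, Fingerprint], path) -> None:
    # debugging export: id <tab> space-separated sorted bit list
    with open(path, "w", encoding="utf-8") as fh:
        for mol_id, fp in fps.items():
            fh.write(f"{mol_id}\t{' '.join(map(str, fp.sorted_bits))}\n")
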