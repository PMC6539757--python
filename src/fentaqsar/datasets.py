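"""Synthetic fentanyl-analog dataset and fragment library generators.

The public μOR binding data behind this kind of model is a curated ChEMBL
subset that is not redistributable compound-by-compound, so everything in
the workflow is exercised against a generated stand-in: analogs built by
combinatorial decoration of the 4-anilidopiperidine scaffold at five
positions (N-tail R1, piperidine 4-substituent R2, anilide acyl R3,
piperidine 3-substituent R4, anilide aryl R5) with pKi assigned by a known
additive structure-activity model plus Gaussian noise, clipped to the
experimental range 5.3-10.1.

The substituent contribution constants are fixed package data chosen to
emulate the qualitative landscape of real fentanyl SAR: removing the acyl
group (R3 = H) collapses potency, chains longer than propionyl erode it,
and aromatic R5 groups are favourable - so activity-cliff mining on the
noise-free set recovers acyl-removal cliffs, and regression models can
recover the additive structure.

No claim is made that the generated pKi values match real compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord, MoleculeTable

__all__ = [
    "SARGroundTruth",
    "generate_dataset",
    "generate_fragment_library",
    "SCAFFOLD",
    "CONTRIBUTIONS",
    "BASE_PKI",
    "PKI_RANGE",
]

# 4-anilidopiperidine scaffold with five decoration sites
SCAFFOLD = "[*:1]N1CC([*:4])C(CC1)([*:2])N([*:5])[*:3]"

PKI_RANGE = (5.3, 10.1)
BASE_PKI = 7.1

# (label, attachment SMILES, pKi increment); frozen package data
CONTRIBUTIONS: dict[str, list[tuple[str, str, float]]] = {
    "R1": [
        ("phenethyl", "[*:1]CCc1ccccc1", 1.0),
        ("thienylethyl", "[*:1]CCc1cccs1", 0.8),
        ("benzyl", "[*:1]Cc1ccccc1", 0.2),
        ("phenylpropyl", "[*:1]CCCc1ccccc1", 0.2),
        ("cyclohexylethyl", "[*:1]CCC1CCCCC1", 0.0),
        ("allyl", "[*:1]CC=C", -0.5),
        ("methyl", "[*:1]C", -0.9),
        ("H", "[*:1][H]", -1.0),
    ],
    "R2": [
        ("H", "[*:2][H]", 0.0),
        ("carbomethoxy", "[*:2]C(=O)OC", 0.9),
        ("methyl", "[*:2]C", 0.1),
        ("hydroxymethyl", "[*:2]CO", -0.2),
    ],
    "R3": [
        ("H", "[*:3][H]", -1.9),
        ("acetyl", "[*:3]C(=O)C", 0.7),
        ("propanoyl", "[*:3]C(=O)CC", 1.4),
        ("butanoyl", "[*:3]C(=O)CCC", 0.8),
        ("pentanoyl", "[*:3]C(=O)CCCC", 0.1),
        ("isobutyryl", "[*:3]C(=O)C(C)C", 0.7),
        ("cyclopropanoyl", "[*:3]C(=O)C1CC1", 1.5),
        ("acryloyl", "[*:3]C(=O)C=C", 1.1),
        ("methoxyacetyl", "[*:3]C(=O)COC", 0.6),
        ("furoyl", "[*:3]C(=O)c1ccco1", 1.0),
    ],
    "R4": [
        ("H", "[*:4][H]", 0.0),
        ("methyl", "[*:4]C", 0.3),
        ("ethyl", "[*:4]CC", 0.1),
    ],
    "R5": [
        ("phenyl", "[*:5]c1ccccc1", 1.0),
        ("thienyl", "[*:5]c1cccs1", 0.9),
        ("fluorophenyl", "[*:5]c1ccc(F)cc1", 0.9),
        ("methoxyphenyl", "[*:5]c1ccccc1OC", 0.6),
        ("pyridyl", "[*:5]c1ccccn1", 0.3),
        ("benzyl", "[*:5]Cc1ccccc1", 0.0),
        ("H", "[*:5][H]", -0.9),
    ],
}

SITES = ("R1", "R2", "R3", "R4", "R5")

# combos guaranteed to be present: fentanyl, its acyl-removal partner and
# the chain-length / aryl-swap motifs that the cliff analysis should find
MANDATORY_COMBOS = [
    ("phenethyl", "H", "propanoyl", "H", "phenyl"),  # fentanyl
    ("phenethyl", "H", "H", "H", "phenyl"),  # despropionyl (R3 = H)
    ("phenethyl", "H", "pentanoyl", "H", "phenyl"),  # long-chain R3
    ("phenethyl", "H", "acetyl", "H", "phenyl"),  # acetyl analog
    ("phenethyl", "H", "propanoyl", "H", "thienyl"),  # R5 aryl swap
    ("phenethyl", "H", "propanoyl", "H", "H"),  # R5 removed
    ("phenethyl", "carbomethoxy", "propanoyl", "H", "phenyl"),  # carfentanil-like
    ("phenethyl", "H", "propanoyl", "methyl", "phenyl"),  # 3-methyl analog
]


@dataclass(frozen=True)
class SARGroundTruth:
    """The additive structure-activity model behind a generated dataset."""

    base_pki: float
    contributions: dict[str, dict[str, float]]  # site -> label -> increment
    sigma: float
    combos: dict[str, tuple[str, ...]]  # molecule id -> substituent labels

    def additive_pki(self, combo: tuple[str, ...]) -> float:
        raw = self.base_pki + sum(
            self.contributions[site][label] for site, label in zip(SITES, combo)
        )
        return float(np.clip(raw, *PKI_RANGE))

    def true_pki(self, mol_id: str) -> float:
        return self.additive_pki(self.combos[mol_id])


def _frag_smiles(site: str, label: str) -> str:
    for name, smi, _ in CONTRIBUTIONS[site]:
        if name == label:
            return smi
    raise KeyError(f"{site}:{label}")


def build_analog(combo: tuple[str, ...]) -> str:
    """Weld one substituent combination onto the scaffold; canonical SMILES."""
    m = Chem.MolFromSmiles(SCAFFOLD)
    for site, label in zip(SITES, combo):
        frag = Chem.MolFromSmiles(_frag_smiles(site, label), sanitize=False)
        m = Chem.CombineMols(m, frag)
    z = Chem.molzip(m)
    z = Chem.RemoveHs(z)
    Chem.SanitizeMol(z)
    return Chem.MolToSmiles(z)


def generate_dataset(
    n: int = 115, sigma: float = 0.2, seed: int = 1
) -> tuple[MoleculeTable, SARGroundTruth]:
    """Generate n distinct analogs with additive-SAR pKi plus noise.

    Always includes fentanyl itself and the cliff-motif combinations; the
    remainder is a seeded random sample of the decoration space.  pKi =
    base + sum(contributions) + N(0, sigma^2), clipped to [5.3, 10.1].
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    space = [
        (r1, r2, r3, r4, r5)
        for r1, _, _ in CONTRIBUTIONS["R1"]
        for r2, _, _ in CONTRIBUTIONS["R2"]
        for r3, _, _ in CONTRIBUTIONS["R3"]
        for r4, _, _ in CONTRIBUTIONS["R4"]
        for r5, _, _ in CONTRIBUTIONS["R5"]
    ]
    if n > len(space):
        raise ValueError(f"n={n} exceeds the {len(space)}-combination space")
    rng = np.random.default_rng(seed)
    chosen = list(MANDATORY_COMBOS[: min(n, len(MANDATORY_COMBOS))])
    seen = set(chosen)
    # analog-series sampling: each site keeps its fentanyl-native group with
    # high probability, so the set is congeneric (single- and double-point
    # variations dominate) the way curated SAR series are
    native = MANDATORY_COMBOS[0]
    p_native = {"R1": 0.6, "R2": 0.7, "R3": 0.45, "R4": 0.7, "R5": 0.6}
    labels = {site: [name for name, _, _ in CONTRIBUTIONS[site]] for site in SITES}
    while len(chosen) < n:
        combo = tuple(
            nat
            if rng.random() < p_native[site]
            else labels[site][rng.integers(len(labels[site]))]
            for site, nat in zip(SITES, native)
        )
        if combo not in seen:
            seen.add(combo)
            chosen.append(combo)

    contributions = {
        site: {name: val for name, _, val in CONTRIBUTIONS[site]} for site in SITES
    }
    combos: dict[str, tuple[str, ...]] = {}
    records = []
    seen_smiles: dict[str, str] = {}
    noise = rng.normal(0.0, sigma, size=len(chosen)) if sigma > 0 else np.zeros(len(chosen))
    truth = SARGroundTruth(
        base_pki=BASE_PKI, contributions=contributions, sigma=sigma, combos=combos
    )
    for i, combo in enumerate(chosen):
        smiles = build_analog(combo)
        if smiles in seen_smiles:  # pragma: no cover - sites are chemically distinct
            raise RuntimeError(f"duplicate structure for {combo}")
        seen_smiles[smiles] = combo
        mol_id = f"M{i + 1:03d}"
        combos[mol_id] = combo
        pki = float(np.clip(truth.additive_pki(combo) + noise[i], *PKI_RANGE))
        records.append(MoleculeRecord(id=mol_id, smiles=smiles, pki=pki))
    table = MoleculeTable(records, provenance=f"synthetic n={n} sigma={sigma} seed={seed}")
    return table, truth


# ---------------------------------------------------------------------------
# fragment library

_ALKYL = [
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)CC", "CC(C)C", "C(C)(C)C",
    "CCCCC", "CCC(C)C", "CC(C)CC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
]
_CYCLO = [
    "C1CC1", "CC1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "C1CC1C", "CC1CCC1",
]
_ALKENYL = ["C=C", "CC=C", "C=CC", "C(=C)C", "CC=CC"]
_ETHER = ["COC", "CCOC", "COCC", "C1CCOC1", "C1CCCO1", "C1CCOCC1", "CO", "CCO"]
_HETEROARYL = [
    "c1ccco1", "c1ccoc1", "c1cccs1", "c1ccsc1", "c1ccncc1", "c1cccnc1",
    "c1ccccn1", "c1cnccn1", "c1ccc2c(c1)OCO2", "c1ccc2ccccc2c1",
    "c1cc2ccccc2cc1", "c1cn[nH]c1", "c1cnoc1", "c1csnc1",
]
_PHENYL_SUBS = ["F", "Cl", "Br", "I", "C", "CC", "OC", "O", "C(F)(F)F", "C#N", "N(C)C", "N"]


def _phenyl_variants():
    yield "c1ccccc1"
    for s in _PHENYL_SUBS:
        for pattern in (
            f"c1ccc({s})cc1",  # para
            f"c1cccc({s})c1",  # meta
            f"c1ccccc1{s}",  # ortho (as ring-atom substituent suffix)
        ):
            yield pattern
    for s1 in _PHENYL_SUBS:
        for s2 in _PHENYL_SUBS:
            yield f"c1cc({s1})c({s2})cc1"  # 3,4-disubstituted
            yield f"c1cc({s1})cc({s2})c1"  # 3,5-disubstituted


def _all_fragment_bodies():
    for body in _ALKYL + _CYCLO + _ALKENYL + _ETHER + _HETEROARYL:
        yield body
    for ring in _phenyl_variants():
        yield ring
        yield "C" + ring  # benzyl-type
        yield "CC" + ring  # phenethyl-type


@dataclass(frozen=True)
class FragmentLibrary:
    """Single-attachment fragments (dummy atom, map number 1)."""

    fragments: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self):
        for smi in self.fragments:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"fragment does not parse: {smi!r}")
            dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 1 or dummies[0].GetAtomMapNum() != 1:
                raise ValueError(f"fragment needs exactly one [*:1]: {smi!r}")

    def __len__(self):
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def merged(self, other: "FragmentLibrary") -> "FragmentLibrary":
        return FragmentLibrary(
            _dedup(list(self.fragments) + list(other.fragments)),
            provenance=f"{self.provenance}+{other.provenance}",
        )

    @classmethod
    def from_smiles_file(cls, path) -> "FragmentLibrary":
        frags = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                smi = line.split()[0] if line.split() else ""
                if smi and not smi.startswith("#"):
                    frags.append(smi)
        return cls(_dedup(frags), provenance=str(path))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, smi in enumerate(self.fragments):
                fh.write(f"{smi}\tfrag_{i + 1:04d}\n")


def _dedup(smiles_list) -> tuple[str, ...]:
    seen = {}
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        seen.setdefault(Chem.MolToSmiles(mol), None)
    return tuple(sorted(seen))


def generate_fragment_library(n_min: int = 600, seed: int = 1) -> FragmentLibrary:
    """Combinatorial single-attachment fragment set (>= n_min after dedup).

    Covers alkyl, cycloalkyl, alkenyl, ether, aryl and heteroaryl bodies,
    including the substituents of known designer fentanyl analogs
    (furanyl, acryloyl, cyclopropyl, tetrahydrofuranyl, methoxymethyl...).
    Content is exhaustive and deterministic; the seed only shuffles the
    ordering so downstream caps sample reproducibly.
    """
    bodies = _dedup(f"[*:1]{body}" for body in _all_fragment_bodies())
    if len(bodies) < n_min:
        raise ValueError(
            f"combinatorial space yields {len(bodies)} fragments < n_min={n_min}"
        )
    order = np.random.default_rng(seed).permutation(len(bodies))
    frags = tuple(bodies[i] for i in order)
    return FragmentLibrary(frags, provenance=f"generated seed={seed}")
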