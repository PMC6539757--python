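"""Scaffold-hopping enumeration and applicability-domain-gated consensus.

Six series carve the fentanyl skeleton into a constant scaffold with one
attachment point and a varied region (N-tail, anilide aryl, piperidine
decoration, acyl group, anilide-ring substituent, phenethyl aryl).  Every
fragment of a library is welded onto each scaffold, products are
valence-checked, deduplicated and capped, and each product is scored by
the three fitted models.  A prediction only counts toward the consensus
when the molecule lies inside that model's applicability domain: for the
fingerprint kNN models a maximum Tanimoto similarity to the training set
of at least 0.40, for the field model a leverage below 3(A+1)/n.  The
consensus is the median of the in-domain predictions (mean of two).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import MoleculeRecord, MoleculeTable
from .datasets import FragmentLibrary
from .field import AlignmentError, FieldQSARResults
from .knn import KNNResults

__all__ = [
    "SeriesDefinition",
    "ConsensusPrediction",
    "DEFAULT_SERIES",
    "enumerate_series",
    "applicability_domain",
    "consensus_predict",
    "screen",
    "AD_SIMILARITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

AD_SIMILARITY_THRESHOLD = 0.40
MAX_PRODUCT_MW = 700.0


@dataclass(frozen=True)
class SeriesDefinition:
    """A constant scaffold with exactly one attachment point."""

    name: str
    scaffold: str  # SMILES with one [*:1]
    description: str = ""

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.scaffold)
        if mol is None:
            raise ValueError(f"scaffold does not parse: {self.scaffold!r}")
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError("scaffold needs exactly one attachment point")

    def core(self) -> Chem.Mol:
        """The scaffold with the attachment dummy removed (a query core)."""
        mol = Chem.RWMol(Chem.MolFromSmiles(self.scaffold))
        dummy = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        mol.RemoveAtom(dummy)
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out


# The six series: one varied region each, the rest of fentanyl constant.
# Region boundaries are an interpretation of the usual R1..R5 decoration
# scheme of the 4-anilidopiperidine skeleton.
DEFAULT_SERIES = (
    SeriesDefinition(
        "Series1",
        "[*:1]N1CCC(N(c2ccccc2)C(=O)CC)CC1",
        "piperidine N-tail replaced (R1)",
    ),
    SeriesDefinition(
        "Series2",
        "CCC(=O)N([*:1])C1CCN(CCc2ccccc2)CC1",
        "anilide N-aryl replaced (R5 region)",
    ),
    SeriesDefinition(
        "Series3",
        "CCC(=O)N(c1ccccc1)C1CC([*:1])N(CCc2ccccc2)CC1",
        "piperidine core decorated at C3 (R2/R4 region)",
    ),
    SeriesDefinition(
        "Series4",
        "[*:1]C(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
        "acyl substituent replaced (R3)",
    ),
    SeriesDefinition(
        "Series5",
        "CCC(=O)N(c1ccc([*:1])cc1)C1CCN(CCc2ccccc2)CC1",
        "anilide phenyl para-decorated",
    ),
    SeriesDefinition(
        "Series6",
        "CCC(=O)N(c1ccccc1)C1CCN(CC[*:1])CC1",
        "phenethyl aryl replaced",
    ),
)


def enumerate_series(
    series: SeriesDefinition,
    lib: FragmentLibrary,
    cap: int = 500,
) -> MoleculeTable:
    """Weld every library fragment onto the series scaffold.

    Products are sanitized (valence check), restricted to single fragments
    under 700 Da, deduplicated by canonical SMILES and returned in
    canonical-sort order, at most ``cap`` of them.  Invalid welds are
    dropped and counted in the table provenance.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    scaffold = Chem.MolFromSmiles(series.scaffold)
    products: dict[str, None] = {}
    dropped = 0
    for frag_smiles in lib:
        frag = Chem.MolFromSmiles(frag_smiles, sanitize=False)
        if frag is None:
            dropped += 1
            continue
        try:
            welded = Chem.molzip(Chem.CombineMols(scaffold, frag))
            welded = Chem.RemoveHs(welded)
            Chem.SanitizeMol(welded)
        except Exception:
            dropped += 1
            continue
        if len(Chem.GetMolFrags(welded)) != 1:
            dropped += 1
            continue
        if Descriptors.MolWt(welded) > MAX_PRODUCT_MW:
            dropped += 1
            continue
        products.setdefault(Chem.MolToSmiles(welded))
    ordered = sorted(products)[:cap]
    records = [
        MoleculeRecord(id=f"{series.name}_{i + 1:04d}", smiles=smi, pki=float("nan"))
        for i, smi in enumerate(ordered)
    ]
    return MoleculeTable(
        records,
        provenance=f"{series.name}: {len(ordered)} products, {dropped} dropped",
    )


def applicability_domain(model, query) -> bool:
    """Is a query inside a model's applicability domain?

    Fingerprint kNN models: max Tanimoto similarity to the training set
    >= 0.40 (inclusive).  Field model: PLS score-space leverage
    h = t^T (T^T T)^-1 t below 3(A+1)/n_train; ``query`` is then a
    descriptor row.
    """
    if isinstance(model, KNNResults):
        return model.max_similarity(query) >= AD_SIMILARITY_THRESHOLD
    if isinstance(model, FieldQSARResults):
        return model.in_domain(np.asarray(query, dtype=float))
    raise TypeError(f"unsupported model type {type(model).__name__}")


@dataclass(frozen=True)
class ConsensusPrediction:
    """Per-model predictions, domain flags and the gated median verdict."""

    id: str
    smiles: str
    series: str
    pred_field: float  # NaN when alignment fails
    pred_ecfp6: float
    pred_fcfp6: float
    in_domain_field: bool
    in_domain_ecfp6: bool
    in_domain_fcfp6: bool
    consensus: float | None

    def as_row(self) -> dict:
        return {
            "id": self.id,
            "series": self.series,
            "smiles": self.smiles,
            "pred_field": self.pred_field,
            "pred_ecfp6": self.pred_ecfp6,
            "pred_fcfp6": self.pred_fcfp6,
            "in_domain_field": self.in_domain_field,
            "in_domain_ecfp6": self.in_domain_ecfp6,
            "in_domain_fcfp6": self.in_domain_fcfp6,
            "consensus": np.nan if self.consensus is None else self.consensus,
        }


def _mol_seed(smiles: str, seed: int) -> int:
    return (zlib.crc32(smiles.encode()) ^ seed) & 0x7FFFFFFF


def gated_median(predictions, in_domain) -> float | None:
    """Median of the in-domain predictions (mean of two, absent if none)."""
    contributing = [
        p for p, ok in zip(predictions, in_domain) if ok and np.isfinite(p)
    ]
    return float(np.median(contributing)) if contributing else None


def consensus_predict(
    mol: MoleculeRecord,
    field_model: FieldQSARResults,
    ecfp_model: KNNResults,
    fcfp_model: KNNResults,
    series: str = "",
    core: Chem.Mol | None = None,
    seed: int = 0,
    minimize: bool | None = None,
) -> ConsensusPrediction:
    """Score one molecule with all three models and take the gated median.

    Out-of-domain predictions are recorded but excluded from the median;
    with no in-domain model the consensus is absent.
    """
    try:
        x = field_model.descriptor_row(
            mol, seed=_mol_seed(mol.smiles, seed), core=core, minimize=minimize
        )
        pred_field = float(field_model.pls.predict(x)[0])
        dom_field = field_model.in_domain(x)
    except (AlignmentError, ValueError) as exc:
        logger.debug("field prediction failed for %s: %s", mol.id, exc)
        pred_field, dom_field = float("nan"), False

    pred_e, sim_e = ecfp_model.predict_with_similarity(mol)
    dom_e = sim_e >= AD_SIMILARITY_THRESHOLD
    pred_f, sim_f = fcfp_model.predict_with_similarity(mol)
    dom_f = sim_f >= AD_SIMILARITY_THRESHOLD

    consensus = gated_median(
        (pred_field, pred_e, pred_f), (dom_field, dom_e, dom_f)
    )
    return ConsensusPrediction(
        id=mol.id,
        smiles=mol.smiles,
        series=series,
        pred_field=pred_field,
        pred_ecfp6=pred_e,
        pred_fcfp6=pred_f,
        in_domain_field=dom_field,
        in_domain_ecfp6=dom_e,
        in_domain_fcfp6=dom_f,
        consensus=consensus,
    )


def screen(
    series_list,
    lib: FragmentLibrary,
    field_model: FieldQSARResults,
    ecfp_model: KNNResults,
    fcfp_model: KNNResults,
    cap: int = 500,
    seed: int = 0,
    minimize: bool = False,
) -> pd.DataFrame:
    """Enumerate every series and rank all products by gated consensus.

    Returns one row per enumerated product (series-scoped identity, so a
    structure produced by two series appears once per series), sorted by
    consensus descending with absent consensus last.  Field-model
    conformers use fast distance-geometry embedding by default
    (``minimize=True`` switches on MMFF refinement).
    """
    if len(lib) == 0:
        logger.warning("empty fragment library: empty screen report")
        return pd.DataFrame(
            columns=[
                "id", "series", "smiles", "pred_field", "pred_ecfp6", "pred_fcfp6",
                "in_domain_field", "in_domain_ecfp6", "in_domain_fcfp6", "consensus",
            ]
        )
    rows = []
    for series in series_list:
        table = enumerate_series(series, lib, cap=cap)
        logger.info("%s", table.provenance)
        # the constant scaffold doubles as the alignment core for the
        # field model, so the per-molecule MCS search is skipped
        try:
            core = series.core()
            if not Chem.RemoveHs(field_model.template).HasSubstructMatch(core):
                core = None
        except Exception:
            core = None
        for rec in table:
            rows.append(
                consensus_predict(
                    rec,
                    field_model,
                    ecfp_model,
                    fcfp_model,
                    series=series.name,
                    core=core,
                    seed=seed,
                    minimize=minimize,
                ).as_row()
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["consensus", "id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df
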