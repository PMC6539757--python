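"""Field-based 3D-QSAR: template alignment, probe-grid descriptors, SIMPLS.

Every molecule is embedded by distance geometry with its maximum common
substructure (MCS) to a fentanyl template pinned to the template's
coordinates, optionally refined with MMFF94, and rigidly superposed
(Kabsch least squares) onto the template over the MCS atoms.  Molecular
interaction fields are then sampled on a regular grid shared by the whole
model: at each grid point a steric probe energy sum((r_min/r)^12) and an
electrostatic probe energy sum(q_i/(eps*r)) with a +1 probe charge and
distance-dependent dielectric eps = r (hence q_i/r^2), both truncated at
+/-30 and zeroed beyond an 8 A per-atom cutoff.  The descriptor matrix is
regressed on pKi with an explicit SIMPLS partial-least-squares fit; the
component count is chosen by leave-one-out q^2.

``FieldQSAR(table, ...)`` specifies the model; ``.fit()`` returns a
:class:`FieldQSARResults` with coefficients, diagnostics, prediction,
leverage-based applicability domain and a coefficient-grid export.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFMCS, rdMolAlign
from rdkit.Geometry import Point3D

# distance-geometry embedding of heavy-atom skeletons is intentional here;
# silence the per-call reminder (errors stay on)
RDLogger.DisableLog("rdApp.warning")

from .chemio import MoleculeTable
from .simpls import PLSModel, loo_q2_profile, simpls_fit
from .validation import ModelMetrics, regression_metrics

__all__ = [
    "AlignmentError",
    "AlignedConformer",
    "FieldGrid",
    "FieldQSAR",
    "FieldQSARResults",
    "embed_and_align",
    "field_descriptors",
    "load_template",
    "protonate_basic_amine",
]

logger = logging.getLogger(__name__)

MIN_MCS_ATOMS = 6
PROBE_RADIUS = 1.7  # sp3-carbon probe, A
STERIC_CAP = 30.0
ELEC_CAP = 30.0
ATOM_CUTOFF = 8.0  # per-atom field cutoff, A
MIN_R = 0.1  # grid point "on top of" an atom below this distance, A

_BOHR = 0.529177210903  # A per bohr, for cube-format headers


class AlignmentError(ValueError):
    """Molecule shares too small an MCS with the template to be aligned."""


@dataclass(frozen=True)
class AlignedConformer:
    """Heavy-atom coordinates, absorbed charges and alignment diagnostics."""

    coords: np.ndarray  # (n_heavy, 3) A
    charges: np.ndarray  # (n_heavy,) e; H charges absorbed into heavy atoms
    radii: np.ndarray  # (n_heavy,) vdW radii, A
    alignment_rmsd: float  # A, over MCS-mapped atoms
    n_core: int  # MCS atoms used for the superposition
    smiles: str = ""


def protonate_basic_amine(mol: Chem.Mol) -> Chem.Mol:
    """Protonate the most substituted basic aliphatic amine (pH ~7 form).

    Amide/aniline/aromatic nitrogens are skipped.  Returns a new molecule;
    if no candidate exists the input is returned unchanged.
    """
    mol = Chem.Mol(mol)
    best = None
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetIsAromatic():
            continue
        if atom.GetFormalCharge() != 0:
            continue
        if any(b.GetBondTypeAsDouble() > 1.0 for b in atom.GetBonds()):
            continue
        # skip amide / sulfonamide nitrogens and anilines
        neighbors = atom.GetNeighbors()
        if any(n.GetIsAromatic() for n in neighbors):
            continue
        amide = False
        for n in neighbors:
            for b in n.GetBonds():
                other = b.GetOtherAtom(n)
                if b.GetBondTypeAsDouble() == 2.0 and other.GetSymbol() in ("O", "S"):
                    amide = True
        if amide:
            continue
        degree = atom.GetDegree()
        if best is None or degree > best.GetDegree():
            best = atom
    if best is not None:
        best.SetFormalCharge(1)
        best.SetNoImplicit(False)
        Chem.SanitizeMol(mol)
    return mol


def load_template() -> Chem.Mol:
    """The shipped fentanyl template conformer (protonated, with Hs)."""
    with resources.as_file(
        resources.files("fentaqsar") / "data" / "fentanyl_template.sdf"
    ) as p:
        supplier = Chem.SDMolSupplier(str(p), removeHs=False)
        mol = next(iter(supplier))
    if mol is None:  # pragma: no cover
        raise RuntimeError("shipped template failed to load")
    return mol


def _heavy_charges(mol: Chem.Mol) -> np.ndarray:
    """Gasteiger charges with hydrogen charges absorbed into heavy atoms."""
    AllChem.ComputeGasteigerCharges(mol)
    charges = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        if atom.HasProp("_GasteigerHCharge"):
            q += float(atom.GetDoubleProp("_GasteigerHCharge"))
        for n in atom.GetNeighbors():
            if n.GetAtomicNum() == 1:
                q += float(n.GetDoubleProp("_GasteigerCharge"))
        charges.append(q)
    out = np.asarray(charges, dtype=float)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def _heavy_coords(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    return np.array([list(conf.GetAtomPosition(i)) for i in idx])


def _vdw_radii(mol: Chem.Mol) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    return np.array(
        [pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    )


def find_core(mol: Chem.Mol, template_heavy: Chem.Mol) -> Chem.Mol:
    """MCS of a molecule and the template as a query molecule.

    Complete rings only, so ring systems of different sizes are never
    partially mapped onto each other (which would produce geometrically
    infeasible alignment constraints).
    """
    res = rdFMCS.FindMCS(
        [mol, template_heavy], timeout=10, completeRingsOnly=True
    )
    core = Chem.MolFromSmarts(res.smartsString) if res.numAtoms else None
    if core is None or res.numAtoms < MIN_MCS_ATOMS:
        raise AlignmentError(
            f"MCS with template has {res.numAtoms} atoms (< {MIN_MCS_ATOMS})"
        )
    return core


def embed_and_align(
    mol,
    template: Chem.Mol | None = None,
    seed: int = 0,
    core: Chem.Mol | None = None,
    minimize: bool = True,
    protonate: bool = True,
) -> AlignedConformer:
    """Generate one conformer aligned onto the fentanyl template.

    The molecule is embedded by distance geometry with the MCS atoms pinned
    to the template's coordinates, optionally MMFF94-refined, then rigidly
    superposed (Kabsch) onto the template over the MCS mapping.  ``core``
    may supply a precomputed common substructure (e.g. a series scaffold)
    to skip the per-molecule MCS search.  Deterministic for a fixed seed.
    """
    if template is None:
        template = load_template()
    if isinstance(mol, str):
        m0 = Chem.MolFromSmiles(mol)
        if m0 is None:
            raise ValueError(f"unparsable SMILES: {mol!r}")
    elif hasattr(mol, "mol"):
        m0 = mol.mol()
    else:
        m0 = Chem.Mol(mol)
    smiles = Chem.MolToSmiles(m0)
    if protonate:
        m0 = protonate_basic_amine(m0)

    template_heavy = Chem.RemoveHs(template)
    if core is None:
        core = find_core(m0, template_heavy)
    t_match = template_heavy.GetSubstructMatch(core)
    q_match = m0.GetSubstructMatch(core)
    if not t_match or not q_match or len(q_match) < MIN_MCS_ATOMS:
        raise AlignmentError("core does not match both molecule and template")

    work = Chem.AddHs(m0) if minimize else Chem.Mol(m0)
    # heavy-atom indices are preserved by AddHs, so the match carries over
    t_conf = template.GetConformer()
    coord_map = {
        q_match[i]: Point3D(*t_conf.GetAtomPosition(t_match[i]))
        for i in range(len(q_match))
    }
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.useRandomCoords = True
    params.SetCoordMap(coord_map)
    params.clearConfs = True
    def _try_embed() -> bool:
        from rdkit import rdBase

        try:
            with rdBase.BlockLogs():
                return AllChem.EmbedMolecule(work, params) == 0
        except RuntimeError:  # rare optimizer blow-ups inside the embedder
            return False

    if not _try_embed():
        # retry with a shifted seed, then without the coordinate pins
        # (the rigid superposition below still aligns the result)
        params.randomSeed = (int(seed) + 7919) & 0x7FFFFFFF
        if not _try_embed():
            params.SetCoordMap({})
            params.randomSeed = int(seed) & 0x7FFFFFFF
            params.useRandomCoords = False
            if not _try_embed():
                raise AlignmentError(f"distance-geometry embedding failed for {smiles}")
    if minimize:
        try:
            AllChem.MMFFOptimizeMolecule(work, maxIters=200)
        except Exception:  # pragma: no cover - MMFF typing gaps
            logger.warning("MMFF refinement failed for %s; using DG geometry", smiles)
    atom_map = list(zip(q_match, t_match))
    rmsd = rdMolAlign.AlignMol(work, template, atomMap=atom_map)
    return AlignedConformer(
        coords=_heavy_coords(work),
        charges=_heavy_charges(work),
        radii=_vdw_radii(work),
        alignment_rmsd=float(rmsd),
        n_core=len(q_match),
        smiles=smiles,
    )


@dataclass(frozen=True)
class FieldGrid:
    """Regular probe grid shared by training and prediction."""

    origin: np.ndarray  # (3,) A
    spacing: float  # A
    dims: tuple[int, int, int]

    @classmethod
    def from_conformers(
        cls, conformers, spacing: float = 1.0, margin: float = 4.0
    ) -> "FieldGrid":
        all_xyz = np.vstack([c.coords for c in conformers])
        lo = all_xyz.min(axis=0) - margin
        hi = all_xyz.max(axis=0) + margin
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(origin=lo, spacing=float(spacing), dims=dims)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        ax = [self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def to_json_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "dims": list(self.dims),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FieldGrid":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            spacing=float(d["spacing"]),
            dims=tuple(d["dims"]),
        )


def field_descriptors(conf: AlignedConformer, grid: FieldGrid) -> np.ndarray:
    """Steric and electrostatic probe values at every grid point.

    Layout: all steric points first, then all electrostatic points.
    Both probes are truncated at +/-30 and zero beyond the 8 A per-atom
    cutoff; distances below 0.1 A are floored (so an overlapped point
    reports the cap rather than a singularity).
    """
    pts = grid.points()  # (G, 3)
    diff = pts[:, None, :] - conf.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))  # (G, A)
    within = r <= ATOM_CUTOFF
    r_eff = np.maximum(r, MIN_R)
    rmin = conf.radii + PROBE_RADIUS
    steric = np.where(within, (rmin[None, :] / r_eff) ** 12, 0.0).sum(axis=1)
    steric = np.minimum(steric, STERIC_CAP)
    elec = np.where(within, conf.charges[None, :] / r_eff**2, 0.0).sum(axis=1)
    elec = np.clip(elec, -ELEC_CAP, ELEC_CAP)
    return np.concatenate([steric, elec])


@dataclass
class FieldQSAR:
    """Field-based 3D-QSAR model specification."""

    train: MoleculeTable
    spacing: float = 1.0
    margin: float = 4.0
    protonate: bool = True
    minimize: bool = True
    seed: int = 0
    max_components: int = 10
    template: Chem.Mol | None = None

    def fit(self, n_components: int | None = None) -> "FieldQSARResults":
        if len(self.train) < 3:
            raise ValueError("field model needs at least 3 training molecules")
        template = self.template if self.template is not None else load_template()

        conformers, ids, pkis, excluded = [], [], [], []
        for rec in self.train:
            try:
                conf = embed_and_align(
                    rec,
                    template=template,
                    seed=self.seed,
                    minimize=self.minimize,
                    protonate=self.protonate,
                )
            except (AlignmentError, ValueError) as exc:
                logger.warning("field model excludes %s: %s", rec.id, exc)
                excluded.append((rec.id, str(exc)))
                continue
            conformers.append(conf)
            ids.append(rec.id)
            pkis.append(rec.pki)
        if len(conformers) < 3:
            raise ValueError("fewer than 3 molecules aligned; cannot fit")

        grid = FieldGrid.from_conformers(conformers, self.spacing, self.margin)
        X_full = np.vstack([field_descriptors(c, grid) for c in conformers])
        y = np.asarray(pkis)

        # grid points no molecule reaches carry no information; drop them
        active = X_full.std(axis=0) > 1e-9
        X = X_full[:, active]

        max_a = max(1, min(self.max_components, len(y) - 2))
        if n_components is None:
            q2_by_count = loo_q2_profile(X, y, max_a)
            n_components = max(q2_by_count, key=lambda a: (q2_by_count[a], -a))
            if q2_by_count[n_components] <= 0:
                warnings.warn("no component count achieves q2 > 0")
                n_components = min(q2_by_count)
        else:
            q2_by_count = loo_q2_profile(X, y, min(n_components, max_a))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = simpls_fit(X, y, n_components)

        return FieldQSARResults(
            model=self,
            template=template,
            grid=grid,
            active=active,
            pls=pls,
            ids=ids,
            y=y,
            X=X,
            q2_by_count=q2_by_count,
            excluded=excluded,
        )


class FieldQSARResults:
    """Fitted field model: SIMPLS coefficients, AD machinery, prediction."""

    def __init__(self, model, template, grid, active, pls, ids, y, X, q2_by_count, excluded):
        self.model = model
        self.template = template
        self.grid = grid
        self.active = active
        self.pls: PLSModel = pls
        self.ids = ids
        self.y = y
        self.X = X
        self.q2_by_count = q2_by_count
        self.excluded = excluded
        # leverage lives in the PLS score space (Williams-plot convention):
        # with p >> n raw-descriptor leverage saturates near 1 for every
        # compound and the 3(A+1)/n cutoff would reject the training set
        T = (X - pls.x_mean) @ pls.weights
        self._score_gram_inv = np.linalg.inv(T.T @ T)

    # -- prediction ----------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.pls.n_components

    @property
    def q2(self) -> float:
        return self.q2_by_count[self.n_components]

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.pls.predict(self.X)

    def descriptor_row(self, mol, seed: int | None = None, core=None,
                       minimize: bool | None = None) -> np.ndarray:
        conf = embed_and_align(
            mol,
            template=self.template,
            seed=self.model.seed if seed is None else seed,
            core=core,
            minimize=self.model.minimize if minimize is None else minimize,
            protonate=self.model.protonate,
        )
        return field_descriptors(conf, self.grid)[self.active]

    def predict_one(self, mol, seed: int | None = None, core=None,
                    minimize: bool | None = None) -> float:
        x = self.descriptor_row(mol, seed=seed, core=core, minimize=minimize)
        return float(self.pls.predict(x)[0])

    def predict(self, table, seed: int | None = None) -> np.ndarray:
        """Predict pKi for an iterable of records; NaN where alignment fails."""
        out = []
        for rec in table:
            try:
                out.append(self.predict_one(rec, seed=seed))
            except (AlignmentError, ValueError):
                out.append(np.nan)
        return np.asarray(out)

    # -- applicability domain ------------------------------------------
    def leverage(self, x_row: np.ndarray) -> float:
        """Score-space leverage h = t^T (T^T T)^-1 t of a descriptor row."""
        xc = np.asarray(x_row, dtype=float) - self.pls.x_mean
        t = xc @ self.pls.weights
        return float(t @ self._score_gram_inv @ t)

    @property
    def leverage_threshold(self) -> float:
        return 3.0 * (self.n_components + 1) / len(self.y)

    def in_domain(self, x_row: np.ndarray) -> bool:
        return self.leverage(x_row) < self.leverage_threshold

    # -- reporting -----------------------------------------------------
    def metrics(self, table: MoleculeTable, seed: int | None = None) -> ModelMetrics:
        preds = self.predict(table, seed=seed)
        ok = ~np.isnan(preds)
        return regression_metrics(table.pki[ok], preds[ok])

    def summary(self) -> str:
        train_m = regression_metrics(self.y, self.fittedvalues)
        lines = [
            "Field-based 3D-QSAR (SIMPLS on steric+electrostatic probe grid)",
            f"  grid: {self.grid.dims} points @ {self.grid.spacing} A "
            f"({int(self.active.sum())} active descriptors)",
            f"  n_train = {len(self.y)}"
            + (f" ({len(self.excluded)} excluded by alignment)" if self.excluded else ""),
            f"  components = {self.n_components} (LOO-selected)",
            f"  training r2 = {train_m.r2:.4f}, LOO q2 = {self.q2:.4f}",
        ]
        return "\n".join(lines)

    # -- coefficient-grid export ---------------------------------------
    def export_coefficient_grid(self, prefix) -> list[Path]:
        """Write per-point steric/electrostatic PLS coefficients.

        Two plain-text files in Gaussian cube layout (values in the order
        z fastest, then y, then x) for external visualization.
        """
        coef_full = np.zeros(2 * self.grid.n_points)
        coef_full[self.active] = self.pls.coef
        g = self.grid.n_points
        paths = []
        for name, block in (("steric", coef_full[:g]), ("electrostatic", coef_full[g:])):
            path = Path(f"{prefix}_{name}.cube")
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"fentaqsar field coefficients: {name}\n")
                fh.write("PLS regression coefficient per grid point\n")
                ox, oy, oz = (self.grid.origin / _BOHR).tolist()
                step = self.grid.spacing / _BOHR
                nx, ny, nz = self.grid.dims
                fh.write(f"{1:5d} {ox:11.6f} {oy:11.6f} {oz:11.6f}\n")
                fh.write(f"{nx:5d} {step:11.6f} {0.0:11.6f} {0.0:11.6f}\n")
                fh.write(f"{ny:5d} {0.0:11.6f} {step:11.6f} {0.0:11.6f}\n")
                fh.write(f"{nz:5d} {0.0:11.6f} {0.0:11.6f} {step:11.6f}\n")
                fh.write(f"{6:5d} {0.0:11.6f} {ox:11.6f} {oy:11.6f} {oz:11.6f}\n")
                vals = block.reshape(self.grid.dims)
                for ix in range(nx):
                    for iy in range(ny):
                        row = vals[ix, iy]
                        for start in range(0, nz, 6):
                            fh.write(
                                " ".join(f"{v:12.5e}" for v in row[start : start + 6])
                                + "\n"
                            )
            paths.append(path)
        return paths

    # -- serialization -------------------------------------------------
    def save(self, path):
        """Versioned JSON metadata + .npz matrix sidecar."""
        path = Path(path)
        sidecar = path.with_suffix(".npz")
        np.savez_compressed(
            sidecar,
            active=self.active,
            X=self.X,
            y=self.y,
            coef=self.pls.coef,
            x_mean=self.pls.x_mean,
            weights=self.pls.weights,
            x_loadings=self.pls.x_loadings,
            y_loadings=self.pls.y_loadings,
        )
        meta = {
            "format": "fentaqsar-field-v1",
            "grid": self.grid.to_json_dict(),
            "n_components": self.pls.n_components,
            "y_mean": self.pls.y_mean,
            "ids": self.ids,
            "q2_by_count": {str(k): v for k, v in self.q2_by_count.items()},
            "excluded": self.excluded,
            "sidecar": sidecar.name,
            "spacing": self.model.spacing,
            "margin": self.model.margin,
            "protonate": self.model.protonate,
            "minimize": self.model.minimize,
            "seed": self.model.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "FieldQSARResults":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta.get("format") != "fentaqsar-field-v1":
            raise ValueError("not a serialized field model")
        arrays = np.load(path.parent / meta["sidecar"])
        pls = PLSModel(
            n_components=int(meta["n_components"]),
            x_mean=arrays["x_mean"],
            y_mean=float(meta["y_mean"]),
            weights=arrays["weights"],
            x_loadings=arrays["x_loadings"],
            y_loadings=arrays["y_loadings"],
            coef=arrays["coef"],
        )
        model = FieldQSAR(
            train=MoleculeTable([]),
            spacing=meta["spacing"],
            margin=meta["margin"],
            protonate=meta["protonate"],
            minimize=meta["minimize"],
            seed=meta["seed"],
        )
        return cls(
            model=model,
            template=load_template(),
            grid=FieldGrid.from_json_dict(meta["grid"]),
            active=arrays["active"],
            pls=pls,
            ids=meta["ids"],
            y=arrays["y"],
            X=arrays["X"],
            q2_by_count={int(k): v for k, v in meta["q2_by_count"].items()},
            excluded=[tuple(e) for e in meta["excluded"]],
        )
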