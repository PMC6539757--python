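"""Template alignment, probe-grid descriptors and the field QSAR model."""

import numpy as np
import pytest
from rdkit import Chem

import fentaqsar as fq
from fentaqsar.field import (
    AlignedConformer,
    AlignmentError,
    FieldGrid,
    load_template,
    protonate_basic_amine,
)
from fentaqsar.simpls import loo_q2_profile, simpls_fit

FENTANYL = "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1"
ACETYLFENTANYL = "CC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1"


class TestAlignment:
    def test_template_aligned_to_itself_has_near_zero_rmsd(self):
        conf = fq.embed_and_align(FENTANYL, seed=1)
        assert conf.alignment_rmsd < 0.1
        assert conf.n_core >= 20

    def test_close_analog_maps_anilidopiperidine_core(self):
        conf = fq.embed_and_align(ACETYLFENTANYL, seed=1)
        assert conf.n_core >= 13

    def test_unrelated_molecule_rejected(self):
        with pytest.raises(AlignmentError):
            fq.embed_and_align("CC", seed=1)

    def test_deterministic_for_fixed_seed(self):
        a = fq.embed_and_align(ACETYLFENTANYL, seed=5)
        b = fq.embed_and_align(ACETYLFENTANYL, seed=5)
        assert np.allclose(a.coords, b.coords)

    def test_protonation_targets_the_piperidine_amine(self):
        mol = protonate_basic_amine(Chem.MolFromSmiles(FENTANYL))
        charged = [a for a in mol.GetAtoms() if a.GetFormalCharge() == 1]
        assert len(charged) == 1
        atom = charged[0]
        assert atom.GetSymbol() == "N"
        assert atom.IsInRing()  # the basic amine, not the anilide nitrogen


def single_atom_conformer(q=0.0):
    return AlignedConformer(
        coords=np.zeros((1, 3)),
        charges=np.array([q]),
        radii=np.array([1.7]),
        alignment_rmsd=0.0,
        n_core=6,
    )


class TestFieldDescriptors:
    def test_far_grid_point_contributes_zero(self):
        grid = FieldGrid(origin=np.array([20.0, 0, 0]), spacing=1.0, dims=(1, 1, 1))
        row = fq.field_descriptors(single_atom_conformer(q=0.5), grid)
        assert np.all(row == 0.0)

    def test_overlapping_grid_point_hits_the_cap(self):
        grid = FieldGrid(origin=np.array([0.05, 0, 0]), spacing=1.0, dims=(1, 1, 1))
        row = fq.field_descriptors(single_atom_conformer(q=0.5), grid)
        steric, elec = row[0], row[1]
        assert steric == 30.0
        assert elec == 30.0  # q/r^2 = 0.5/0.01 = 50, clipped

    def test_identical_conformers_give_identical_rows(self):
        grid = FieldGrid(origin=np.array([-2.0, -2, -2]), spacing=1.0, dims=(5, 5, 5))
        a = fq.field_descriptors(single_atom_conformer(0.3), grid)
        b = fq.field_descriptors(single_atom_conformer(0.3), grid)
        assert np.array_equal(a, b)

    def test_row_layout_is_steric_then_electrostatic(self):
        grid = FieldGrid(origin=np.array([2.0, 0, 0]), spacing=1.0, dims=(2, 1, 1))
        row = fq.field_descriptors(single_atom_conformer(q=-0.5), grid)
        assert len(row) == 4
        assert np.all(row[:2] > 0)  # steric repulsion is positive
        assert np.all(row[2:] < 0)  # negative charge, negative potential

    def test_grid_encloses_conformers_with_margin(self):
        conf = fq.embed_and_align(FENTANYL, seed=1)
        grid = FieldGrid.from_conformers([conf], spacing=1.0, margin=4.0)
        lo, hi = conf.coords.min(0), conf.coords.max(0)
        assert np.all(grid.origin <= lo - 4.0 + 1e-9)
        top = grid.origin + grid.spacing * (np.array(grid.dims) - 1)
        assert np.all(top >= hi + 4.0 - grid.spacing)


class TestFieldModel:
    def test_recovery_of_a_linear_field_response(self, models):
        """A response linear in the descriptors is recovered nearly exactly."""
        _, trained = models
        X = trained.field.X
        rng = np.random.default_rng(0)
        # linear response along the leading field-variation directions
        Xc = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        y = U[:, :5] @ rng.normal(size=5)
        y = (y - y.mean()) / y.std() + 8.0 + rng.normal(0, 0.1, len(y))
        profile = loo_q2_profile(X, y, 10)
        best = max(profile, key=profile.get)
        m = simpls_fit(X, y, best)
        r2 = fq.regression_metrics(y, m.predict(X)).r2
        assert r2 >= 0.95
        assert profile[best] >= 0.7

    def test_training_molecules_are_in_domain(self, models):
        _, trained = models
        fm = trained.field
        levs = np.array([fm.leverage(x) for x in fm.X])
        assert np.all(levs < fm.leverage_threshold)

    def test_fitted_values_reproduce_coefficient_identity(self, models):
        _, trained = models
        fm = trained.field
        manual = (fm.X - fm.pls.x_mean) @ fm.pls.coef + fm.pls.y_mean
        assert np.allclose(manual, fm.fittedvalues)

    def test_serialization_round_trip(self, models, tmp_path):
        _, trained = models
        fm = trained.field
        fm.save(tmp_path / "field.json")
        back = fq.FieldQSARResults.load(tmp_path / "field.json")
        assert back.n_components == fm.n_components
        x = fm.X[0]
        assert back.pls.predict(x)[0] == pytest.approx(fm.pls.predict(x)[0])
        assert back.leverage(x) == pytest.approx(fm.leverage(x))

    def test_coefficient_grid_export_is_complete(self, models, tmp_path):
        _, trained = models
        fm = trained.field
        paths = fm.export_coefficient_grid(tmp_path / "coef")
        assert len(paths) == 2
        for p in paths:
            lines = p.read_text().splitlines()
            nx = int(lines[3].split()[0])
            assert nx == fm.grid.dims[0]
            values = [float(v) for ln in lines[7:] for v in ln.split()]
            assert len(values) == fm.grid.n_points
            assert np.all(np.isfinite(values))

    def test_misaligned_molecules_predict_nan(self, models):
        _, trained = models
        preds = trained.field.predict(
            [fq.MoleculeRecord(id="x", smiles="CC", pki=5.0)]
        )
        assert np.isnan(preds[0])
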